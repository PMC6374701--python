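"""Median-binarization signature scoring and survival stratification.

The 22-gene-style signature workflow: signature genes are split into two
groups by average-linkage hierarchical clustering on 1 - Pearson distance in
the *normal* samples (Group1 = the cluster with higher mean normal
expression); each gene is binarized against its median over *cancer* samples
(strictly greater -> 1, ties -> 0); per-sample group scores are means of the
indicators, with score > 0.5 labelling the sample "High" (exactly 0.5 is
"Low" — the strict reading of the rule); combined labels form up to four
patient clusters. Stratified overall survival is compared by Kaplan-Meier
curves, the two-group log-rank test and a univariate Cox model (Efron ties),
all via lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    MissingGenesError,
    ValidationError,
)

__all__ = [
    "GeneGroupSplit",
    "SignatureScore",
    "SurvivalComparison",
    "split_gene_groups",
    "median_binarize",
    "score_and_label",
    "km_estimate",
    "logrank_test",
    "cox_hr",
]


@dataclass
class GeneGroupSplit:
    group1: list  # higher mean expression in normals
    group2: list
    linkage_matrix: np.ndarray | None = None

    def __post_init__(self):
        if set(self.group1) & set(self.group2):
            raise ValidationError("gene groups must be disjoint")

    @property
    def all_genes(self) -> list:
        return list(self.group1) + list(self.group2)


@dataclass
class SignatureScore:
    indicators: pd.DataFrame  # genes x samples, {0,1}
    scores: pd.DataFrame  # samples x groups, mean indicator in [0,1]
    labels: pd.DataFrame  # samples x groups, 'High'/'Low'
    combined: pd.Series  # e.g. 'HighGroup1.LowGroup2'


@dataclass
class SurvivalComparison:
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    unbounded_ci: bool = False


def _check_genes(expr: pd.DataFrame, genes) -> list:
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise MissingGenesError(missing)
    return genes


def split_gene_groups(expr_normals: pd.DataFrame, signature_genes, k: int = 2) -> GeneGroupSplit:
    """Cluster signature genes on their normal-sample expression profiles.

    Average-linkage agglomeration on distance 1 - Pearson correlation, cut at
    ``k`` clusters. For k = 2, Group1 is the cluster with the higher mean
    expression across normals. Genes constant across normals (correlation
    undefined) are assigned afterwards to the cluster whose mean profile is
    nearest in Euclidean distance, with a warning.
    """
    genes = _check_genes(expr_normals, signature_genes)
    if expr_normals.shape[1] < 3:
        raise InsufficientDataError("need >= 3 normal samples to split gene groups")
    if len(genes) < k:
        raise ValidationError(f"need >= k={k} genes")
    x = expr_normals.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    const_genes = [g for g, o in zip(genes, ok) if not o]
    var_genes = [g for g, o in zip(genes, ok) if o]
    if len(var_genes) < k:
        raise ValidationError("too few non-constant genes to cluster")
    xc = x[ok]
    corr = np.corrcoef(xc)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust")
    clusters = {c: [g for g, a in zip(var_genes, assign) if a == c] for c in np.unique(assign)}
    if const_genes:
        warnings.warn(
            f"assigning constant genes {const_genes} by nearest cluster centroid",
            stacklevel=2,
        )
        for g in const_genes:
            prof = expr_normals.loc[g].to_numpy(dtype=float)
            dists = {
                c: np.linalg.norm(expr_normals.loc[mem].mean(axis=0).to_numpy() - prof)
                for c, mem in clusters.items()
            }
            clusters[min(dists, key=dists.get)].append(g)
    if k == 2:
        means = {c: float(expr_normals.loc[mem].mean().mean()) for c, mem in clusters.items()}
        hi = max(means, key=means.get)
        lo = next(c for c in clusters if c != hi)
        return GeneGroupSplit(group1=clusters[hi], group2=clusters[lo], linkage_matrix=Z)
    ordered = [clusters[c] for c in sorted(clusters)]
    return GeneGroupSplit(group1=ordered[0], group2=[g for mem in ordered[1:] for g in mem],
                          linkage_matrix=Z)


def median_binarize(expr_cancer: pd.DataFrame, signature_genes) -> pd.DataFrame:
    """Per-gene indicator of expression strictly above the cancer-cohort median.

    Medians are computed over cancer samples only; a value equal to the
    median scores 0.
    """
    genes = _check_genes(expr_cancer, signature_genes)
    if expr_cancer.shape[1] < 2:
        raise InsufficientDataError("need >= 2 cancer samples")
    sub = expr_cancer.loc[genes]
    med = sub.median(axis=1)
    return (sub.gt(med, axis=0)).astype(int)


def score_and_label(binary: pd.DataFrame, split: GeneGroupSplit) -> SignatureScore:
    """Group-mean scores and High/Low labels from a binarized matrix.

    High iff score > 0.5; a score of exactly 0.5 is Low.
    """
    if not split.group1 or not split.group2:
        raise ConfigurationError("both gene groups must be non-empty")
    missing = set(split.all_genes) - set(binary.index)
    if missing:
        raise MissingGenesError(missing)
    groups = {"Group1": split.group1, "Group2": split.group2}
    scores = pd.DataFrame(
        {name: binary.loc[genes].mean(axis=0) for name, genes in groups.items()}
    )
    labels = scores.gt(0.5).replace({True: "High", False: "Low"})
    combined = labels["Group1"] + "Group1." + labels["Group2"] + "Group2"
    return SignatureScore(indicators=binary, scores=scores, labels=labels, combined=combined)


def _check_surv(surv: pd.DataFrame):
    if not {"time", "event"}.issubset(surv.columns):
        raise ValidationError("survival table needs 'time' and 'event' columns")
    if (surv["time"] < 0).any():
        raise ValidationError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0/1")


def km_estimate(surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate: DataFrame (time, survival)."""
    _check_surv(surv)
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(surv: pd.DataFrame, stratum: str = "stratum") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    _check_surv(surv)
    levels = surv[stratum].unique()
    if len(levels) != 2 or any((surv[stratum] == l).sum() == 0 for l in levels):
        raise ValidationError("need exactly two non-empty strata")
    a = surv[surv[stratum] == levels[0]]
    b = surv[surv[stratum] == levels[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(surv: pd.DataFrame, stratum: str = "stratum", reference=None) -> SurvivalComparison:
    """Univariate Cox proportional hazards for a binary stratum.

    The hazard ratio is for the non-reference level relative to ``reference``
    (default: the lexicographically first level). Wald 95% CI on the log-HR
    scale; Efron tie handling (lifelines default). If one stratum has no
    events the partial likelihood is monotone: a warning is issued and the CI
    is flagged unbounded.
    """
    _check_surv(surv)
    levels = sorted(surv[stratum].unique())
    if len(levels) != 2:
        raise ValidationError("cox_hr requires exactly two strata")
    if reference is None:
        reference = levels[0]
    other = next(l for l in levels if l != reference)
    df = pd.DataFrame(
        {
            "time": surv["time"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "x": (surv[stratum] == other).astype(int).to_numpy(),
        }
    )
    events_per = df.groupby("x")["event"].sum()
    unbounded = bool((events_per == 0).any())
    if unbounded:
        warnings.warn(
            "a stratum has zero events: monotone partial likelihood, CI unbounded",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    chi2, p = logrank_test(surv, stratum)
    return SurvivalComparison(
        logrank_chi2=chi2,
        logrank_p=p,
        hazard_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci95_high=float(np.exp(beta + 1.959963984540054 * se)),
        unbounded_ci=unbounded,
    )
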