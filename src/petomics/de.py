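"""Paired tumor-vs-normal differential expression.

The test is a moderated paired t-test on per-patient log2 differences: each
gene's sample variance is shrunk toward a pooled prior variance estimated
from all genes by method-of-moments (an empirical-Bayes scheme in the spirit
of limma's moderated statistics), the t reference gains the prior degrees of
freedom, and p-values are Benjamini-Hochberg adjusted. Significance requires
both adj_p < alpha and |log2FC| >= lfc_threshold.

Three comparisons (all pairs, non-metastatic pairs, metastatic pairs) are
intersected by :func:`consensus_intersection` to form a consensus DE set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, PairingError, ValidationError

__all__ = ["paired_de", "bh_adjust", "consensus_intersection", "ConsensusSet"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_matrices(expr: pd.DataFrame, annot: pd.DataFrame):
    """Align tumor and normal columns patient-by-patient.

    ``annot`` needs columns sample_id, patient_id, condition ('tumor'/'normal').
    Returns (tumor_values, normal_values, patient_ids) with matching column
    order.
    """
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(annot.columns):
        raise ValidationError(f"annotation must have columns {sorted(required)}")
    ann = annot.set_index("sample_id")
    missing = set(ann.index) - set(expr.columns)
    if missing:
        raise PairingError(f"annotated samples absent from matrix: {sorted(missing)[:5]}")
    tumors = ann[ann["condition"] == "tumor"]
    normals = ann[ann["condition"] == "normal"]
    t_by_patient = dict(zip(tumors["patient_id"], tumors.index))
    n_by_patient = dict(zip(normals["patient_id"], normals.index))
    patients = sorted(t_by_patient)
    if set(patients) != set(n_by_patient) or len(t_by_patient) != len(tumors):
        raise PairingError("every tumor sample needs exactly one matched normal per patient")
    t_cols = [t_by_patient[p] for p in patients]
    n_cols = [n_by_patient[p] for p in patients]
    return expr[t_cols].to_numpy(), expr[n_cols].to_numpy(), patients


def _moments_shrinkage(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for variance shrinkage.

    Matches the first two moments of the observed per-gene variances to a
    scaled inverse-chi-square prior: with no extra between-gene dispersion
    beyond chi-square sampling noise, d0 -> inf (complete pooling).
    """
    m1 = float(np.mean(s2))
    if m1 <= 0:
        return np.inf, max(m1, 1e-12)
    m2 = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    excess = m2 / (m1 * m1) - 2.0 / df
    if excess <= 1e-12:
        return np.inf, m1
    return 2.0 / excess, m1


def paired_de(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Moderated paired t-test per gene.

    Parameters
    ----------
    expr
        log2 expression, genes x samples (index = gene IDs).
    annot
        Sample annotation with sample_id / patient_id / condition columns.

    Returns
    -------
    DataFrame indexed by gene with columns log2_fc, t_stat, p_value, adj_p,
    direction ('up'/'down') and significant (bool).
    """
    tumor, normal, patients = _pair_matrices(expr, annot)
    n = len(patients)
    if n < 3:
        raise InsufficientDataError(f"paired DE needs >= 3 pairs, got {n}")
    d = tumor - normal
    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    d0, s02 = _moments_shrinkage(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = min(df * len(s2), 1_000_000)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(np.maximum(s2_post, 1e-300) / n)
    t_stat = mean_d / se
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2_fc": mean_d,
            "t_stat": t_stat,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(mean_d >= 0, "up", "down"),
            "significant": (adj < alpha) & (np.abs(mean_d) >= lfc_threshold),
        },
        index=expr.index,
    )
    return out


@dataclass
class ConsensusSet:
    """Per-comparison significant gene sets, their intersection and uniques."""

    sets: dict[str, set]
    intersection: set
    unique: dict[str, set]

    def __post_init__(self):
        assert all(self.intersection <= s for s in self.sets.values())


def consensus_intersection(de_results: dict[str, pd.DataFrame]) -> ConsensusSet:
    """Intersect significant genes across >= 2 labelled DE comparisons."""
    if len(de_results) < 2:
        raise ValidationError("need at least 2 comparisons to intersect")
    sets = {}
    for label, res in de_results.items():
        sig = set(res.index[res["significant"]])
        if not sig:
            warnings.warn(f"comparison '{label}' has no significant genes", stacklevel=2)
        sets[label] = sig
    inter = set.intersection(*sets.values())
    unique = {
        lab: s - set.union(*(o for k, o in sets.items() if k != lab)) for lab, s in sets.items()
    }
    return ConsensusSet(sets=sets, intersection=inter, unique=unique)
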