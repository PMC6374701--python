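"""Synthetic radiogenomic cohort generator.

Three generators share a :class:`~petomics.config.CohortConfig` and a seeded
RNG so every downstream stage has a recoverable ground truth:

* :func:`simulate_paired_expression` — paired tumor/normal log2 expression
  for ``n_patients`` with ``n_de_genes`` planted differential genes (shift
  +/- ``de_effect`` in tumors) and a metastatic patient subgroup.
* :func:`simulate_patient_kinetics` — per-patient two-tissue-compartment
  rate constants where a latent tumor-metabolism factor (shared with the
  linked genes of the expression simulator through the config seed) drives
  k3 — and through it Ki, late-time uptake (SUV) and curve heterogeneity
  (FD) — while k1, k2, k4 and VB are drawn independently. Tumor and normal
  28-frame/60-min TACs are produced through the analytic compartment solver.
* :func:`simulate_tcga_like` — a large expression + overall-survival cohort
  in which a planted High-Group2 stratum multiplies the exponential hazard
  by ``planted_hr``, with independent uniform censoring thinned to the
  requested censoring rate.

All outputs are bit-identical for identical configs (seeded
``numpy.random.default_rng`` streams keyed per component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig, SurvivalSimConfig
from .exceptions import ConfigurationError
from .kinetics import (
    PET_FEATURE_COLUMNS,
    KineticParameters,
    TimeActivityCurve,
    default_frame_schedule,
    feng_input_function,
    fractal_dimension,
    influx,
    solve_two_tissue,
    suv,
)

__all__ = [
    "GroundTruth",
    "simulate_paired_expression",
    "simulate_patient_kinetics",
    "simulate_tcga_like",
    "simulate_selection_benchmark",
]

# acquisition constants used for the simulated SUV (typical adult FDG study)
INJECTED_DOSE_MBQ = 370.0
BODY_WEIGHT_KG = 75.0


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort (fields filled per generator)."""

    de_gene_ids: list = field(default_factory=list)
    de_signs: dict = field(default_factory=dict)
    linked_gene_ids: list = field(default_factory=list)
    latent_factors: pd.Series | None = None
    true_kinetics: dict[str, KineticParameters] | None = None
    normal_pet: pd.DataFrame | None = None
    score_groups: pd.DataFrame | None = None
    group1_genes: list = field(default_factory=list)
    group2_genes: list = field(default_factory=list)


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per component of the simulation."""
    return np.random.default_rng([config.seed, abs(hash_stable(stream))])


def hash_stable(s: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")


def _patient_ids(n: int) -> list[str]:
    return [f"P{i+1:03d}" for i in range(n)]


def _latent_factors(config: CohortConfig) -> pd.Series:
    """Shared per-patient tumor-metabolism factor (standard normal)."""
    rng = _rng(config, "latent")
    return pd.Series(rng.standard_normal(config.n_patients), index=_patient_ids(config.n_patients))


def _metastatic_patients(config: CohortConfig) -> list[str]:
    rng = _rng(config, "metastatic")
    pats = _patient_ids(config.n_patients)
    return sorted(rng.choice(pats, size=config.n_metastatic, replace=False))


def simulate_paired_expression(config: CohortConfig):
    """Paired tumor/normal log2 expression with planted DE and linked genes.

    Returns (expression genes x 2*n_patients, annotation, GroundTruth). DE
    genes are shifted by +/- de_effect in tumor samples only; the first
    ``n_linked_genes`` of them additionally receive ``latent_loading`` times
    the patient's latent factor in tumors, coupling them to the PET block.
    """
    config.validate()
    rng = _rng(config, "expression")
    pats = _patient_ids(config.n_patients)
    genes = [f"G{i+1:05d}" for i in range(config.n_genes)]
    z = _latent_factors(config)
    base = rng.normal(7.0, 1.5, size=config.n_genes)
    patient_eff = rng.normal(0.0, 0.3, size=config.n_patients)
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    linked_idx = de_idx[: config.n_linked_genes]
    normal = (
        base[:, None]
        + patient_eff[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_patients))
    )
    tumor = (
        base[:, None]
        + patient_eff[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_patients))
    )
    tumor[de_idx] += (signs * config.de_effect)[:, None]
    tumor[linked_idx] += config.latent_loading * z.to_numpy()[None, :]
    t_ids = [f"{p}_T" for p in pats]
    n_ids = [f"{p}_N" for p in pats]
    expr = pd.DataFrame(
        np.concatenate([tumor, normal], axis=1), index=genes, columns=t_ids + n_ids
    )
    expr.index.name = "gene_id"
    mets = set(_metastatic_patients(config))
    annot = pd.DataFrame(
        {
            "sample_id": t_ids + n_ids,
            "patient_id": pats + pats,
            "condition": ["tumor"] * config.n_patients + ["normal"] * config.n_patients,
            "metastatic": [int(p in mets) for p in pats + pats],
        }
    )
    truth = GroundTruth(
        de_gene_ids=[genes[i] for i in de_idx],
        de_signs={genes[i]: float(s) for i, s in zip(de_idx, signs)},
        linked_gene_ids=[genes[i] for i in linked_idx],
        latent_factors=z,
    )
    return expr, annot, truth


# lognormal location/scale of the tumor rate constants (1/min); typical FDG
# colorectal values: transport ~0.15, efflux ~0.4, phosphorylation ~0.08,
# dephosphorylation ~0.01, blood fraction ~0.05
_TUMOR_KINETIC_PRIORS = {
    "k1": (np.log(0.15), 0.25),
    "k2": (np.log(0.40), 0.25),
    "k4": (np.log(0.010), 0.30),
}
_K3_LOC, _K3_SCALE = np.log(0.08), 0.5
# normal colon tissue: lower transport and phosphorylation, per-patient
# lognormal variability (scale 0.2) around these medians
_NORMAL_TISSUE = {"k1": 0.08, "k2": 0.5, "k3": 0.015, "k4": 0.008}
_NORMAL_VB = 0.04


def simulate_patient_kinetics(config: CohortConfig):
    """Per-patient kinetic parameters, TACs and the 8-variable feature table.

    k3 is a monotone (log-linear) function of the latent metabolism factor
    with correlation ``latent_loading`` on the log scale; k1, k2, k4 and VB
    are independent draws. Tumor TAC measurement noise grows with the latent
    factor so curve heterogeneity (FD) tracks metabolism as well. Returns
    (list of TACs, PETFeatureTable DataFrame, GroundTruth).
    """
    config.validate()
    rng = _rng(config, "kinetics")
    pats = _patient_ids(config.n_patients)
    z = _latent_factors(config)
    lam = config.latent_loading
    eps = rng.standard_normal(config.n_patients)
    log_k3 = _K3_LOC + _K3_SCALE * (lam * z.to_numpy() + np.sqrt(max(1 - lam**2, 0.0)) * eps)
    draws = {
        name: np.exp(rng.normal(loc, scale, size=config.n_patients))
        for name, (loc, scale) in _TUMOR_KINETIC_PRIORS.items()
    }
    vb = expit(rng.normal(np.log(0.05 / 0.95), 0.3, size=config.n_patients))
    cp = feng_input_function()
    mids, durs = default_frame_schedule()
    tacs: list[TimeActivityCurve] = []
    rows = []
    normal_rows = []
    truth_kin: dict[str, KineticParameters] = {}
    normal_draws = {
        name: np.exp(rng.normal(np.log(v), 0.2, size=config.n_patients))
        for name, v in _NORMAL_TISSUE.items()
    }
    normal_vb = expit(rng.normal(np.log(_NORMAL_VB / (1 - _NORMAL_VB)), 0.2,
                                 size=config.n_patients))
    for i, p in enumerate(pats):
        params = KineticParameters(
            k1=float(draws["k1"][i]),
            k2=float(draws["k2"][i]),
            k3=float(np.exp(log_k3[i])),
            k4=float(draws["k4"][i]),
            vb=float(vb[i]),
        )
        truth_kin[p] = params
        tumor_clean = solve_two_tissue(params, cp, mids, durs, voi_label="tumor")
        noise_amp = 0.01 + 0.10 * expit(2.0 * z[p])
        noisy = tumor_clean.activity * (
            1.0 + noise_amp * rng.standard_normal(len(mids))
        )
        tumor_tac = TimeActivityCurve(
            mids, np.clip(noisy, 0.0, None), durs, voi_label="tumor", patient_id=p
        )
        normal_params = KineticParameters(
            k1=float(normal_draws["k1"][i]),
            k2=float(normal_draws["k2"][i]),
            k3=float(normal_draws["k3"][i]),
            k4=float(normal_draws["k4"][i]),
            vb=float(normal_vb[i]),
        )
        normal_clean = solve_two_tissue(normal_params, cp, mids, durs, voi_label="normal")
        normal_noisy = normal_clean.activity * (1.0 + 0.01 * rng.standard_normal(len(mids)))
        normal_tac = TimeActivityCurve(
            mids, np.clip(normal_noisy, 0.0, None), durs, voi_label="normal", patient_id=p
        )
        tacs.extend([tumor_tac, normal_tac])

        def _feature_row(kp: KineticParameters, tac: TimeActivityCurve) -> dict:
            return {
                "SUV": suv(tac, INJECTED_DOSE_MBQ, BODY_WEIGHT_KG),
                "k1": kp.k1,
                "k2": kp.k2,
                "k3": kp.k3,
                "k4": kp.k4,
                "VB": kp.vb,
                "INF": influx(kp.k1, kp.k2, kp.k3),
                "FD": fractal_dimension(tac),
            }

        rows.append(_feature_row(params, tumor_tac))
        normal_rows.append(_feature_row(normal_params, normal_tac))
    pet = pd.DataFrame(rows, index=pats)[PET_FEATURE_COLUMNS]
    pet.index.name = "patient_id"
    normal_pet = pd.DataFrame(normal_rows, index=pats)[PET_FEATURE_COLUMNS]
    normal_pet.index.name = "patient_id"
    truth = GroundTruth(latent_factors=z, true_kinetics=truth_kin, normal_pet=normal_pet)
    return tacs, pet, truth


def _split_signature(signature_genes):
    """Accept {'group1': [...], 'group2': [...]} or a flat list (16:6-style split)."""
    if isinstance(signature_genes, dict):
        g1, g2 = list(signature_genes["group1"]), list(signature_genes["group2"])
    else:
        genes = list(signature_genes)
        n1 = max(1, round(len(genes) * 16 / 22))
        n1 = min(n1, len(genes) - 1)
        g1, g2 = genes[:n1], genes[n1:]
    if not g1 or not g2:
        raise ConfigurationError("both signature groups must be non-empty")
    return g1, g2


def simulate_tcga_like(
    config: SurvivalSimConfig,
    signature_genes,
    seed: int = 0,
    n_background_genes: int = 200,
):
    """TCGA-like expression + overall-survival cohort with a planted hazard ratio.

    Normal samples express Group1 genes high and Group2 genes low. Each
    cancer sample gets independent latent High/Low states for the two
    groups; group genes are shifted +/- 1.5 log2 units around the cohort
    center accordingly, so median binarization recovers the states. Event
    times are exponential with hazard ``baseline_hazard *
    planted_hr**is_high_group2``; censoring is independent uniform on
    [0, max_followup], thinned per stratum so the realized censoring
    fraction approximates ``censor_rate``.

    Returns (expression genes x (normals + cancers), survival table for the
    cancer samples, GroundTruth with the per-sample true states).
    """
    config.validate()
    g1, g2 = _split_signature(signature_genes)
    rng = np.random.default_rng([seed, hash_stable("tcga")])
    sig = g1 + g2
    background = [f"BG{i+1:05d}" for i in range(n_background_genes)]
    genes = sig + background
    n_c, n_n = config.n_samples, config.n_normals
    normal_ids = [f"N{i+1:04d}" for i in range(n_n)]
    cancer_ids = [f"C{i+1:04d}" for i in range(n_c)]
    base = pd.Series(rng.normal(7.0, 1.0, size=len(genes)), index=genes)
    base[g1] = 9.0
    base[g2] = 5.0
    normals = base.to_numpy()[:, None] + rng.normal(0.0, 0.5, size=(len(genes), n_n))
    # shared per-sample factors give each group a coherent expression pattern
    # across normals, so correlation-distance clustering separates the groups
    u1 = rng.normal(0.0, 0.8, size=n_n)
    u2 = rng.normal(0.0, 0.8, size=n_n)
    normals[: len(g1)] += u1[None, :]
    normals[len(g1): len(sig)] += u2[None, :]
    high_g1 = rng.random(n_c) < 0.5
    high_g2 = rng.random(n_c) < 0.5
    center = 7.0
    cancers = rng.normal(0.0, 0.5, size=(len(genes), n_c)) + center
    delta = 1.5
    cancers[: len(g1)] += np.where(high_g1[None, :], delta, -delta)
    cancers[len(g1): len(sig)] += np.where(high_g2[None, :], delta, -delta)
    cancers[len(sig):] += base[background].to_numpy()[:, None] - center
    expr = pd.DataFrame(
        np.concatenate([normals, cancers], axis=1), index=genes, columns=normal_ids + cancer_ids
    )
    expr.index.name = "gene_id"
    # survival: hazard multiplied by planted_hr for the favorable High-Group2 stratum
    lam = config.baseline_hazard * np.where(high_g2, config.planted_hr, 1.0)
    T = rng.exponential(1.0 / lam)
    M = config.max_followup
    time = T.copy()
    event = np.ones(n_c, dtype=int)
    if config.censor_rate > 0:
        # P(censored | C ~ U(0,M)) per stratum; thin toward the target rate
        for is_high in (True, False):
            mask = high_g2 == is_high
            lam_s = config.baseline_hazard * (config.planted_hr if is_high else 1.0)
            r0 = (1.0 - np.exp(-lam_s * M)) / (lam_s * M)
            q = min(1.0, config.censor_rate / r0)
            has_censor = rng.random(mask.sum()) < q
            ctimes = np.where(has_censor, rng.uniform(0.0, M, size=mask.sum()), np.inf)
            idx = np.where(mask)[0]
            censored = ctimes < T[idx]
            time[idx] = np.minimum(T[idx], ctimes)
            event[idx] = (~censored).astype(int)
    surv = pd.DataFrame({"sample_id": cancer_ids, "time": time, "event": event})
    truth = GroundTruth(
        group1_genes=g1,
        group2_genes=g2,
        score_groups=pd.DataFrame(
            {"high_group1": high_g1, "high_group2": high_g2}, index=cancer_ids
        ),
    )
    return expr, surv, truth


def simulate_selection_benchmark(
    n_samples: int = 200,
    n_informative_gene: int = 7,
    n_informative_pet: int = 5,
    n_noise_modules: int = 3,
    module_size: int = 30,
    module_rho: float = 0.97,
    effect: float = 1.0,
    seed: int = 0,
):
    """Feature matrix with planted informative features for selection benchmarks.

    The informative block mimics a compact composite signature: independent
    standardized features (tagged ``gene:``/``pet:``) whose sum drives the
    cancer log-odds with ``effect`` per feature. The remaining features form
    ``n_noise_modules`` tightly co-expressed background modules (within-module
    correlation ``module_rho``, the redundancy scale of same-transcript
    microarray probe sets), unrelated to the label: an L1 path can prune a
    redundant module to at most a representative or two, which is what the
    aggregated selection frequency is meant to discard.

    Returns (features DataFrame n_samples x p, labels array of
    'cancer'/'control', informative feature names).
    """
    rng = np.random.default_rng([seed, hash_stable("selection-benchmark")])
    n_info = n_informative_gene + n_informative_pet
    info = rng.standard_normal((n_samples, n_info))
    logits = info @ np.full(n_info, float(effect))
    labels = np.where(rng.random(n_samples) < expit(logits), "cancer", "control")
    blocks = [info]
    names = [f"gene:S{i+1}" for i in range(n_informative_gene)] + [
        f"pet:S{i+1}" for i in range(n_informative_pet)
    ]
    for m in range(n_noise_modules):
        factor = rng.standard_normal(n_samples)
        mod = factor[:, None] * np.sqrt(module_rho) + np.sqrt(
            1.0 - module_rho
        ) * rng.standard_normal((n_samples, module_size))
        blocks.append(mod)
        names.extend(f"gene:M{m+1}_{j+1}" for j in range(module_size))
    X = pd.DataFrame(np.concatenate(blocks, axis=1), columns=names)
    return X, labels, names[:n_info]
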