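"""Radiogenomic integration: Spearman screening and Multiple Factor Analysis.

The Spearman screen correlates every gene with each of the 8 PET kinetic
variables over the common samples and flags pairs with |rho| above a
threshold and an asymptotic p below a threshold (raw p by design: the screen
mirrors a filtering convention, an optional BH flag is provided).

MFA standardizes every variable, down-weights each block by its leading
singular value so no single block can dominate the first axis, and runs one
global SVD on the concatenation; block contributions per dimension are sums
of squared loadings, normalized to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .exceptions import InsufficientDataError, ValidationError

__all__ = ["spearman_screen", "mfa", "MFAResult"]


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Row-wise midranks, centered and scaled to unit norm (constant rows -> nan)."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, ranks / norm, np.nan)


def spearman_screen(
    expr_cancer: pd.DataFrame,
    pet: pd.DataFrame,
    rho_thr: float = 0.6,
    p_thr: float = 0.05,
    adjust: bool = False,
    n_perm: int | None = None,
    perm_seed: int = 0,
) -> pd.DataFrame:
    """Spearman rho + asymptotic p for every (gene, PET variable) pair.

    Parameters
    ----------
    expr_cancer
        log2 expression, genes x samples.
    pet
        PET feature table, samples x variables; sample IDs must overlap
        ``expr_cancer`` columns in >= 5 samples.
    adjust
        If True, the p filter is applied to BH-adjusted p-values instead of
        raw p-values.
    n_perm
        If given, p-values come from a seeded permutation null of the sample
        order instead of the asymptotic t approximation — preferable below
        ~10 samples where the approximation is coarse.

    Returns
    -------
    Long DataFrame with columns gene, pet_variable, rho, p_value,
    passes_filter.
    """
    common = [s for s in expr_cancer.columns if s in set(pet.index)]
    n = len(common)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 common samples, got {n}")
    gx = expr_cancer[common].to_numpy(dtype=float)
    px = pet.loc[common].to_numpy(dtype=float).T  # variables x samples
    gr = _rank_standardize(gx)
    pr = _rank_standardize(px)
    const_genes = np.isnan(gr).any(axis=1)
    const_pet = np.isnan(pr).any(axis=1)
    if const_genes.any() or const_pet.any():
        warnings.warn(
            f"skipping {int(const_genes.sum())} constant genes and "
            f"{int(const_pet.sum())} constant PET variables (rho undefined)",
            stacklevel=2,
        )
    rho = gr @ pr.T  # genes x variables, nan where either side constant
    if n_perm is not None:
        perm_rng = np.random.default_rng(perm_seed)
        exceed = np.zeros_like(rho)
        for _ in range(n_perm):
            perm = perm_rng.permutation(n)
            exceed += np.abs(gr[:, perm] @ pr.T) >= np.abs(rho) - 1e-12
        p = (exceed + 1.0) / (n_perm + 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            tval = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-15))
        p = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    rows = pd.DataFrame(
        {
            "gene": np.repeat(expr_cancer.index.to_numpy(), pet.shape[1]),
            "pet_variable": np.tile(pet.columns.to_numpy(), len(expr_cancer)),
            "rho": rho.ravel(),
            "p_value": p.ravel(),
        }
    ).dropna(subset=["rho"])
    pcol = rows["p_value"].to_numpy()
    if adjust:
        pcol = bh_adjust(pcol)
        rows["adj_p"] = pcol
    rows["passes_filter"] = (np.abs(rows["rho"]) >= rho_thr) & (pcol < p_thr)
    return rows.reset_index(drop=True)


@dataclass
class MFAResult:
    """Global SVD of block-weighted standardized data."""

    eigenvalues: np.ndarray  # one per retained dimension (all of them)
    percent_variance: np.ndarray  # sums to 100 over all dimensions
    group_contribution: pd.DataFrame  # blocks x dims, each column sums to 100
    variable_coords: pd.DataFrame  # variables x dims (correlation with axis)
    sample_coords: pd.DataFrame  # samples x dims
    n_dims: int

    def summary_frame(self) -> pd.DataFrame:
        dims = [f"Dim{i+1}" for i in range(len(self.eigenvalues))]
        return pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "percent_variance": self.percent_variance},
            index=dims,
        )


def _standardize_block(block: pd.DataFrame):
    x = block.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD, FactoMineR-style
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant variables: {list(block.columns[~keep])}", stacklevel=3
        )
    return (x[:, keep] - mu[keep]) / sd[keep], list(block.columns[keep])


def mfa(blocks: dict[str, pd.DataFrame], n_dims: int = 5) -> MFAResult:
    """Multiple Factor Analysis over named variable blocks on common samples.

    Every variable is centered and scaled to unit (population) variance; each
    block is divided by its first singular value so each block's leading
    principal direction carries unit inertia; the concatenation is decomposed
    by one global SVD. Components are oriented so the largest-magnitude
    variable loading is positive.
    """
    if len(blocks) < 1 or any(b.shape[1] == 0 for b in blocks.values()):
        raise ValidationError("each block must be non-empty")
    idx = None
    for b in blocks.values():
        idx = b.index if idx is None else idx.intersection(b.index)
    if idx is None or len(idx) == 0:
        raise ValidationError("blocks share no common samples")
    n = len(idx)
    if n <= n_dims + 1:
        raise InsufficientDataError(
            f"need more than n_dims + 1 = {n_dims + 1} samples, got {n}"
        )
    mats, owners, names, block_weights = [], [], [], {}
    for label, block in blocks.items():
        z, cols = _standardize_block(block.loc[idx])
        if z.shape[1] == 0:
            raise ValidationError(f"block '{label}' has only constant variables")
        s1 = np.linalg.svd(z, compute_uv=False)[0]
        block_weights[label] = 1.0 / s1
        mats.append(z / s1)
        owners.extend([label] * z.shape[1])
        names.extend([f"{label}:{c}" for c in cols])
    X = np.concatenate(mats, axis=1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # orient: largest-|loading| positive per component
    for j in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eig = S**2
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    ndim_all = len(eig)
    dims = [f"Dim{i+1}" for i in range(ndim_all)]
    owners = np.asarray(owners)
    contrib = pd.DataFrame(
        {
            d: [100.0 * float(np.sum(Vt[j, owners == lab] ** 2)) for lab in blocks]
            for j, d in enumerate(dims)
        },
        index=list(blocks),
    )
    # variable coordinate = correlation with the component scores:
    # col_k = sum_s U_s S_s V_ks with U orthonormal, so corr = S*V / ||col_k||
    col_norms = np.linalg.norm(X, axis=0)
    var_coords = pd.DataFrame(
        (Vt.T * S[None, :]) / col_norms[:, None], index=names, columns=dims
    )
    sample_coords = pd.DataFrame(U * S[None, :], index=idx, columns=dims)
    return MFAResult(
        eigenvalues=eig,
        percent_variance=pct,
        group_contribution=contrib,
        variable_coords=var_coords,
        sample_coords=sample_coords,
        n_dims=min(n_dims, ndim_all),
    )
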