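"""Normalization, highly variable gene selection, and PCA projection.

Size factors follow the ratio-to-geometric-mean convention; gene selection
ranks a method-of-moments negative-binomial dispersion against a fitted
mean-dispersion trend; projection is PCA of gene-centered log1p-normalized
expression on the selected genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class PreprocessResult:
    size_factors: np.ndarray          # per cell; NaN for zero-total cells
    dispersion_table: pd.DataFrame    # gene, mean, dispersion, dispersion_fit, ratio
    selected_genes: list[str]
    pc_coords: np.ndarray             # cells x n_pcs
    variance_explained: np.ndarray    # fraction of total variance per PC


def size_factors(m: CountMatrix) -> np.ndarray:
    """Per-cell library size factor: total / geometric mean of totals.

    Cells with zero total get NaN and are meant to be excluded downstream.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(np.float64)
    positive = totals > 0
    if not positive.any():
        raise ValueError("all cells have zero total counts")
    geo = np.exp(np.mean(np.log(totals[positive])))
    factors = totals / geo
    factors[~positive] = np.nan
    return factors


def normalized_matrix(m: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """Dense counts divided per cell by its size factor (NaN factors -> 0)."""
    dense = m.dense()
    safe = np.where(np.isnan(factors) | (factors == 0), 1.0, factors)
    out = dense / safe[None, :]
    out[:, np.isnan(factors)] = 0.0
    return out


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Least-squares fit of dispersion ~ a + b / mean on positive dispersions."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 2:
        return np.full_like(mean, np.nanmean(disp[disp > 0]) if (disp > 0).any() else 1.0)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    fit = coef[0] + coef[1] / np.where(mean > 0, mean, np.nan)
    # the trend is a scale for ranking; keep it positive
    floor = np.nanpercentile(fit, 5) if np.isfinite(fit).any() else 1e-6
    return np.maximum(fit, max(floor, 1e-6))


def select_high_dispersion_genes(m: CountMatrix, factors: np.ndarray,
                                 n: int = 1500) -> tuple[list[str], pd.DataFrame]:
    """Top-``n`` genes by NB dispersion relative to the mean-dispersion trend.

    Dispersion is the method-of-moments estimate (var - mean) / mean^2 on
    size-factor-normalized counts.  Ties break deterministically by gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    norm = normalized_matrix(m, factors)
    keep_cells = ~np.isnan(factors)
    norm = norm[:, keep_cells]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, (var - mean) / mean**2, np.nan)
    fit = _fit_dispersion_trend(mean, np.nan_to_num(disp, nan=0.0))
    with np.errstate(invalid="ignore"):
        ratio = disp / fit
    table = pd.DataFrame({
        "gene": m.gene_ids, "mean": mean, "dispersion": disp,
        "dispersion_fit": fit, "ratio": ratio,
    })
    eligible = table.dropna(subset=["dispersion"])
    eligible = eligible[eligible["mean"] > 0]
    if n > len(eligible):
        warnings.warn(
            f"requested {n} genes but only {len(eligible)} have positive mean"
        )
        n = len(eligible)
    ranked = eligible.sort_values(
        ["ratio", "gene"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked["gene"].iloc[:n]), table


def project_cells(m: CountMatrix, genes: list[str], factors: np.ndarray,
                  n_pcs: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """PCA of log1p(normalized counts) on the selected genes.

    Returns (cells x n_pcs coordinates, per-PC fraction of total variance).
    Component signs are fixed from the gene loadings so the result is
    equivariant under cell permutation.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells for PCA")
    if n_pcs > len(genes):
        raise ValueError("n_pcs exceeds number of selected genes")
    idx = m.gene_index(genes)
    norm = normalized_matrix(m, factors)[idx, :]
    X = np.log1p(norm).T                       # cells x genes
    X = X - X.mean(axis=0, keepdims=True)      # gene-centered
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| gene coefficient positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    U, Vt = U * signs[None, :], Vt * signs[:, None]
    coords = U[:, :n_pcs] * S[:n_pcs]
    total_var = (S**2).sum()
    var_explained = (S[:n_pcs] ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    return coords, var_explained


def preprocess(m: CountMatrix, n_genes: int = 1500, n_pcs: int = 25) -> PreprocessResult:
    """Full normalization -> gene selection -> PCA pipeline stage."""
    factors = size_factors(m)
    selected, table = select_high_dispersion_genes(m, factors, n=n_genes)
    n_pcs = min(n_pcs, len(selected), m.n_cells - 1)
    coords, var_exp = project_cells(m, selected, factors, n_pcs=n_pcs)
    return PreprocessResult(
        size_factors=factors, dispersion_table=table, selected_genes=selected,
        pc_coords=coords, variance_explained=var_exp,
    )
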