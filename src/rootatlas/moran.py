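"""Cluster-specific genes via Moran's I over a gridded 2-D embedding.

The embedding's bounding box is partitioned into nbins x nbins spatial units
(rook adjacency); per-unit mean expression is tested for positive spatial
autocorrelation with a permutation Moran's I test, p-values are BH-corrected,
and genes passing I, q, and a Jensen-Shannon specificity threshold are called
specific to their argmax cell group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import bh_qvalues, specificity_score


@dataclass
class SpatialWeights:
    unit_ids: np.ndarray       # occupied (row, col) flat ids, sorted
    W: sp.csr_matrix           # symmetric 0/1 rook adjacency, zero diagonal
    cell_to_unit: np.ndarray   # per-cell index into unit_ids
    nbins: int


def grid_weights(embedding: np.ndarray, nbins: int = 25) -> SpatialWeights:
    """Rook-adjacency weights over an nbins x nbins grid of the embedding."""
    emb = np.asarray(embedding, dtype=np.float64)
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    lo = emb.min(axis=0)
    hi = emb.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    bins = np.minimum((((emb - lo) / span) * nbins).astype(int), nbins - 1)
    flat = bins[:, 0] * nbins + bins[:, 1]
    unit_ids = np.unique(flat)
    if len(unit_ids) < 2:
        raise ValueError("degenerate grid: all cells fall in one unit")
    lut = {int(u): i for i, u in enumerate(unit_ids)}
    cell_to_unit = np.array([lut[int(f)] for f in flat])
    rows, cols = [], []
    occupied = set(int(u) for u in unit_ids)
    for u in unit_ids:
        r, c = divmod(int(u), nbins)
        for dr, dc in ((1, 0), (0, 1)):  # rook neighbors, add each pair once
            rr, cc = r + dr, c + dc
            if rr < nbins and cc < nbins:
                v = rr * nbins + cc
                if v in occupied:
                    rows += [lut[int(u)], lut[v]]
                    cols += [lut[v], lut[int(u)]]
    k = len(unit_ids)
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(k, k)
    )
    return SpatialWeights(unit_ids=unit_ids, W=W, cell_to_unit=cell_to_unit,
                          nbins=nbins)


def unit_values(cell_values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Mean of per-cell values within each occupied grid unit.

    ``cell_values`` may be 1-D (one gene) or genes x cells.
    """
    x = np.atleast_2d(np.asarray(cell_values, dtype=np.float64))
    k = len(weights.unit_ids)
    counts = np.bincount(weights.cell_to_unit, minlength=k)
    sums = np.zeros((x.shape[0], k))
    for g in range(x.shape[0]):
        sums[g] = np.bincount(weights.cell_to_unit, weights=x[g], minlength=k)
    out = sums / counts[None, :]
    return out[0] if np.asarray(cell_values).ndim == 1 else out


def morans_i(values: np.ndarray, W: sp.spmatrix) -> float:
    """Moran's I statistic: (N / sum W) * (z' W z) / (z' z)."""
    z = np.asarray(values, dtype=np.float64)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined")
    s0 = W.sum()
    return float(len(z) / s0 * (z @ (W @ z)) / denom)


def morans_i_test(values: np.ndarray, W: sp.spmatrix, n_perm: int = 999,
                  seed: int = 0) -> tuple[float, float]:
    """One-sided (positive autocorrelation) permutation test for Moran's I.

    p = (#{I_perm >= I_obs} + 1) / (n_perm + 1) under random relabeling of
    unit values.
    """
    rng = np.random.default_rng(seed)
    obs = morans_i(values, W)
    z = np.asarray(values, dtype=np.float64)
    count = 0
    for _ in range(n_perm):
        count += morans_i(rng.permutation(z), W) >= obs
    return obs, (count + 1) / (n_perm + 1)


def morans_i_test_genes(value_matrix: np.ndarray, W: sp.spmatrix,
                        n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Vectorized permutation Moran's I over many genes at once.

    ``value_matrix`` is genes x units; the same unit permutations are applied
    to every gene (one draw per permutation round).  Genes with zero variance
    across units are flagged and get NaN statistics.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(value_matrix, dtype=np.float64)
    n_genes, k = X.shape
    Z = X - X.mean(axis=1, keepdims=True)
    denom = (Z**2).sum(axis=1)
    ok = denom > 0
    s0 = W.sum()
    scale = k / s0
    obs = np.full(n_genes, np.nan)
    obs[ok] = scale * np.einsum("ij,ij->i", Z[ok], (W @ Z[ok].T).T) / denom[ok]
    exceed = np.zeros(n_genes)
    for _ in range(n_perm):
        perm = rng.permutation(k)
        Zp = Z[:, perm]
        num = np.einsum("ij,ij->i", Zp, (W @ Zp.T).T)
        with np.errstate(invalid="ignore"):
            stat = scale * num / denom
        exceed[ok] += stat[ok] >= obs[ok]
    p = np.full(n_genes, np.nan)
    p[ok] = (exceed[ok] + 1) / (n_perm + 1)
    return pd.DataFrame({"I": obs, "p": p, "tested": ok})


def call_specific_genes(moran_table: pd.DataFrame, expr: np.ndarray,
                        genes: list[str], groups: np.ndarray,
                        i_min: float = 0.1, q_max: float = 0.05,
                        spec_min: float = 0.7) -> pd.DataFrame:
    """Call genes specific to their argmax group at the I/q/specificity rule.

    ``expr`` is genes x cells normalized expression on the *linear* scale
    (log-compression would flatten the group distribution); ``groups``
    per-cell labels.  Specificity compares a gene's mean expression per
    group with the indicator distribution of its best group (Jensen-Shannon
    convention).
    """
    if len(moran_table) == 0:
        raise ValueError("empty Moran results")
    labels = pd.unique(groups)
    group_means = np.stack(
        [expr[:, groups == lab].mean(axis=1) for lab in labels], axis=1
    )
    spec = np.zeros(len(genes))
    best = np.empty(len(genes), dtype=object)
    for i in range(len(genes)):
        s, arg = specificity_score(group_means[i])
        spec[i] = s
        best[i] = labels[arg]
    out = moran_table.copy()
    out.insert(0, "gene", genes)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["specificity"] = spec
    passed = (
        (out["I"] > i_min) & (out["q"] < q_max) & (out["specificity"] > spec_min)
    ).fillna(False)
    out["specific_to"] = np.where(passed, best, None)
    out["specific"] = passed.to_numpy()
    return out
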