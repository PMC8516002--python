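"""Total-mRNA trends along pseudotime and the gene-set slope permutation test.

Cells ordered by pseudotime are split into near-equal-count bins; the per-bin
median of summed gene-set counts is regressed on bin pseudotime (OLS, the
identity-link Gaussian GLM).  Significance of an observed slope comes from
re-drawing random gene sets of the same size and recording the proportion of
null slopes at least as large: p = (#{null >= observed} + 1) / (n_perm + 1),
so p is never 0 and equals 1/(n_perm + 1) when no null slope reaches the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class TotalRnaBins:
    table: pd.DataFrame  # bin, pseudotime (bin mean), median_total, sd_total, n_cells


@dataclass
class PermutationResult:
    observed_slope: float
    null_slopes: np.ndarray
    p: float
    n_perm: int
    geneset_size: int
    seed: int


def _bin_slices(n_cells: int, n_bins: int) -> list[slice]:
    """Contiguous near-equal splits (sizes differ by at most 1)."""
    edges = np.linspace(0, n_cells, n_bins + 1).round().astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(n_bins)]


def bin_total_mrna(pseudotime: np.ndarray, totals: np.ndarray,
                   n_bins: int = 20) -> TotalRnaBins:
    """Median and sd of total UMIs in equal-count pseudotime bins."""
    pseudotime = np.asarray(pseudotime, dtype=np.float64)
    totals = np.asarray(totals, dtype=np.float64)
    n = len(pseudotime)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds {n} cells")
    order = np.argsort(pseudotime, kind="stable")
    pt, tot = pseudotime[order], totals[order]
    rows = []
    for b, sl in enumerate(_bin_slices(n, n_bins)):
        chunk = tot[sl]
        sd = float(np.std(chunk, ddof=1)) if len(chunk) > 1 else 0.0
        rows.append((b, float(pt[sl].mean()), float(np.median(chunk)), sd,
                     len(chunk)))
    return TotalRnaBins(table=pd.DataFrame(
        rows, columns=["bin", "pseudotime", "median_total", "sd_total",
                       "n_cells"]
    ))


def _binned_median_slope(per_cell_sums: np.ndarray, bin_slices: list[slice],
                         x_centered: np.ndarray, sxx: float) -> np.ndarray:
    """OLS slope of per-bin medians against bin pseudotime.

    ``per_cell_sums`` may be 1-D (cells) or 2-D (draws x cells, cells already
    sorted by pseudotime); returns one slope per draw.
    """
    sums = np.atleast_2d(per_cell_sums)
    medians = np.stack([np.median(sums[:, sl], axis=1) for sl in bin_slices],
                       axis=1)
    medians = medians - medians.mean(axis=1, keepdims=True)
    return (medians @ x_centered) / sxx


def geneset_slope_permutation_test(m: CountMatrix, geneset: list[str],
                                   pseudotime: np.ndarray,
                                   n_perm: int = 10000, n_bins: int = 20,
                                   seed: int = 0,
                                   block: int = 250) -> PermutationResult:
    """Permutation test for a gene set's total-mRNA trend along pseudotime.

    Null gene sets are uniform draws (without replacement) of ``len(geneset)``
    genes from all genes in the matrix; the one-sided comparison is
    null slope >= observed slope.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = len(geneset)
    if k > m.n_genes:
        raise ValueError("gene set larger than the matrix")
    if k == 0:
        raise ValueError("empty gene set")
    pseudotime = np.asarray(pseudotime, dtype=np.float64)
    order = np.argsort(pseudotime, kind="stable")
    counts = m.dense()[:, order]
    slices = _bin_slices(m.n_cells, n_bins)
    x = np.array([pseudotime[order][sl].mean() for sl in slices])
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("pseudotime has no spread across bins")

    obs_sums = counts[m.gene_index(geneset), :].sum(axis=0)
    observed = float(_binned_median_slope(obs_sums, slices, xc, sxx)[0])

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        picks = np.stack([rng.choice(m.n_genes, size=k, replace=False)
                          for _ in range(b)])
        sums = np.stack([counts[row].sum(axis=0) for row in picks])
        null[done:done + b] = _binned_median_slope(sums, slices, xc, sxx)
        done += b
    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return PermutationResult(
        observed_slope=observed, null_slopes=null, p=float(p),
        n_perm=n_perm, geneset_size=k, seed=seed,
    )
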