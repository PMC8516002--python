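"""Cell identity assignment by rank correlation to a reference expression map.

Each cell is correlated (Spearman by default) against every (cell type,
longitudinal zone) column of a deconvolved reference map over a shared
highly-variable gene set; the argmax column names the cell.  Marker-gene
k-means signatures and pseudo-bulk vs. bulk comparisons provide independent
annotation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import CountMatrix


@dataclass
class ReferenceMap:
    """Genes x reference-column expression means.

    Each column is labeled (cell_type, zone); zone is a positive integer
    position along the root's longitudinal axis.
    """

    genes: list[str]
    columns: list[tuple[str, int]]
    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.shape != (len(self.genes), len(self.columns)):
            raise ValueError("reference dimensions inconsistent with labels")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate reference column labels")
        if any(z < 1 for _, z in self.columns):
            raise ValueError("zones must be positive integers")
        if np.any(self.means < 0):
            raise ValueError("reference means must be nonnegative")

    def column_names(self) -> list[str]:
        return [f"{t}_{z}" for t, z in self.columns]

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class IdentityAssignment:
    table: pd.DataFrame        # per cell: best_column, best_rho, second_column,
                               # second_rho, cell_type, zone, tie
    proportions: pd.Series     # fraction of assigned cells per cell type

    UNASSIGNED = "unassigned"


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def correlate_cells_to_reference(m: CountMatrix, ref: ReferenceMap,
                                 gene_subset: list[str] | None = None,
                                 method: str = "spearman",
                                 size_factors: np.ndarray | None = None,
                                 ) -> pd.DataFrame:
    """cells x reference-columns correlation matrix.

    Computed on the intersection of ``gene_subset`` (default: all matrix
    genes) with the reference genes.  Spearman uses average-tie ranks of raw
    counts (rank correlations are invariant to per-cell monotone scaling);
    Pearson uses log1p of size-factor-normalized counts.  Cells with zero
    variance over the gene set get an all-NaN row.
    """
    if gene_subset is None:
        gene_subset = list(m.gene_ids)
    ref_lut = {g: i for i, g in enumerate(ref.genes)}
    shared = [g for g in gene_subset if g in ref_lut and g in set(m.gene_ids)]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared with reference (need >= 10)"
        )
    cell_expr = m.dense()[m.gene_index(shared), :].T        # cells x genes
    ref_expr = ref.means[[ref_lut[g] for g in shared], :].T  # columns x genes

    if method == "spearman":
        a = _rank_rows(cell_expr)
        b = _rank_rows(ref_expr)
    elif method == "pearson":
        if size_factors is not None:
            safe = np.where(np.isnan(size_factors) | (size_factors == 0),
                            1.0, size_factors)
            cell_expr = cell_expr / safe[:, None]
        a = np.log1p(cell_expr)
        b = np.log1p(ref_expr)
    else:
        raise ValueError(f"unknown method: {method}")

    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a**2).sum(axis=1))
    b_sd = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (a @ b.T) / np.outer(a_sd, b_sd)
    corr[a_sd == 0, :] = np.nan  # zero-variance cell: undefined
    return pd.DataFrame(corr, index=m.barcodes, columns=ref.column_names())


def assign_identity(corr: pd.DataFrame) -> IdentityAssignment:
    """Argmax-column identity per cell with first-in-order tie-break.

    The runner-up column and correlation are recorded (used as a diagnostic
    for perturbed data sets); cells with all-NaN correlations are flagged
    unassigned but kept.
    """
    values = corr.to_numpy()
    cols = list(corr.columns)
    n = values.shape[0]
    best_col, best_rho = [], []
    second_col, second_rho, ties = [], [], []
    for i in range(n):
        row = values[i]
        if np.all(np.isnan(row)):
            best_col.append(IdentityAssignment.UNASSIGNED)
            best_rho.append(np.nan)
            second_col.append(IdentityAssignment.UNASSIGNED)
            second_rho.append(np.nan)
            ties.append(False)
            continue
        order = np.argsort(np.where(np.isnan(row), -np.inf, row), kind="stable")
        b = int(order[-1])
        # stable argsort puts the first-in-order maximum last among equals only
        # by index order; enforce the first-column-wins contract explicitly
        maxval = row[b]
        firsts = np.flatnonzero(row == maxval)
        b = int(firsts[0])
        ties.append(len(firsts) > 1)
        best_col.append(cols[b])
        best_rho.append(float(maxval))
        rest = np.where(np.isnan(row), -np.inf, row).copy()
        rest[b] = -np.inf
        s = int(np.argmax(rest))
        if np.isfinite(rest[s]):
            second_col.append(cols[s])
            second_rho.append(float(row[s]))
        else:
            second_col.append(IdentityAssignment.UNASSIGNED)
            second_rho.append(np.nan)

    table = pd.DataFrame({
        "barcode": corr.index,
        "best_column": best_col, "best_rho": best_rho,
        "second_column": second_col, "second_rho": second_rho,
        "tie": ties,
    })
    assigned = table.best_column != IdentityAssignment.UNASSIGNED
    split = table.loc[assigned, "best_column"].str.rpartition("_")
    table["cell_type"] = IdentityAssignment.UNASSIGNED
    table["zone"] = np.nan
    table.loc[assigned, "cell_type"] = split[0]
    table.loc[assigned, "zone"] = split[2].astype(float)
    props = table.loc[assigned, "cell_type"].value_counts(normalize=True)
    return IdentityAssignment(table=table, proportions=props)


def marker_signatures(m: CountMatrix, markers: pd.DataFrame, k: int = 7,
                      seed: int = 0, size_factors: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """k-means grouping of marker genes and per-cell signature means.

    ``markers`` needs columns (gene, type).  Genes are clustered on their
    standardized log1p-normalized expression profiles across cells; each cell
    then gets the mean normalized expression of each gene cluster.
    Returns (cells x k signature matrix, gene -> signature-cluster table).
    """
    present = [g for g in markers["gene"] if g in set(m.gene_ids)]
    if len(present) < k:
        raise ValueError(f"k={k} exceeds the {len(present)} markers present")
    expr = m.dense()[m.gene_index(present), :]
    if size_factors is not None:
        safe = np.where(np.isnan(size_factors) | (size_factors == 0),
                        1.0, size_factors)
        expr = expr / safe[None, :]
    logx = np.log1p(expr)
    sd = logx.std(axis=1, ddof=0)
    profiles = (logx - logx.mean(axis=1, keepdims=True)) \
        / np.where(sd > 0, sd, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
    gene_cluster = km.fit_predict(profiles) + 1
    signatures = np.stack(
        [logx[gene_cluster == c].mean(axis=0) for c in range(1, k + 1)], axis=1
    )
    gene_map = pd.DataFrame({"gene": present, "signature_cluster": gene_cluster})
    return signatures, gene_map


def pseudobulk_compare(m: CountMatrix, bulk: pd.Series) -> tuple[float, float]:
    """(R^2, Spearman rho) between log pseudo-bulk and log bulk expression.

    Pseudo-bulk is the per-gene sum over all cells; both vectors are log(x+1)
    transformed over the shared gene set.
    """
    shared = [g for g in m.gene_ids if g in bulk.index]
    if len(shared) < 10:
        raise ValueError("fewer than 10 genes shared with bulk table")
    pseudo = np.log1p(
        np.asarray(m.values[m.gene_index(shared), :].sum(axis=1)).ravel()
    )
    bulk_v = np.log1p(bulk.loc[shared].to_numpy(dtype=np.float64))
    r = stats.pearsonr(pseudo, bulk_v).statistic
    rho = stats.spearmanr(pseudo, bulk_v).statistic
    return float(r**2), float(rho)
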