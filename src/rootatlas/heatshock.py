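"""Control/treated alignment, negative-binomial differential expression, and
heat-shock response summaries.

Differential expression per gene is a likelihood-ratio test between nested
negative-binomial GLMs (log link, library size-factor offset); the per-gene
dispersion is estimated by maximum likelihood at the full-model means and
then held fixed in both fits.  Per-cluster tests are BH-corrected jointly
across all gene x cluster tests, significant-call overlaps are summarized
upset-style, and responsive genes are grouped into k signature clusters by
Ward hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.neighbors import NearestNeighbors

from ._stats import bh_qvalues
from .io import CountMatrix
from .preprocess import size_factors as compute_size_factors

DISPERSION_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# MNN alignment

def _mnn_pairs(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn_ab = NearestNeighbors(n_neighbors=k).fit(b)
    _, nbr_a = nn_ab.kneighbors(a)          # for each control: treated nbrs
    nn_ba = NearestNeighbors(n_neighbors=k).fit(a)
    _, nbr_b = nn_ba.kneighbors(b)          # for each treated: control nbrs
    b_sets = [set(row) for row in nbr_b]
    pairs = [(i, j) for i in range(len(a)) for j in nbr_a[i] if i in b_sets[j]]
    if not pairs:
        raise ValueError("no mutual nearest-neighbor pairs; increase k_mnn")
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


def mnn_align(coords_control: np.ndarray, coords_treated: np.ndarray,
              k_mnn: int = 20, sigma: float | None = None,
              max_iter: int = 10, tol: float = 1e-3
              ) -> tuple[np.ndarray, np.ndarray]:
    """Remove the treatment-wide embedding shift via mutual nearest neighbors.

    Mutual nearest-neighbor pairs across conditions define correction
    vectors (control - treated); every treated cell is shifted by a
    Gaussian-kernel weighted average of pair vectors (bandwidth ``sigma``,
    default: median distance from treated cells to paired treated cells).
    Nearest-neighbor pairing cannot see a translation of the whole cloud
    (matches simply shift index-wise), so the global mean offset between
    conditions is removed first as initialization; the MNN kernel pass then
    corrects local, non-constant distortions and is iterated until the mean
    residual correction is below ``tol`` times the data scale.  Control
    cells are returned unchanged.
    """
    a = np.asarray(coords_control, dtype=np.float64)
    b = np.asarray(coords_treated, dtype=np.float64).copy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both conditions need cells")
    k = min(k_mnn, len(a), len(b))
    if k < 1:
        raise ValueError("k_mnn must be >= 1")
    scale = max(float(np.linalg.norm(a.std(axis=0))), 1e-12)
    b = b + (a.mean(axis=0) - b.mean(axis=0))
    for _ in range(max_iter):
        pa, pb = _mnn_pairs(a, b, k)
        vectors = a[pa] - b[pb]
        anchors = b[pb]
        d2 = ((b[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        # bandwidth from the pair mismatch scale: near-zero when conditions
        # already coincide, so matched data receives (almost) no correction
        norms = np.linalg.norm(vectors, axis=1)
        s = sigma if sigma is not None else float(np.median(norms))
        if s <= 0:
            correction = np.zeros_like(b)
        else:
            # down-weight long pair vectors: tight pairs are the trustworthy
            # correspondences, loose ones are boundary mismatches
            w = np.exp(-d2 / (2 * s**2)) * np.exp(-norms[None, :] ** 2 / (2 * s**2))
            w_sum = w.sum(axis=1, keepdims=True)
            w = np.where(w_sum > 0, w / w_sum, 0.0)
            correction = w @ vectors
        # the kernel pass corrects local distortion only; the global
        # translation between conditions is owned by the centroid step
        correction = correction - correction.mean(axis=0)
        b = b + correction
        if float(np.linalg.norm(correction, axis=1).mean()) < tol * scale:
            break
    return a.copy(), b


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    size = 1.0 / alpha
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def estimate_dispersion(y: np.ndarray, mu: np.ndarray,
                        floor: float = DISPERSION_FLOOR) -> float:
    """ML estimate of the NB dispersion alpha (var = mu + alpha mu^2)."""
    if np.all(y == 0):
        return floor
    res = optimize.minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(np.log(floor), np.log(1e3)), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(max(np.exp(res.x), floor))


def nb_glm_lrt(counts: np.ndarray, design_full: np.ndarray,
               design_reduced: np.ndarray,
               offset: np.ndarray | None = None) -> tuple[float, float]:
    """Likelihood-ratio test between nested NB GLMs for one gene.

    Returns (p, dispersion).  ``offset`` is log(size factor) per cell.
    Non-convergence yields p = NaN.
    """
    y = np.asarray(counts, dtype=np.float64)
    df_diff = design_full.shape[1] - design_reduced.shape[1]
    if df_diff <= 0:
        return 1.0, DISPERSION_FLOOR
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, design_full, family=sm.families.Poisson(),
                          offset=offset).fit()
            alpha = estimate_dispersion(y, pois.mu)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(y, design_full, family=fam, offset=offset).fit()
            red = sm.GLM(y, design_reduced, family=fam, offset=offset).fit()
        stat = 2 * (full.llf - red.llf)
        if not np.isfinite(stat):
            return np.nan, alpha
        p = float(stats.chi2.sf(max(stat, 0.0), df_diff))
        return p, alpha
    except Exception:
        return np.nan, np.nan


def de_test(m: CountMatrix, covariates: pd.DataFrame, full_terms: list[str],
            reduced_terms: list[str],
            size_fac: np.ndarray | None = None,
            genes: list[str] | None = None) -> pd.DataFrame:
    """NB-LRT differential expression over a gene set.

    ``covariates`` holds per-cell factors (e.g. treatment, cluster); terms
    are column names, "1" denotes the intercept-only model, and "a*b" adds
    the interaction of two factors.
    """
    if size_fac is None:
        size_fac = compute_size_factors(m)
    keep = ~np.isnan(size_fac)
    offset = np.log(size_fac[keep])

    def build(terms: list[str]) -> np.ndarray:
        cols = [np.ones((int(keep.sum()), 1))]
        for t in terms:
            if t == "1":
                continue
            if "*" in t:
                t1, t2 = t.split("*")
                d1 = pd.get_dummies(covariates.loc[keep, t1], drop_first=True)
                d2 = pd.get_dummies(covariates.loc[keep, t2], drop_first=True)
                cols.append(d1.to_numpy(float))
                cols.append(d2.to_numpy(float))
                inter = np.einsum("ij,ik->ijk", d1.to_numpy(float),
                                  d2.to_numpy(float))
                cols.append(inter.reshape(inter.shape[0], -1))
            else:
                cols.append(
                    pd.get_dummies(covariates.loc[keep, t], drop_first=True)
                    .to_numpy(float)
                )
        X = np.unique(np.hstack(cols), axis=1) if len(cols) > 1 \
            else np.hstack(cols)
        return X

    X_full = build(full_terms)
    X_red = build(reduced_terms)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("full design matrix is rank deficient")

    if genes is None:
        genes = list(m.gene_ids)
    dense = m.dense()[:, keep]
    idx = m.gene_index(genes)
    rows = []
    for g, gi in zip(genes, idx):
        p, alpha = nb_glm_lrt(dense[gi], X_full, X_red, offset=offset)
        rows.append((g, p, alpha))
    return pd.DataFrame(rows, columns=["gene", "p", "dispersion"])


def log2_fold_change(m: CountMatrix, mask_treated: np.ndarray,
                     size_fac: np.ndarray) -> np.ndarray:
    """log2 of (treated + 1) / (control + 1) mean normalized expression."""
    safe = np.where(np.isnan(size_fac) | (size_fac == 0), 1.0, size_fac)
    norm = m.dense() / safe[None, :]
    norm[:, np.isnan(size_fac)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mt = np.nanmean(norm[:, mask_treated], axis=1)
        mc = np.nanmean(norm[:, ~mask_treated], axis=1)
    return np.log2((mt + 1) / (mc + 1))


# ---------------------------------------------------------------------------
# per-cluster DE and upset summaries

@dataclass
class PerClusterDE:
    table: pd.DataFrame            # gene, cluster, p, dispersion, lfc, fdr, significant
    skipped_clusters: list
    intersections: pd.DataFrame    # clusters (frozenset as sorted tuple), count


def per_cluster_de(control: CountMatrix, treated: CountMatrix,
                   cluster_labels: np.ndarray, min_cells: int = 15,
                   fdr_max: float = 0.001, lfc_min: float = 1.0,
                   genes: list[str] | None = None) -> PerClusterDE:
    """Treatment DE within every cluster populated by both conditions.

    ``cluster_labels`` covers the concatenated (control then treated) cells.
    Clusters with fewer than ``min_cells`` cells in either arm are skipped
    and recorded.  FDR is BH across all gene x cluster tests; significance
    requires FDR < ``fdr_max`` and |log2 fold change| > ``lfc_min``.
    """
    if control.gene_ids != treated.gene_ids:
        raise ValueError("control and treated matrices must share genes")
    combined = CountMatrix(
        sp.hstack([control.values, treated.values]).tocsr(),
        list(control.gene_ids),
        [f"c_{b}" for b in control.barcodes] + [f"t_{b}" for b in treated.barcodes],
    )
    treated_mask = np.zeros(combined.n_cells, dtype=bool)
    treated_mask[control.n_cells:] = True
    labels = np.asarray(cluster_labels)
    if len(labels) != combined.n_cells:
        raise ValueError("cluster labels must cover all cells")
    size_fac = compute_size_factors(combined)

    eligible, skipped = [], []
    for lab in pd.unique(labels):
        n_c = int(((labels == lab) & ~treated_mask).sum())
        n_t = int(((labels == lab) & treated_mask).sum())
        if n_c >= min_cells and n_t >= min_cells:
            eligible.append(lab)
        else:
            skipped.append(lab)
    if not eligible:
        raise ValueError("no cluster has enough cells in both conditions")

    frames = []
    for lab in eligible:
        in_cluster = labels == lab
        sub = combined.subset_cells(in_cluster)
        cov = pd.DataFrame({"treatment": np.where(
            treated_mask[in_cluster], "heat", "control")})
        sf = size_fac[in_cluster]
        res = de_test(sub, cov, ["treatment"], ["1"], size_fac=sf, genes=genes)
        res["cluster"] = lab
        res["lfc"] = log2_fold_change(sub, treated_mask[in_cluster], sf)[
            sub.gene_index(res["gene"])]
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    table["fdr"] = bh_qvalues(table["p"].to_numpy())
    table["significant"] = (
        (table["fdr"] < fdr_max) & (table["lfc"].abs() > lfc_min)
    ).fillna(False)

    sig = table[table.significant]
    combos: dict[tuple, int] = {}
    for _, grp in sig.groupby("gene"):
        key = tuple(sorted(map(str, grp["cluster"])))
        combos[key] = combos.get(key, 0) + 1
    inter = pd.DataFrame(
        sorted(combos.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["clusters", "count"],
    )
    return PerClusterDE(table=table, skipped_clusters=skipped,
                        intersections=inter)


# ---------------------------------------------------------------------------
# gene signature clustering

@dataclass
class SignatureSet:
    gene_clusters: pd.DataFrame    # gene, signature_cluster
    cell_signatures: np.ndarray    # cells x k mean log-normalized expression


def gene_cluster_signatures(m: CountMatrix, gene_list: list[str], k: int = 8,
                            size_fac: np.ndarray | None = None) -> SignatureSet:
    """Ward (ward.D2-equivalent) clustering of response genes into k groups.

    Genes are clustered on standardized log1p-normalized expression profiles;
    each cell then receives the mean log-normalized expression of every
    group.  Genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in gene_list if g in set(m.gene_ids)]
    dropped = len(gene_list) - len(present)
    if dropped:
        warnings.warn(f"{dropped} genes absent from matrix were dropped")
    if k > len(present):
        raise ValueError(f"k={k} exceeds the {len(present)} genes available")
    if size_fac is None:
        size_fac = compute_size_factors(m)
    safe = np.where(np.isnan(size_fac) | (size_fac == 0), 1.0, size_fac)
    logx = np.log1p(m.dense()[m.gene_index(present), :] / safe[None, :])
    sd = logx.std(axis=1, ddof=0)
    profiles = (logx - logx.mean(axis=1, keepdims=True)) \
        / np.where(sd > 0, sd, 1.0)[:, None]
    if len(present) == 1:
        assignments = np.array([1])
    else:
        Z = linkage(profiles, method="ward")
        assignments = fcluster(Z, t=k, criterion="maxclust")
    signatures = np.stack(
        [logx[assignments == c].mean(axis=0) if (assignments == c).any()
         else np.zeros(m.n_cells) for c in range(1, k + 1)],
        axis=1,
    )
    return SignatureSet(
        gene_clusters=pd.DataFrame(
            {"gene": present, "signature_cluster": assignments}),
        cell_signatures=signatures,
    )
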