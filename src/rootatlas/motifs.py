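"""Promoter extraction, PWM scanning with exact match p-values, and motif
set enrichment.

Match significance uses the classical exact approach: per-position log-odds
scores (motif vs. background) are discretized to a fixed lattice and the
score distribution under the background model is built by dynamic-programming
convolution, giving the exact tail probability of every achievable score.
Hits are emitted where the match p-value is at or below the cutoff, on both
strands by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MotifModel
from .simulate import reverse_complement

SCORE_LATTICE = 0.01  # log2-odds units per lattice step

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ScoreDistribution:
    """Discretized background distribution of a motif's match score."""

    int_scores: np.ndarray        # L x 4 lattice scores; minimal int for -inf
    offset: int                   # lattice value of probs[0]
    sf: np.ndarray                # sf[i] = P(score >= offset + i)
    neg_inf: np.ndarray           # L x 4 mask of zero-probability bases

    def pvalue(self, total_int: int) -> float:
        i = total_int - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.sf):
            return 0.0
        return float(self.sf[i])

    def threshold(self, p_cutoff: float) -> int:
        """Smallest lattice score whose tail probability is <= p_cutoff."""
        idx = np.searchsorted(-self.sf, -p_cutoff, side="left")
        return self.offset + int(idx)


def score_distribution(motif: MotifModel,
                       lattice: float = SCORE_LATTICE) -> ScoreDistribution:
    """Exact DP convolution of per-position score distributions."""
    probs = motif.matrix
    bg = motif.background
    with np.errstate(divide="ignore"):
        lod = np.log2(probs / bg[None, :])
    neg_inf = probs == 0
    ints = np.zeros(probs.shape, dtype=np.int64)
    ints[~neg_inf] = np.round(lod[~neg_inf] / lattice).astype(np.int64)

    # DP over positions; dist indexed by (score - running_lo)
    dist = np.array([1.0])
    cur_lo = 0
    for i in range(probs.shape[0]):
        row_scores = ints[i][~neg_inf[i]]
        row_probs = bg[~neg_inf[i]]
        new_lo = cur_lo + int(row_scores.min())
        new_hi = cur_lo + len(dist) - 1 + int(row_scores.max())
        new = np.zeros(new_hi - new_lo + 1)
        for s, pr in zip(row_scores, row_probs):
            start = cur_lo + int(s) - new_lo
            new[start:start + len(dist)] += dist * pr
        dist, cur_lo = new, new_lo
    sf = np.cumsum(dist[::-1])[::-1]
    ints[neg_inf] = np.iinfo(np.int32).min // probs.shape[0]
    return ScoreDistribution(int_scores=ints, offset=cur_lo, sf=sf,
                             neg_inf=neg_inf)


def _scan_one_strand(seq_idx: np.ndarray, valid: np.ndarray,
                     dist: ScoreDistribution, p_cutoff: float,
                     lattice: float) -> list[tuple[int, float, float]]:
    L = dist.int_scores.shape[0]
    n = len(seq_idx)
    if n < L:
        return []
    thr = dist.threshold(p_cutoff)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, L)
    totals = dist.int_scores[np.arange(L)[None, :], windows].sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    hits = []
    for pos in np.flatnonzero(ok & (totals >= thr)):
        total = int(totals[pos])
        hits.append((int(pos), total * lattice, dist.pvalue(total)))
    return hits


def _rc_motif(motif: MotifModel) -> MotifModel:
    return MotifModel(id=motif.id, matrix=motif.matrix[::-1, ::-1].copy(),
                      background=motif.background.copy())


def pwm_scan(seq: str, motif: MotifModel, p_cutoff: float = 1e-5,
             both_strands: bool = True,
             lattice: float = SCORE_LATTICE) -> pd.DataFrame:
    """Scan a sequence for motif matches at an exact p-value cutoff.

    Positions are 0-based on the given (forward) sequence and always satisfy
    position + motif length <= sequence length; minus-strand hits report the
    leftmost forward coordinate of the matched window.
    """
    seq = seq.upper()
    L = len(motif)
    cols = ["position", "strand", "score", "p"]
    if L > len(seq):
        return pd.DataFrame(columns=cols)
    seq_idx = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    valid = seq_idx >= 0
    seq_idx = np.where(valid, seq_idx, 0)

    records = []
    dist_fwd = score_distribution(motif, lattice)
    for pos, score, p in _scan_one_strand(seq_idx, valid, dist_fwd,
                                          p_cutoff, lattice):
        records.append((pos, "+", score, p))
    if both_strands:
        dist_rev = score_distribution(_rc_motif(motif), lattice)
        for pos, score, p in _scan_one_strand(seq_idx, valid, dist_rev,
                                              p_cutoff, lattice):
            records.append((pos, "-", score, p))
    out = pd.DataFrame(records, columns=cols)
    return out.sort_values(["position", "strand"]).reset_index(drop=True)


def scan_promoters(promoters: dict[str, str], motifs: list[MotifModel],
                   p_cutoff: float = 1e-5,
                   both_strands: bool = True) -> pd.DataFrame:
    """All motif hits across a promoter set (columns: gene, motif, ...)."""
    frames = []
    for motif in motifs:
        for gene, seq in promoters.items():
            hits = pwm_scan(seq, motif, p_cutoff, both_strands)
            if len(hits):
                hits.insert(0, "motif", motif.id)
                hits.insert(0, "gene", gene)
                frames.append(hits)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "motif", "position", "strand", "score", "p"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# promoter extraction

def extract_promoters(gene_table: pd.DataFrame, genome: dict[str, str],
                      length: int = 500,
                      one_based: bool = True) -> dict[str, str]:
    """Promoters: ``length`` bases upstream of each gene's start site.

    ``gene_table`` needs columns (chrom, start, end, strand, id); coordinates
    are 1-based inclusive by default and converted internally to 0-based
    half-open.  Plus-strand promoters end immediately before the start;
    minus-strand promoters are the reverse complement of the window after the
    gene end.  Windows clipped by a chromosome edge are truncated with a
    warning.
    """
    unknown = sorted(set(gene_table["chrom"]) - set(genome))
    if unknown:
        raise ValueError(f"unknown chromosomes: {unknown}")
    out: dict[str, str] = {}
    truncated = []
    for row in gene_table.itertuples(index=False):
        seq = genome[row.chrom]
        start0 = int(row.start) - 1 if one_based else int(row.start)
        end0 = int(row.end) if one_based else int(row.end)
        if row.strand == "+":
            lo = max(0, start0 - length)
            prom = seq[lo:start0]
            if start0 - length < 0:
                truncated.append(row.id)
        else:
            hi = min(len(seq), end0 + length)
            prom = reverse_complement(seq[end0:hi])
            if end0 + length > len(seq):
                truncated.append(row.id)
        out[str(row.id)] = prom.upper()
    if truncated:
        warnings.warn(f"{len(truncated)} promoters truncated at chromosome "
                      f"edges: {truncated[:5]}")
    return out


# ---------------------------------------------------------------------------
# enrichment

def set_enrichment(hits: pd.DataFrame, gene_sets: dict[str, list[str]],
                   all_genes: list[str]) -> pd.DataFrame:
    """Per-motif, per-set promoter hit frequencies and log2 enrichment.

    Frequency counts promoters containing >= 1 hit.  Enrichment is
    log2((f_set + eps) / (f_background + eps)) with eps = 1/(2 n_promoters),
    keeping absent motifs finite (and exactly 0 when absent everywhere).
    """
    n_prom = len(all_genes)
    if n_prom == 0:
        raise ValueError("no scanned promoters")
    eps = 1.0 / (2 * n_prom)
    motifs = sorted(hits["motif"].unique()) if len(hits) else []
    hit_genes = {
        m: set(hits.loc[hits.motif == m, "gene"]) for m in motifs
    }
    records = []
    all_set = set(all_genes)
    for set_name, members in gene_sets.items():
        members = [g for g in members if g in all_set]
        if not members:
            warnings.warn(f"gene set {set_name} has no scanned promoters")
            for m in motifs:
                records.append((m, set_name, np.nan, np.nan, np.nan))
            continue
        for m in motifs:
            f_set = sum(g in hit_genes[m] for g in members) / len(members)
            f_bg = len(hit_genes[m] & all_set) / n_prom
            enr = np.log2((f_set + eps) / (f_bg + eps))
            records.append((m, set_name, f_set, f_bg, enr))
    return pd.DataFrame(
        records,
        columns=["motif", "set", "freq_set", "freq_background",
                 "log2_enrichment"],
    )


def early_late_calls(freq_early: pd.Series, freq_late: pd.Series,
                     sd_mult: float = 1.5) -> pd.Series:
    """Call motifs early/late by the mean + sd_mult * sd frequency rule.

    A motif is "early" when its early-cell frequency exceeds the mean early
    frequency over motifs by ``sd_mult`` standard deviations and beats its
    late frequency; symmetrically for "late"; otherwise "none".
    """
    if not freq_early.index.equals(freq_late.index):
        raise ValueError("early/late frequencies must cover the same motifs")
    if len(freq_early) < 3:
        raise ValueError("need >= 3 motifs for a stable sd threshold")
    fe, fl = freq_early.to_numpy(float), freq_late.to_numpy(float)
    thr_e = fe.mean() + sd_mult * fe.std(ddof=1)
    thr_l = fl.mean() + sd_mult * fl.std(ddof=1)
    calls = np.where(
        (fe > thr_e) & (fe > fl), "early",
        np.where((fl > thr_l) & (fl > fe), "late", "none"),
    )
    return pd.Series(calls, index=freq_early.index, name="call")


def aggregate_families(enrichment: pd.DataFrame,
                       family_map: dict[str, str]) -> pd.DataFrame:
    """Max log2 enrichment per transcription-factor family and gene set."""
    df = enrichment.assign(
        family=enrichment["motif"].map(lambda m: family_map.get(m, m))
    )
    return (
        df.groupby(["family", "set"], as_index=False)["log2_enrichment"].max()
    )
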