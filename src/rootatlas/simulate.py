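"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of a root single-cell atlas: a handful of
cell types, each traversing a smooth developmental gradient (longitudinal
zones), with type-specific marker genes, stage-graded genes, negative-binomial
UMI counts under variable library sizes, one designated hair-like lineage
whose total mRNA declines across stages, a heat-shock condition that switches
on a shared stress program while repressing markers, and promoters with
planted transcription-factor motifs.

Everything is deterministic given (config, seed): the same configuration
always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import ReferenceMap
from .io import CountMatrix, MotifModel

DEFAULT_TYPE_NAMES = ["hair", "nonhair", "cortex", "endodermis", "stele"]

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic atlas.

    Folds are multiplicative and must be >= 1; ``nb_dispersion`` is the NB
    size parameter (mean/size convention), shared across genes; ``np.inf``
    gives Poisson counts.  The first cell type is the designated hair-like
    lineage: it carries the total-mRNA decay and the largest marker program.
    """

    n_types: int = 5
    n_stages: int = 4
    n_genes: int = 5000
    markers_per_type: int = 50
    stage_genes_per_type: int = 40
    n_cells: int = 2000
    nb_dispersion: float = 2.0
    libsize_lognormal_sigma: float = 0.3
    marker_fold: float = 8.0
    stage_gradient_fold: float = 4.0
    mrna_decay_fold: float = 4.0
    hs_program_size: int = 100
    hs_up_fold: float = 8.0
    marker_down_fold: float = 4.0
    motif_plant_rate: float = 0.8
    promoter_length: int = 500
    base_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "n_stages", "n_genes", "markers_per_type",
                     "stage_genes_per_type"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        for name in ("marker_fold", "stage_gradient_fold", "mrna_decay_fold",
                     "hs_up_fold", "marker_down_fold"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ConfigurationError("motif_plant_rate must be in [0, 1]")
        if self.libsize_lognormal_sigma < 0:
            raise ConfigurationError("libsize_lognormal_sigma must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        n_planted = (self.markers_per_type + self.stage_genes_per_type) \
            * self.n_types + self.hs_program_size
        if n_planted > self.n_genes:
            raise ConfigurationError(
                f"{n_planted} planted genes exceed n_genes={self.n_genes}"
            )

    def type_names(self) -> list[str]:
        names = list(DEFAULT_TYPE_NAMES[: self.n_types])
        names += [f"type{i}" for i in range(len(names), self.n_types)]
        return names

    @property
    def lineage(self) -> str:
        """Name of the designated hair-like lineage."""
        return self.type_names()[0]


@dataclass
class GroundTruth:
    """True labels behind a simulated data set.

    ``cells`` has one row per cell (barcode, true_type, true_stage,
    treatment); ``genes`` one row per gene (gene, role, type), with role in
    {marker, stage-gradient, hs-program, background} and disjoint role sets.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    planted_motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "motif", "offset", "strand"]
        )
    )

    def markers_of(self, cell_type: str) -> list[str]:
        g = self.genes
        return list(g.loc[(g.role == "marker") & (g.type == cell_type), "gene"])

    def genes_with_role(self, role: str, cell_type: str | None = None) -> list[str]:
        g = self.genes
        mask = g.role == role
        if cell_type is not None:
            mask &= g.type == cell_type
        return list(g.loc[mask, "gene"])


class ReferenceSim(NamedTuple):
    reference: ReferenceMap
    gene_roles: pd.DataFrame
    markers: pd.DataFrame  # columns: gene, type


def simulate_reference_map(config: SimConfig) -> ReferenceSim:
    """Build a genes x (type, stage) matrix of expression means.

    Per-gene baselines are lognormal.  Marker genes of type t have exactly
    ``marker_fold`` x their baseline in every column of t; stage-gradient
    genes of type t rise geometrically from baseline at stage 1 to
    ``stage_gradient_fold`` x baseline at the last stage.
    """
    rng = np.random.default_rng(config.seed)
    G, T, S = config.n_genes, config.n_types, config.n_stages
    genes = [f"G{i:05d}" for i in range(G)]
    types = config.type_names()

    baseline = config.base_mean * rng.lognormal(0.0, 0.75, size=G)

    roles = np.full(G, "background", dtype=object)
    role_type = np.full(G, "", dtype=object)
    cursor = 0
    for t in range(T):
        idx = slice(cursor, cursor + config.markers_per_type)
        roles[idx], role_type[idx] = "marker", types[t]
        cursor += config.markers_per_type
    for t in range(T):
        idx = slice(cursor, cursor + config.stage_genes_per_type)
        roles[idx], role_type[idx] = "stage-gradient", types[t]
        cursor += config.stage_genes_per_type
    idx = slice(cursor, cursor + config.hs_program_size)
    roles[idx], role_type[idx] = "hs-program", "all"

    means = np.tile(baseline[:, None], (1, T * S))
    if S > 1:
        grad = config.stage_gradient_fold ** (np.arange(S) / (S - 1))
    else:
        grad = np.ones(1)
    for t, tname in enumerate(types):
        cols = slice(t * S, (t + 1) * S)
        marker_rows = (roles == "marker") & (role_type == tname)
        means[marker_rows, cols] *= config.marker_fold
        stage_rows = (roles == "stage-gradient") & (role_type == tname)
        means[np.ix_(np.flatnonzero(stage_rows), np.arange(t * S, (t + 1) * S))] \
            *= grad[None, :]

    columns = [(tname, s + 1) for tname in types for s in range(S)]
    ref = ReferenceMap(genes=genes, columns=columns, means=means)
    gene_roles = pd.DataFrame({"gene": genes, "role": roles, "type": role_type})
    markers = gene_roles.loc[gene_roles.role == "marker", ["gene", "type"]]
    return ReferenceSim(ref, gene_roles, markers.reset_index(drop=True))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    if np.isinf(size_param):
        return rng.poisson(mu)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _draw_cells(config: SimConfig, ref: ReferenceMap, rng: np.random.Generator,
                means_override: np.ndarray | None = None,
                barcode_prefix: str = "cell") -> tuple[CountMatrix, pd.DataFrame]:
    means = ref.means if means_override is None else means_override
    S = config.n_stages
    types = config.type_names()
    n = config.n_cells
    type_idx = rng.integers(0, config.n_types, size=n)
    stage_idx = rng.integers(0, S, size=n)  # 0-based
    lib = rng.lognormal(0.0, config.libsize_lognormal_sigma, size=n)
    if S > 1:
        decay = config.mrna_decay_fold ** (-(stage_idx / (S - 1)))
    else:
        decay = np.ones(n)
    decay = np.where(type_idx == 0, decay, 1.0)  # only the hair-like lineage

    counts = np.zeros((config.n_genes, n), dtype=np.int64)
    for c in range(n):
        col = means[:, type_idx[c] * S + stage_idx[c]] * lib[c] * decay[c]
        counts[:, c] = _nb_draw(rng, col, config.nb_dispersion)

    barcodes = [f"{barcode_prefix}{i:05d}" for i in range(n)]
    cells = pd.DataFrame({
        "barcode": barcodes,
        "true_type": [types[t] for t in type_idx],
        "true_stage": stage_idx + 1,
        "treatment": "control",
    })
    matrix = CountMatrix(sp.csr_matrix(counts), list(ref.genes), barcodes)
    return matrix, cells


def simulate_cells(config: SimConfig, ref_sim: ReferenceSim) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB-distributed UMI counts for ``n_cells`` cells.

    Each cell picks a (type, stage) uniformly, scales its reference column by
    a lognormal library factor and — in the hair-like lineage — by the
    stage-dependent total-mRNA decay, then draws NB counts per gene.
    """
    rng = np.random.default_rng(config.seed + 1)
    matrix, cells = _draw_cells(config, ref_sim.reference, rng)
    return matrix, GroundTruth(cells=cells, genes=ref_sim.gene_roles)


def heat_shock_means(config: SimConfig, ref_sim: ReferenceSim,
                     type_restricted: dict[str, tuple[str, float]] | None = None
                     ) -> np.ndarray:
    """Reference means under heat shock: stress program up, markers down.

    ``type_restricted`` maps gene id -> (cell type, fold) for perturbations
    confined to one type (used to plant cluster x treatment interactions).
    """
    ref = ref_sim.reference
    roles = ref_sim.gene_roles
    means = ref.means.copy()
    hs_rows = (roles.role == "hs-program").to_numpy()
    means[hs_rows, :] *= config.hs_up_fold
    marker_rows = (roles.role == "marker").to_numpy()
    means[marker_rows, :] /= config.marker_down_fold
    if type_restricted:
        S = config.n_stages
        types = config.type_names()
        gene_lut = {g: i for i, g in enumerate(ref.genes)}
        for gene, (ctype, fold) in type_restricted.items():
            t = types.index(ctype)
            means[gene_lut[gene], t * S:(t + 1) * S] *= fold
    return means


def simulate_heat_shock(config: SimConfig, ref_sim: ReferenceSim,
                        base: tuple[CountMatrix, GroundTruth],
                        type_restricted: dict[str, tuple[str, float]] | None = None,
                        ) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Paired (control, treated) matrices plus combined ground truth.

    Control cells are the ``base`` draw, untouched.  Treated cells are a
    fresh cohort drawn from the heat-shock means.
    """
    control, truth = base
    rng = np.random.default_rng(config.seed + 2)
    hs_means = heat_shock_means(config, ref_sim, type_restricted)
    treated, treated_cells = _draw_cells(
        config, ref_sim.reference, rng, means_override=hs_means,
        barcode_prefix="heat",
    )
    treated_cells = treated_cells.assign(treatment="heat")
    combined = pd.concat([truth.cells, treated_cells], ignore_index=True)
    return control, treated, GroundTruth(
        cells=combined, genes=truth.genes, planted_motifs=truth.planted_motifs
    )


def random_motifs(n: int, length: int = 8, sharpness: float = 0.85,
                  seed: int = 0) -> list[MotifModel]:
    """Informative random PWMs: one preferred base per position."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pref = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), (1 - sharpness) / 3)
        mat[np.arange(length), pref] = sharpness
        out.append(MotifModel(id=f"M{i:03d}", matrix=mat))
    return out


def simulate_promoters(config: SimConfig, gene_ids: list[str],
                       gene_sets: dict[str, list[str]],
                       motif_for_set: dict[str, MotifModel],
                       rate_for_set: dict[str, float] | None = None,
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background promoters with motif consensus planted in gene sets.

    Every gene in ``gene_ids`` gets a ``promoter_length`` i.i.d. A/C/G/T
    sequence.  For each named set, each member promoter independently
    receives the set's motif consensus with probability ``motif_plant_rate``
    (overridable per set via ``rate_for_set``), at a uniform position and
    strand.  Returns (promoters, plant records).
    """
    L = config.promoter_length
    for m in motif_for_set.values():
        if len(m) > L:
            raise ConfigurationError(
                f"motif {m.id} (len {len(m)}) longer than promoter ({L})"
            )
    rng = np.random.default_rng(config.seed + 3)
    promoters = {
        g: "".join(BASES[rng.integers(0, 4, size=L)]) for g in gene_ids
    }
    records = []
    rate_for_set = rate_for_set or {}
    for set_name in sorted(gene_sets):
        motif = motif_for_set[set_name]
        cons = motif.consensus
        rate = rate_for_set.get(set_name, config.motif_plant_rate)
        for g in gene_sets[set_name]:
            if g not in promoters:
                raise ConfigurationError(f"gene {g} has no promoter")
            if rng.random() >= rate:
                continue
            pos = int(rng.integers(0, L - len(cons) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = cons if strand == "+" else reverse_complement(cons)
            s = promoters[g]
            promoters[g] = s[:pos] + insert + s[pos + len(insert):]
            records.append((g, motif.id, pos, strand))
    plants = pd.DataFrame(records, columns=["gene", "motif", "offset", "strand"])
    return promoters, plants
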