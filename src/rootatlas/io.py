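"""Readers and writers for the formats the pipeline touches.

Count matrices use the CellRanger-style layout: a MatrixMarket coordinate
file ``matrix.mtx`` (genes x cells, integer UMI counts) next to ``genes.tsv``
and ``barcodes.tsv``.  Motifs use JASPAR-style text (``>id`` line followed by
one row per base).  All writer/reader pairs round-trip exactly and order
deterministically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with gene ids and cell barcodes."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("duplicate cell barcodes")
        if self.values.nnz:
            data = self.values.data
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.values.data = np.asarray(np.round(self.values.data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of the given gene ids (all must be present)."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}...")
        return np.array([lut[g] for g in genes], dtype=np.intp)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.barcodes[i] for i in idx],
        )


@dataclass
class MotifModel:
    """A position weight matrix with its background base composition.

    ``matrix`` is L x 4 with columns ordered A, C, G, T; rows are per-position
    base probabilities (or nonnegative weights normalized on construction).
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"motif {self.id}: matrix must be L x 4")
        if self.matrix.shape[0] < 1:
            raise FormatError(f"motif {self.id}: empty matrix")
        if np.any(self.matrix < 0):
            raise FormatError(f"motif {self.id}: negative weights")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise FormatError(f"motif {self.id}: background must sum to 1")
        rowsums = self.matrix.sum(axis=1)
        if np.any(rowsums <= 0):
            raise FormatError(f"motif {self.id}: all-zero position")
        self.matrix = self.matrix / rowsums[:, None]

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))


# ---------------------------------------------------------------------------
# count matrices

def write_count_matrix(m: CountMatrix, path: str) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``path``."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"), sp.coo_matrix(m.values), field="integer"
    )
    with open(os.path.join(path, "genes.tsv"), "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")


def read_count_matrix(path: str) -> CountMatrix:
    """Read a CellRanger-style directory written by :func:`write_count_matrix`."""
    try:
        values = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    except ValueError as exc:
        raise FormatError(f"bad MatrixMarket file: {exc}") from exc
    genes = []
    with open(os.path.join(path, "genes.tsv")) as fh:
        for line in fh:
            if line.strip():
                genes.append(line.rstrip("\n").split("\t")[0])
    with open(os.path.join(path, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return CountMatrix(sp.csr_matrix(values), genes, barcodes)


# ---------------------------------------------------------------------------
# PWMs

PWM_PSEUDOCOUNT = 0.5  # added per cell before normalization; avoids -inf log-odds


def read_pwms(path: str, pseudocount: float = PWM_PSEUDOCOUNT) -> list[MotifModel]:
    """Read JASPAR-like motif text into normalized :class:`MotifModel` objects.

    Counts (or weights) in each position are normalized to probabilities after
    adding ``pseudocount`` to every cell.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # Biopython raises bare Exceptions here
            raise FormatError(f"bad PWM file {path}: {exc}") from exc
    out = []
    for mot in parsed:
        counts = np.array(
            [[mot.counts[b][i] for b in "ACGT"] for i in range(mot.length)],
            dtype=np.float64,
        )
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        out.append(MotifModel(id=mot.matrix_id or mot.name, matrix=probs))
    return out


def write_pwms(motifs: list[MotifModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id}\n")
            for j, base in enumerate("ACGT"):
                row = " ".join(f"{x:.6f}" for x in m.matrix[:, j])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> dict[str, str]:
    """Read FASTA into an insertion-ordered {name: uppercased sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record name: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# TSV tables

def write_reference_map(ref, path: str) -> None:
    """Reference map as TSV: first column gene, remaining columns type_zone."""
    df = pd.DataFrame(ref.means, index=ref.genes, columns=ref.column_names())
    df.to_csv(path, sep="\t", index_label="gene")


def read_reference_map(path: str):
    from .annotate import ReferenceMap

    df = pd.read_csv(path, sep="\t", index_col=0)
    columns = []
    for c in df.columns:
        ctype, _, zone = c.rpartition("_")
        columns.append((ctype, int(zone)))
    return ReferenceMap(
        genes=list(df.index.astype(str)),
        columns=columns,
        means=df.to_numpy(dtype=np.float64),
    )


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
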