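"""Readers and writers for every external table the framework touches.

All genomic coordinates are normalised to the 0-based half-open convention
internally; BED input is native, and :func:`from_1based` converts 1-based
inclusive records at the boundary.  Strand is retained where present but is
never consulted by overlap logic.

Dialects
--------
contact TSV
    Header ``read_id  chrom  start  end``; one aligned monomer per row.
    Rows belonging to one read need not be adjacent.
BED3/BED6
    Peaks, enhancers and gene annotation.  For genes, ``name`` carries the
    gene identifier and the TSS is derivable from strand (``start`` on ``+``,
    ``end - 1`` on ``-``).
expression TSV
    Two columns ``gene_id  value`` (non-negative, TPM-like scale).
motif TSV
    Genes x transcription factors matrix of binding-site counts, plus a
    two-column sidecar mapping each TF to its encoding gene.
chromosome sizes TSV
    Two columns ``chrom  length``.
incidence triplets
    Sparse ``node_id  hyperedge_id  1`` triplets with ``.nodes.tsv`` and
    ``.edges.tsv`` sidecars, round-tripping a hypergraph losslessly.

Every writer accepts ``header_comment`` lines (emitted with a leading ``#``)
and every reader skips ``#`` comments, so provenance headers survive
round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class FormatError(ValueError):
    """Malformed input table (missing column, bad coordinate, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def tss(self) -> int:
        """Transcription start site (start on '+', end-1 on '-')."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class Monomer:
    """One aligned fragment of a long read."""

    read_id: str
    interval: GenomicInterval


@dataclass
class MultiwayRead:
    """One sequencing read's ordered set of aligned monomers (a raw hyperedge)."""

    read_id: str
    monomers: list[Monomer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.monomers and any(m.read_id != self.read_id for m in self.monomers):
            raise FormatError(f"monomers of read {self.read_id} carry mixed read ids")

    @property
    def order(self) -> int:
        return len(self.monomers)


def from_1based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive coordinate pair to 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# low-level line handling
# ---------------------------------------------------------------------------

def _data_lines(path: str | os.PathLike) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _write_comments(fh, header_comment: Sequence[str] | None) -> None:
    for line in header_comment or ():
        fh.write(f"# {line}\n")


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = ("read_id", "chrom", "start", "end")


def read_contacts(path: str | os.PathLike) -> list[MultiwayRead]:
    """Read a contact TSV into multi-way reads.

    Rows are grouped by ``read_id`` with input order preserved within a read;
    order-1 reads are returned too.
    """
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty contact table") from None
    col = {name: i for i, name in enumerate(header)}
    for required in CONTACT_COLUMNS:
        if required not in col:
            raise FormatError(f"{path}: missing required column '{required}'")
    reads: dict[str, MultiwayRead] = {}
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
        read_id = fields[col["read_id"]]
        chrom = fields[col["chrom"]]
        try:
            start = int(fields[col["start"]])
            end = int(fields[col["end"]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        try:
            interval = GenomicInterval(chrom, start, end)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        reads.setdefault(read_id, MultiwayRead(read_id)).monomers.append(
            Monomer(read_id, interval)
        )
    return list(reads.values())


def write_contacts(
    reads: Iterable[MultiwayRead],
    path: str | os.PathLike,
    header_comment: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_comments(fh, header_comment)
        fh.write("\t".join(CONTACT_COLUMNS) + "\n")
        for read in reads:
            for m in read.monomers:
                iv = m.interval
                fh.write(f"{read.read_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# interval sets (BED)
# ---------------------------------------------------------------------------

class IntervalSet:
    """A set of genomic intervals indexed for overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """Intervals overlapping [start, end) by at least 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return sorted((h.data for h in hits), key=lambda iv: (iv.start, iv.end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read BED3+ (comment/track/browser lines ignored, strand retained)."""
    intervals = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("track", "browser"):
            continue
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED requires >= 3 fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0:
            raise FormatError(f"{path}:{lineno}: negative coordinate")
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else None
        try:
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | os.PathLike,
    header_comment: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_comments(fh, header_comment)
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# chromosome sizes, expression, motifs
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'chrom length'")
        chrom = fields[0]
        if fields[1] == "length":  # header line
            continue
        try:
            length = int(fields[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length") from None
        if length <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive chromosome length")
        if chrom in sizes:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {chrom}")
        sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_expression(path: str | os.PathLike) -> dict[str, float]:
    """Read a two-column ``gene_id  value`` table (header line optional)."""
    table: dict[str, float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'gene_id value'")
        gene, raw = fields[0], fields[1]
        try:
            value = float(raw)
        except ValueError:
            if lineno == 1 or not table:
                continue  # header
            raise FormatError(f"{path}:{lineno}: non-numeric expression") from None
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative expression value")
        if gene in table:
            raise FormatError(f"{path}:{lineno}: duplicate gene {gene}")
        table[gene] = value
    return table


def write_expression(table: Mapping[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene, value in table.items():
            fh.write(f"{gene}\t{value:g}\n")


class MotifTable:
    """Binding-site counts: rows genes, columns transcription factors.

    Absent (gene, TF) pairs count as zero.  ``tf_gene`` maps a TF name to the
    gene encoding it; a TF may be unmapped.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        tf_gene: Mapping[str, str] | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene rows in motif table: {dups}")
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative binding-site counts in motif table")
        self.counts = counts.astype(int)
        self.tf_gene = dict(tf_gene or {})

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.counts.columns)

    def count(self, gene: str, tf: str) -> int:
        if gene in self.counts.index and tf in self.counts.columns:
            return int(self.counts.at[gene, tf])
        return 0

    def binds(self, gene: str, tf: str, min_sites: int = 3) -> bool:
        return self.count(gene, tf) >= min_sites

    def encoding_gene(self, tf: str) -> str | None:
        return self.tf_gene.get(tf)

    def is_master_regulator(self, tf: str, min_sites: int = 3) -> bool:
        """A TF whose motif occurs at its own encoding gene."""
        gene = self.encoding_gene(tf)
        return gene is not None and self.binds(gene, tf, min_sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.tf_gene == other.tf_gene


def read_motif_table(
    path: str | os.PathLike,
    tf_gene_path: str | os.PathLike | None = None,
) -> MotifTable:
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    tf_gene = read_tf_gene_map(tf_gene_path) if tf_gene_path is not None else None
    return MotifTable(counts, tf_gene)


def write_motif_table(table: MotifTable, path: str | os.PathLike) -> None:
    out = table.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_tf_gene_map(path: str | os.PathLike) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'tf gene_id'")
        if fields == ["tf", "gene_id"]:
            continue
        mapping[fields[0]] = fields[1]
    return mapping


def write_tf_gene_map(mapping: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tgene_id\n")
        for tf, gene in mapping.items():
            fh.write(f"{tf}\t{gene}\n")


# ---------------------------------------------------------------------------
# incidence and dense matrices
# ---------------------------------------------------------------------------

def write_incidence(
    hypergraph,
    path: str | os.PathLike,
    header_comment: Sequence[str] | None = None,
) -> None:
    """Write a hypergraph as sparse incidence triplets plus dictionaries.

    ``path`` gets ``node_id  hyperedge_id  1`` triplets; ``path.nodes.tsv``
    and ``path.edges.tsv`` hold the node and hyperedge dictionaries.  The
    trio round-trips losslessly through :func:`read_incidence`.
    """
    path = os.fspath(path)
    with open(path, "w") as fh:
        _write_comments(fh, header_comment)
        fh.write("node_id\thyperedge_id\tvalue\n")
        for j, edge in enumerate(hypergraph.hyperedges):
            for i in sorted(edge):
                fh.write(f"{i}\t{j}\t1\n")
    with open(path + ".nodes.tsv", "w") as fh:
        fh.write("node_id\tchrom\tbin_index\tresolution\tend\n")
        for i, node in enumerate(hypergraph.nodes):
            end = "" if node.end is None else str(node.end)
            fh.write(f"{i}\t{node.chrom}\t{node.bin_index}\t{node.resolution}\t{end}\n")
    with open(path + ".edges.tsv", "w") as fh:
        fh.write("hyperedge_id\tweight\n")
        for j, w in enumerate(hypergraph.weights):
            fh.write(f"{j}\t{w}\n")


def read_incidence(path: str | os.PathLike):
    """Inverse of :func:`write_incidence`."""
    from .hypergraph import GenomicBin, Hypergraph  # lazy: avoid import cycle

    path = os.fspath(path)
    nodes = []
    resolution: int | str = "read"
    for lineno, fields in _data_lines(path + ".nodes.tsv"):
        if fields[0] == "node_id":
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}.nodes.tsv:{lineno}: truncated node record")
        _, chrom, bin_index, res = fields[:4]
        end = int(fields[4]) if len(fields) > 4 and fields[4] else None
        resolution = res if res == "read" else int(res)
        nodes.append(GenomicBin(chrom, int(bin_index), resolution, end))
    weights = []
    for lineno, fields in _data_lines(path + ".edges.tsv"):
        if fields[0] == "hyperedge_id":
            continue
        weights.append(int(fields[1]))
    edges: list[set[int]] = [set() for _ in weights]
    for lineno, fields in _data_lines(path):
        if fields[0] == "node_id":
            continue
        i, j = int(fields[0]), int(fields[1])
        edges[j].add(i)
    return Hypergraph(nodes, edges, weights, resolution)


def write_matrix(
    values: np.ndarray | pd.DataFrame,
    path: str | os.PathLike,
    labels: Sequence[str] | None = None,
    header_comment: Sequence[str] | None = None,
) -> None:
    """Write a dense labelled matrix as TSV (row and column labels kept)."""
    if isinstance(values, pd.DataFrame):
        frame = values
    else:
        values = np.asarray(values)
        if labels is None:
            labels = [str(i) for i in range(values.shape[0])]
        frame = pd.DataFrame(values, index=list(labels), columns=list(labels))
    with open(path, "w") as fh:
        _write_comments(fh, header_comment)
        frame.to_csv(fh, sep="\t")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
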