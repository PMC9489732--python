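"""Binned genomic hypergraphs from multi-way reads.

A multi-way contact captured on one long read is a hyperedge over genomic
loci.  Nodes are genomic bins at a chosen resolution (e.g. 100 kb, 1 Mb,
25 Mb) or individual monomer intervals at "read" resolution.  This module
builds hypergraphs from reads, derives incidence matrices, filters noisy
contacts by pairwise support, decomposes hypergraphs into Hi-C-style
pairwise contact matrices, and computes the descriptive summaries used in
the analysis (contact-order frequencies, top intra-/inter-chromosomal
contacts, chromosome-combination frequencies, node degrees).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MultiwayRead

# Resolutions at or above this use weighted incidence by default: most
# high-resolution contacts are unique, so weighting only matters for the
# coarse bins where recurrent contacts accumulate.
WEIGHTED_RESOLUTION_THRESHOLD = 1_000_000


@dataclass(frozen=True)
class GenomicBin:
    """One node of a genomic hypergraph.

    At an integer resolution the node is the half-open window
    ``[bin_index * resolution, (bin_index + 1) * resolution)``.  At "read"
    resolution each distinct monomer interval is its own node; ``bin_index``
    then holds the interval start and ``end`` its end.
    """

    chrom: str
    bin_index: int
    resolution: int | str
    end: int | None = None

    @property
    def start(self) -> int:
        if self.resolution == "read":
            return self.bin_index
        return self.bin_index * self.resolution

    @property
    def stop(self) -> int:
        if self.resolution == "read":
            assert self.end is not None
            return self.end
        return (self.bin_index + 1) * self.resolution

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.stop}"


class Hypergraph:
    """Node list + weighted hyperedges over node indices.

    Identical hyperedge sets are merged at construction with weights summed,
    and hyperedges are stored in a canonical order (sorted member tuples), so
    two hypergraphs built from the same contacts compare equal regardless of
    input order.
    """

    def __init__(
        self,
        nodes: Sequence[GenomicBin],
        hyperedges: Iterable[Iterable[int]] = (),
        weights: Sequence[int] | None = None,
        resolution: int | str | None = None,
    ) -> None:
        self.nodes: list[GenomicBin] = list(nodes)
        n = len(self.nodes)
        raw = [frozenset(e) for e in hyperedges]
        if weights is None:
            weights = [1] * len(raw)
        if len(weights) != len(raw):
            raise ValueError("weights and hyperedges length mismatch")
        merged: dict[frozenset[int], int] = {}
        for edge, w in zip(raw, weights):
            if not edge:
                raise ValueError("empty hyperedge")
            if w < 1:
                raise ValueError("hyperedge weight must be >= 1")
            if any(i < 0 or i >= n for i in edge):
                raise ValueError("hyperedge references node outside node set")
            merged[edge] = merged.get(edge, 0) + w
        order = sorted(merged, key=lambda e: tuple(sorted(e)))
        self.hyperedges: list[frozenset[int]] = order
        self.weights: list[int] = [merged[e] for e in order]
        if resolution is None:
            resolution = self.nodes[0].resolution if self.nodes else "read"
        self.resolution = resolution

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.hyperedges)

    @property
    def orders(self) -> list[int]:
        return [len(e) for e in self.hyperedges]

    @property
    def total_weight(self) -> int:
        return sum(self.weights)

    @property
    def node_labels(self) -> list[str]:
        return [node.label for node in self.nodes]

    def chroms_of(self, edge: frozenset[int]) -> frozenset[str]:
        return frozenset(self.nodes[i].chrom for i in edge)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.hyperedges == other.hyperedges
            and self.weights == other.weights
            and self.resolution == other.resolution
        )

    def __repr__(self) -> str:
        return (
            f"Hypergraph(n={self.n}, m={self.m}, total_weight={self.total_weight}, "
            f"resolution={self.resolution!r})"
        )


@dataclass
class ContactMatrix:
    """Symmetric pairwise contact counts with hypergraph node labels."""

    values: np.ndarray
    nodes: list[GenomicBin]

    @property
    def labels(self) -> list[str]:
        return [node.label for node in self.nodes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def bin_reads(
    reads: Sequence[MultiwayRead],
    resolution: int | str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> Hypergraph:
    """Bin each read's monomers into genomic bins and build the hypergraph.

    A monomer maps to the bin containing its fragment midpoint.  Duplicate
    bins within one read collapse to one node (so a read's order can shrink,
    down to an order-1 self-contact, which is retained).  Identical hyperedge
    sets merge with weight equal to their multiplicity.

    When ``chrom_sizes`` is supplied at an integer resolution, the node
    universe is *all* bins of the supplied chromosomes in table order, so
    hypergraphs from different samples share a row order and can be compared
    directly.  At "read" resolution (or without sizes) the nodes are the
    distinct observed loci in sorted order.
    """
    if resolution != "read":
        if not isinstance(resolution, (int, np.integer)) or resolution <= 0:
            raise ValueError(f"resolution must be a positive integer or 'read', got {resolution!r}")
        resolution = int(resolution)
    if chrom_sizes is not None:
        for read in reads:
            for m in read.monomers:
                if m.interval.chrom not in chrom_sizes:
                    raise ValueError(
                        f"read {read.read_id}: chromosome {m.interval.chrom} "
                        "absent from sizes table"
                    )

    if resolution == "read":
        seen: dict[GenomicBin, None] = {}
        for read in reads:
            for m in read.monomers:
                iv = m.interval
                seen.setdefault(GenomicBin(iv.chrom, iv.start, "read", iv.end), None)
        nodes = sorted(seen, key=lambda b: (b.chrom, b.bin_index, b.end))
    elif chrom_sizes is not None:
        nodes = [
            GenomicBin(chrom, i, resolution)
            for chrom, length in chrom_sizes.items()
            for i in range(math.ceil(length / resolution))
        ]
    else:
        seen = {}
        for read in reads:
            for m in read.monomers:
                iv = m.interval
                seen.setdefault(GenomicBin(iv.chrom, iv.midpoint // resolution, resolution), None)
        nodes = sorted(seen, key=lambda b: (b.chrom, b.bin_index))

    index = {node: i for i, node in enumerate(nodes)}
    edges: list[set[int]] = []
    for read in reads:
        members: set[int] = set()
        for m in read.monomers:
            iv = m.interval
            if resolution == "read":
                bin_ = GenomicBin(iv.chrom, iv.start, "read", iv.end)
            else:
                bin_ = GenomicBin(iv.chrom, iv.midpoint // resolution, resolution)
            members.add(index[bin_])
        if members:
            edges.append(members)
    return Hypergraph(nodes, edges, None, resolution)


def rebin(hypergraph: Hypergraph, resolution: int) -> Hypergraph:
    """Re-bin a binned hypergraph at a coarser multiple of its resolution."""
    old = hypergraph.resolution
    if old == "read" or not isinstance(old, int):
        raise ValueError("rebin requires an integer-resolution hypergraph")
    if resolution % old != 0:
        raise ValueError("new resolution must be a multiple of the old one")
    factor = resolution // old
    # Map only nodes that participate in hyperedges; rebuild universe from
    # the old one so shared row order is preserved across samples.
    new_nodes_seen: dict[GenomicBin, None] = {}
    for node in hypergraph.nodes:
        new_nodes_seen.setdefault(
            GenomicBin(node.chrom, node.bin_index // factor, resolution), None
        )
    nodes = list(new_nodes_seen)
    index = {node: i for i, node in enumerate(nodes)}
    edges = []
    weights = []
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        members = {
            index[
                GenomicBin(
                    hypergraph.nodes[i].chrom,
                    hypergraph.nodes[i].bin_index // factor,
                    resolution,
                )
            ]
            for i in edge
        }
        edges.append(members)
        weights.append(w)
    return Hypergraph(nodes, edges, weights, resolution)


def build_incidence(hypergraph: Hypergraph, weighted: bool | None = None) -> np.ndarray:
    """Build the n x m 0/1 incidence matrix H.

    ``weighted=True`` gives one column per distinct hyperedge (multiplicity
    carried separately in ``hypergraph.weights``); ``weighted=False`` expands
    a weight-w hyperedge into w identical columns, one per read occurrence.
    The default follows the resolution convention: weighted at coarse
    resolutions (>= 1 Mb), unweighted at read level / fine bins.
    """
    if weighted is None:
        weighted = (
            isinstance(hypergraph.resolution, int)
            and hypergraph.resolution >= WEIGHTED_RESOLUTION_THRESHOLD
        )
    n = hypergraph.n
    if weighted:
        H = np.zeros((n, hypergraph.m))
        for j, edge in enumerate(hypergraph.hyperedges):
            H[list(edge), j] = 1.0
    else:
        H = np.zeros((n, hypergraph.total_weight))
        j = 0
        for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
            for _ in range(w):
                H[list(edge), j] = 1.0
                j += 1
    return H


# ---------------------------------------------------------------------------
# decomposition and filtering
# ---------------------------------------------------------------------------

def pair_counts(hypergraph: Hypergraph) -> dict[tuple[int, int], int]:
    """Weighted counts of unordered node pairs from all order->=2 hyperedges."""
    counts: Counter[tuple[int, int]] = Counter()
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        if len(edge) < 2:
            continue
        for i, j in combinations(sorted(edge), 2):
            counts[(i, j)] += w
    return dict(counts)


def decompose_pairwise(hypergraph: Hypergraph) -> ContactMatrix:
    """Decompose hyperedges into a symmetric pairwise contact matrix.

    An order-k hyperedge of weight w contributes w to each of its C(k, 2)
    unordered locus pairs; order-1 self-contacts contribute w to the diagonal.
    The result is interchangeable with a conventional Hi-C contact matrix.
    """
    n = hypergraph.n
    M = np.zeros((n, n))
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        if len(edge) == 1:
            (i,) = edge
            M[i, i] += w
            continue
        for i, j in combinations(sorted(edge), 2):
            M[i, j] += w
            M[j, i] += w
    return ContactMatrix(M, list(hypergraph.nodes))


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Smallest value with at least ``percentile`` % of the data at or below it."""
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    ordered = sorted(values)
    if not ordered:
        raise ValueError("empty distribution")
    rank = math.ceil(percentile / 100 * len(ordered))
    return ordered[rank - 1]


def filter_hypergraph(hypergraph: Hypergraph, percentile: float = 85) -> Hypergraph:
    """Keep only multi-way contacts whose internal locus pairs recur often.

    The hypergraph is decomposed to weighted pair counts over distinct pairs;
    the support threshold t is the nearest-rank ``percentile`` of that count
    distribution, and a pair is supported iff its count >= t.  Within each
    hyperedge, the node incident to the most unsupported internal pairs is
    removed iteratively (ties to the lower node index) until every remaining
    internal pair is supported; hyperedges left with fewer than two nodes are
    dropped and identical survivors re-merge.  Order-1 self-contacts never
    enter the pair statistics and are dropped from the filtered hypergraph.

    Because trimming lowers the counts of surviving pairs, the pass is
    repeated on its own output until a fixpoint is reached, which makes the
    filter idempotent at a fixed percentile.
    """
    current = hypergraph
    while True:
        filtered = _filter_pass(current, percentile)
        if (
            filtered.hyperedges == current.hyperedges
            and filtered.weights == current.weights
        ):
            return filtered
        current = filtered


def _filter_pass(hypergraph: Hypergraph, percentile: float) -> Hypergraph:
    counts = pair_counts(hypergraph)
    if not counts:
        return Hypergraph(hypergraph.nodes, [], None, hypergraph.resolution)
    threshold = nearest_rank_percentile(list(counts.values()), percentile)
    supported = {pair for pair, c in counts.items() if c >= threshold}

    edges: list[set[int]] = []
    weights: list[int] = []
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        members = set(edge)
        while len(members) >= 2:
            bad: Counter[int] = Counter()
            for i, j in combinations(sorted(members), 2):
                if (i, j) not in supported:
                    bad[i] += 1
                    bad[j] += 1
            if not bad:
                break
            worst = max(bad.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            members.remove(worst)
        if len(members) >= 2:
            edges.append(members)
            weights.append(w)
    return Hypergraph(hypergraph.nodes, edges, weights, hypergraph.resolution)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def order_frequencies(hypergraph: Hypergraph) -> dict[int, int]:
    """Total hyperedge weight per contact order k = 1, 2, 3, ..."""
    freq: Counter[int] = Counter()
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        freq[len(edge)] += w
    return dict(sorted(freq.items()))


def _edge_sort_key(hypergraph: Hypergraph):
    def key(j: int):
        return (-hypergraph.weights[j], tuple(sorted(hypergraph.hyperedges[j])))

    return key


def top_contacts(
    hypergraph: Hypergraph,
    per_chrom_intra: int = 5,
    per_chrom_inter: int = 5,
) -> dict[str, list[int]]:
    """Highest-weight intra- and inter-chromosomal contacts per chromosome.

    For each chromosome (node order), select up to ``per_chrom_intra``
    distinct intra-chromosomal hyperedges and ``per_chrom_inter``
    inter-chromosomal ones by descending weight (ties by lexicographic node
    indices).  A chromosome short on unique intra-chromosomal contacts is
    supplemented with additional inter-chromosomal ones, and a hyperedge
    already selected for an earlier chromosome is never repeated.  Returns
    hyperedge indices into ``hypergraph.hyperedges`` per chromosome.
    """
    chrom_order: list[str] = []
    for node in hypergraph.nodes:
        if node.chrom not in chrom_order:
            chrom_order.append(node.chrom)
    key = _edge_sort_key(hypergraph)
    taken: set[int] = set()
    result: dict[str, list[int]] = {}
    for chrom in chrom_order:
        intra = []
        inter = []
        for j, edge in enumerate(hypergraph.hyperedges):
            if j in taken or len(edge) < 2:
                continue
            chroms = hypergraph.chroms_of(edge)
            if chrom not in chroms:
                continue
            (intra if len(chroms) == 1 else inter).append(j)
        intra.sort(key=key)
        inter.sort(key=key)
        chosen = intra[:per_chrom_intra]
        quota_inter = per_chrom_inter + (per_chrom_intra - len(chosen))
        chosen += inter[:quota_inter]
        taken.update(chosen)
        result[chrom] = chosen
    return result


def chrom_combination_frequencies(
    hypergraph: Hypergraph,
    chrom_sizes: Mapping[str, int],
    max_order: int = 5,
) -> pd.DataFrame:
    """Weighted frequencies of chromosome combinations, length-normalized.

    Each hyperedge maps to its set of distinct chromosomes (unique instances
    only); combinations of 2..``max_order`` chromosomes are counted by
    hyperedge weight, and each count is divided by the summed bp length of
    the member chromosomes.  Returns a tidy frame sorted by normalized
    frequency (descending) with columns ``chroms`` (sorted tuple), ``order``,
    ``count`` and ``normalized``.
    """
    counts: Counter[tuple[str, ...]] = Counter()
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        combo = tuple(sorted(hypergraph.chroms_of(edge)))
        if 2 <= len(combo) <= max_order:
            counts[combo] += w
    rows = []
    for combo, count in counts.items():
        total_len = sum(chrom_sizes[c] for c in combo)
        rows.append(
            {
                "chroms": combo,
                "order": len(combo),
                "count": count,
                "normalized": count / total_len,
            }
        )
    frame = pd.DataFrame(rows, columns=["chroms", "order", "count", "normalized"])
    if len(frame):
        frame = frame.sort_values(
            ["normalized", "chroms"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def top_combination_per_chrom(frequencies: pd.DataFrame) -> pd.DataFrame:
    """Per chromosome and order, the top normalized chromosome combination."""
    rows = []
    chroms = sorted({c for combo in frequencies["chroms"] for c in combo})
    for chrom in chroms:
        sub = frequencies[[chrom in combo for combo in frequencies["chroms"]]]
        for order, group in sub.groupby("order"):
            best = group.iloc[0]  # frame already sorted by normalized desc
            rows.append(
                {
                    "chrom": chrom,
                    "order": int(order),
                    "chroms": best["chroms"],
                    "count": int(best["count"]),
                    "normalized": float(best["normalized"]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "order", "chroms", "count", "normalized"])


def node_degrees(hypergraph: Hypergraph, normalized: bool = False) -> np.ndarray:
    """Weighted number of hyperedges containing each node.

    ``normalized=True`` divides by the maximum degree so the most connected
    locus scores 1.0.
    """
    deg = np.zeros(hypergraph.n)
    for edge, w in zip(hypergraph.hyperedges, hypergraph.weights):
        deg[list(edge)] += w
    if normalized:
        peak = deg.max() if hypergraph.m else 0.0
        if peak > 0:
            deg = deg / peak
    return deg
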