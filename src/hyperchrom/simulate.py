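"""Synthetic multi-way contact data with planted transcription clusters.

The generator emulates the six input types the framework consumes — contact
tables, peak BEDs (ATAC, Pol II, CTCF/RAD21/SMC3, enhancers), gene
annotation, expression, motif counts with a TF-to-gene sidecar, and
chromosome sizes — with fully controllable structure:

* background reads draw their contact order from a configurable
  distribution (defaults decrease monotonically from 2-way to 6-way,
  mirroring the qualitative shape of observed Pore-C order frequencies) and
  place monomers uniformly, mixing intra- and inter-chromosomal contacts;
* planted transcription clusters emit reads whose monomers hit dedicated
  planted loci, and the annotation layers are constructed so each planted
  cluster satisfies exactly the criteria of its labelled tier (potential /
  cluster / specialized / self-sustaining / core) — accessibility at every
  locus, Pol II at one, expressed genes near the loci, a shared TF with at
  least ``min_sites`` motif occurrences, self-binding and in-cluster
  TF-encoding genes per tier.

Planted loci live in a reserved stripe at the start of each chromosome and
background monomers are drawn outside it (with a flank-sized margin), so at
zero background noise the planted set is recoverable exactly; background
noise rates re-introduce peaks, genes and motif counts elsewhere.  All
output is deterministic given the seed, and ``ground_truth`` lists every
planted read with its tier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .io import GenomicInterval, IntervalSet, Monomer, MotifTable, MultiwayRead
from .hypergraph import GenomicBin, Hypergraph

TIERS = ("potential", "cluster", "specialized", "self_sustaining", "core")


def _default_order_probs() -> dict[int, float]:
    return {2: 0.45, 3: 0.25, 4: 0.15, 5: 0.10, 6: 0.05}


def _default_chrom_sizes() -> dict[str, int]:
    return {
        "chr1": 20_000_000,
        "chr2": 16_000_000,
        "chr3": 12_000_000,
        "chr4": 9_000_000,
    }


def _default_clusters_per_tier() -> dict[str, int]:
    return {tier: 4 for tier in TIERS}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_reads: int = 2_000
    order_probs: dict[int, float] = field(default_factory=_default_order_probs)
    inter_prob: float = 0.3          # chance a background monomer jumps chromosome
    clusters_per_tier: dict[str, int] = field(default_factory=_default_clusters_per_tier)
    planted_order_probs: dict[int, float] = field(
        default_factory=lambda: {3: 0.4, 4: 0.3, 5: 0.2, 6: 0.1}
    )
    reads_per_cluster: int = 2
    genes_per_cluster: int = 2       # expressed genes for tiers >= cluster
    n_decoy_tfs: int = 5
    flank: int = 5_000
    locus_length: int = 1_000
    expr_level: float = 50.0         # TPM-like expression of planted genes
    expr_threshold: float = 1.0
    min_sites: int = 3
    reserved_fraction: float = 0.25  # leading stripe per chromosome for planted loci
    background_peak_density: float = 0.0   # peaks per Mb outside the reserved stripe
    background_gene_density: float = 0.0   # genes per Mb outside the reserved stripe
    background_motif_rate: float = 0.0     # P(nonzero background motif count)
    expression_noise: float = 0.0          # sd of log-normal noise on expression
    factor_at_cluster_prob: float = 1.0    # CTCF/RAD21/SMC3/enhancer at planted loci
    background_factor_density: float = 0.0

    def __post_init__(self) -> None:
        for probs in (self.order_probs, self.planted_order_probs):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"order probabilities must sum to 1, got {total}")
        if any(v < 0 for v in self.clusters_per_tier.values()):
            raise ValueError("cluster counts must be >= 0")
        if self.n_reads < 0 or self.reads_per_cluster < 1:
            raise ValueError("read counts must be positive")

    @property
    def n_clusters(self) -> int:
        return sum(self.clusters_per_tier.values())


@dataclass
class PlantedCluster:
    cluster_id: str
    tier: str
    loci: list[GenomicInterval]
    read_ids: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    tf: str | None = None


@dataclass
class SimulatedDataset:
    """In-memory simulation output in the framework's input formats."""

    config: SimConfig
    reads: list[MultiwayRead]
    ground_truth: pd.DataFrame           # read_id, cluster_id, tier
    planted: list[PlantedCluster]
    atac: IntervalSet
    polii: IntervalSet
    factors: dict[str, IntervalSet]      # ctcf / rad21 / smc3 / enhancer
    genes: IntervalSet
    expression: dict[str, float]
    motifs: MotifTable

    def write(self, outdir: str | os.PathLike, header_comment=None) -> dict[str, str]:
        """Write every table in the documented dialects; returns the paths."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "contacts": os.path.join(outdir, "contacts.tsv"),
            "atac": os.path.join(outdir, "atac.bed"),
            "polii": os.path.join(outdir, "polii.bed"),
            "genes": os.path.join(outdir, "genes.bed"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "motifs": os.path.join(outdir, "motifs.tsv"),
            "tf_genes": os.path.join(outdir, "tf_genes.tsv"),
            "chrom_sizes": os.path.join(outdir, "chrom_sizes.tsv"),
            "ground_truth": os.path.join(outdir, "ground_truth.tsv"),
        }
        hio.write_contacts(self.reads, paths["contacts"], header_comment)
        hio.write_bed(self.atac, paths["atac"], header_comment)
        hio.write_bed(self.polii, paths["polii"], header_comment)
        for name, peaks in self.factors.items():
            paths[name] = os.path.join(outdir, f"{name}.bed")
            hio.write_bed(peaks, paths[name], header_comment)
        hio.write_bed(self.genes, paths["genes"], header_comment)
        hio.write_expression(self.expression, paths["expression"])
        hio.write_motif_table(self.motifs, paths["motifs"])
        hio.write_tf_gene_map(self.motifs.tf_gene, paths["tf_genes"])
        hio.write_chrom_sizes(self.config.chrom_sizes, paths["chrom_sizes"])
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _sample_order(probs: Mapping[int, float], rng: np.random.Generator) -> int:
    orders = sorted(probs)
    return int(rng.choice(orders, p=[probs[k] for k in orders]))


def _place_planted_loci(config: SimConfig, rng: np.random.Generator):
    """Lay out planted loci on a grid inside the reserved stripes."""
    spacing = 4 * (config.flank + config.locus_length)
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_sizes.items():
        reserved = int(length * config.reserved_fraction)
        pos = spacing // 2
        while pos + config.locus_length < reserved:
            slots.append((chrom, pos))
            pos += spacing
    rng.shuffle(slots)
    return slots


def simulate_contacts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[MultiwayRead], pd.DataFrame, list[PlantedCluster]]:
    """Draw background reads plus one batch of reads per planted cluster."""
    rng = rng or np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)

    slots = _place_planted_loci(config, rng)
    planted: list[PlantedCluster] = []
    cursor = 0
    cluster_idx = 0
    for tier in TIERS:
        for _ in range(config.clusters_per_tier.get(tier, 0)):
            order = _sample_order(config.planted_order_probs, rng)
            if cursor + order > len(slots):
                raise ValueError(
                    "not enough reserved genome for the requested planted clusters; "
                    "increase chromosome sizes or reserved_fraction"
                )
            loci = []
            for chrom, pos in slots[cursor : cursor + order]:
                loci.append(GenomicInterval(chrom, pos, pos + config.locus_length))
            cursor += order
            planted.append(PlantedCluster(f"pc{cluster_idx}", tier, loci))
            cluster_idx += 1

    reads: list[MultiwayRead] = []
    truth_rows = []
    for cluster in planted:
        for r in range(config.reads_per_cluster):
            read_id = f"{cluster.cluster_id}_read{r}"
            monomers = []
            for locus in cluster.loci:
                jitter = int(rng.integers(-config.locus_length // 4, config.locus_length // 4 + 1))
                start = max(0, locus.start + jitter)
                monomers.append(
                    Monomer(read_id, GenomicInterval(locus.chrom, start, start + config.locus_length))
                )
            reads.append(MultiwayRead(read_id, monomers))
            cluster.read_ids.append(read_id)
            truth_rows.append(
                {"read_id": read_id, "cluster_id": cluster.cluster_id, "tier": cluster.tier}
            )

    margin = 2 * config.flank + config.locus_length
    n_background = config.n_reads - len(reads)
    if n_background < 0:
        raise ValueError("n_reads smaller than the number of planted reads")
    size_arr = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    for b in range(n_background):
        read_id = f"bg{b}"
        order = _sample_order(config.order_probs, rng)
        home = chroms[int(rng.choice(len(chroms), p=size_arr / size_arr.sum()))]
        monomers = []
        for _ in range(order):
            chrom = home
            if len(chroms) > 1 and rng.random() < config.inter_prob:
                chrom = chroms[int(rng.integers(len(chroms)))]
            length = config.chrom_sizes[chrom]
            lo = int(length * config.reserved_fraction) + margin
            hi = length - config.locus_length
            if lo >= hi:
                raise ValueError(f"chromosome {chrom} too small for background reads")
            start = int(rng.integers(lo, hi))
            monomers.append(
                Monomer(read_id, GenomicInterval(chrom, start, start + config.locus_length))
            )
        reads.append(MultiwayRead(read_id, monomers))
        truth_rows.append({"read_id": read_id, "cluster_id": "", "tier": "background"})

    truth = pd.DataFrame(truth_rows, columns=["read_id", "cluster_id", "tier"])
    return reads, truth, planted


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _poisson_intervals(
    config: SimConfig,
    density_per_mb: float,
    length: int,
    rng: np.random.Generator,
    chrom: str,
    width: int,
    name_prefix: str | None = None,
    start_at: int | None = None,
) -> list[GenomicInterval]:
    lo = start_at if start_at is not None else int(length * config.reserved_fraction)
    span = max(0, length - lo - width)
    if span <= 0 or density_per_mb <= 0:
        return []
    count = rng.poisson(density_per_mb * span / 1e6)
    out = []
    for i in range(count):
        start = lo + int(rng.integers(0, span))
        name = f"{name_prefix}_{chrom}_{i}" if name_prefix else None
        out.append(GenomicInterval(chrom, start, start + width, name))
    return out


def simulate_annotations(
    config: SimConfig,
    planted: Sequence[PlantedCluster],
    rng: np.random.Generator,
) -> dict:
    """Build every annotation layer so planted tiers hold by construction."""
    peak_pad = 500
    atac, polii = [], []
    factor_beds: dict[str, list[GenomicInterval]] = {
        "ctcf": [], "rad21": [], "smc3": [], "enhancer": []
    }
    gene_rows: list[GenomicInterval] = []
    expression: dict[str, float] = {}
    motif_counts: dict[str, dict[str, int]] = {}
    tf_gene: dict[str, str] = {}

    def add_gene(gene_id: str, chrom: str, start: int, expressed: bool) -> None:
        gene_rows.append(
            GenomicInterval(chrom, start, start + 2_000, gene_id, None, "+")
        )
        level = config.expr_level if expressed else 0.0
        if config.expression_noise > 0 and expressed:
            level *= float(np.exp(rng.normal(0, config.expression_noise)))
        expression[gene_id] = level

    for cluster in planted:
        for locus in cluster.loci:
            atac.append(
                GenomicInterval(locus.chrom, max(0, locus.start - peak_pad), locus.end + peak_pad)
            )
            for factor, rows in factor_beds.items():
                if rng.random() < config.factor_at_cluster_prob:
                    rows.append(
                        GenomicInterval(
                            locus.chrom, max(0, locus.start - peak_pad), locus.end + peak_pad
                        )
                    )
        first = cluster.loci[0]
        polii.append(
            GenomicInterval(first.chrom, max(0, first.start - peak_pad), first.end + peak_pad)
        )

        tier = cluster.tier
        tf = f"TF_{cluster.cluster_id}"
        cluster.tf = tf
        # tier "potential": a single expressed gene, no shared TF machinery
        if tier == "potential":
            locus = cluster.loci[0]
            gene_id = f"g_{cluster.cluster_id}_0"
            add_gene(gene_id, locus.chrom, locus.end + 1_000, expressed=True)
            cluster.genes = [gene_id]
            continue

        n_genes = config.genes_per_cluster
        if tier == "self_sustaining":
            # needs >= 3 genes so the shared TF can bind a strict majority
            # without binding its own encoding gene (which would make it core)
            n_genes = max(3, n_genes + 1)
        gene_ids = []
        for g in range(n_genes):
            locus = cluster.loci[min(g, len(cluster.loci) - 1)]
            gene_id = f"g_{cluster.cluster_id}_{g}"
            offset = 1_000 + 3_000 * (g // len(cluster.loci))
            add_gene(gene_id, locus.chrom, locus.end + offset, expressed=True)
            gene_ids.append(gene_id)
        cluster.genes = gene_ids

        tf_gene_id = f"g_{cluster.cluster_id}_tf"
        if tier in ("self_sustaining", "core"):
            # the TF's encoding gene is itself one of the cluster's genes
            tf_gene[tf] = gene_ids[0]
        else:
            tf_gene[tf] = tf_gene_id
            # encoding gene lives outside any cluster and is not expressed
            chrom = next(iter(config.chrom_sizes))
            pos = config.chrom_sizes[chrom] - 50_000
            add_gene(tf_gene_id, chrom, pos, expressed=False)

        bound = gene_ids
        if tier == "self_sustaining":
            bound = gene_ids[1:]  # strict majority, but never its own gene
        for gene_id in bound:
            motif_counts.setdefault(gene_id, {})[tf] = int(rng.integers(config.min_sites, 7))
        if tier in ("specialized", "core"):
            own = tf_gene[tf]
            motif_counts.setdefault(own, {})[tf] = int(rng.integers(config.min_sites, 7))

    # background annotation noise
    for chrom, length in config.chrom_sizes.items():
        atac.extend(
            _poisson_intervals(config, config.background_peak_density, length, rng, chrom, 600)
        )
        polii.extend(
            _poisson_intervals(config, config.background_peak_density, length, rng, chrom, 600)
        )
        for factor, rows in factor_beds.items():
            rows.extend(
                _poisson_intervals(
                    config, config.background_factor_density, length, rng, chrom, 400
                )
            )
        for iv in _poisson_intervals(
            config, config.background_gene_density, length, rng, chrom, 2_000, "bgene"
        ):
            expressed = rng.random() < 0.5
            add_gene(iv.name, chrom, iv.start, expressed)

    decoys = [f"TF_decoy{i}" for i in range(config.n_decoy_tfs)]
    all_tfs = sorted({tf for c in motif_counts.values() for tf in c}) + decoys
    all_tfs += sorted(set(tf_gene) - set(all_tfs))
    all_genes = sorted(expression)
    counts = pd.DataFrame(0, index=all_genes, columns=sorted(set(all_tfs)))
    for gene, per_tf in motif_counts.items():
        for tf, c in per_tf.items():
            counts.at[gene, tf] = c
    if config.background_motif_rate > 0:
        mask = rng.random(counts.shape) < config.background_motif_rate
        noise = rng.integers(1, 3, size=counts.shape)  # below min_sites
        counts = counts.mask(mask & (counts.to_numpy() == 0), noise)

    genes_sorted = sorted(gene_rows, key=lambda g: (g.chrom, g.start))
    return {
        "atac": IntervalSet(sorted(atac, key=lambda p: (p.chrom, p.start))),
        "polii": IntervalSet(sorted(polii, key=lambda p: (p.chrom, p.start))),
        "factors": {
            name: IntervalSet(sorted(rows, key=lambda p: (p.chrom, p.start)))
            for name, rows in factor_beds.items()
        },
        "genes": IntervalSet(genes_sorted),
        "expression": expression,
        "motifs": MotifTable(counts, tf_gene),
    }


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full six-input dataset for one seed."""
    rng = np.random.default_rng(config.seed)
    reads, truth, planted = simulate_contacts(config, rng)
    ann = simulate_annotations(config, planted, rng)
    return SimulatedDataset(
        config=config,
        reads=reads,
        ground_truth=truth,
        planted=planted,
        atac=ann["atac"],
        polii=ann["polii"],
        factors=ann["factors"],
        genes=ann["genes"],
        expression=ann["expression"],
        motifs=ann["motifs"],
    )


# ---------------------------------------------------------------------------
# hypergraph perturbations and toys
# ---------------------------------------------------------------------------

def random_toy_hypergraph(
    n_nodes: int,
    n_edges: int,
    seed: int | np.random.Generator = 0,
    active_nodes: int | None = None,
    max_order: int = 4,
    resolution: int = 1_000_000,
) -> Hypergraph:
    """Small random hypergraph for calibration and property tests.

    ``active_nodes`` restricts hyperedge membership to the first nodes,
    leaving the rest as an empty block (useful for relocation experiments).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = active_nodes if active_nodes is not None else n_nodes
    if not 2 <= active <= n_nodes:
        raise ValueError("active_nodes must be in [2, n_nodes]")
    nodes = [GenomicBin("chr1", i, resolution) for i in range(n_nodes)]
    edges = []
    for _ in range(n_edges):
        k = int(rng.integers(2, min(max_order, active) + 1))
        edges.append(set(rng.choice(active, size=k, replace=False).tolist()))
    return Hypergraph(nodes, edges, None, resolution)


def perturb_hypergraph(
    hypergraph: Hypergraph,
    mode: str,
    strength: float,
    seed: int | np.random.Generator = 0,
) -> Hypergraph:
    """Controlled structural perturbation for distance calibration.

    ``relocate`` moves a ``strength`` fraction of hyperedges to a disjoint
    node block by shifting node indices by n//2 (mod n); ``rewire`` replaces
    each node membership with a uniform random non-member with probability
    ``strength``.  Strength 0 returns an identical hypergraph.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    if mode not in ("relocate", "rewire"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = hypergraph.n
    edges = [set(e) for e in hypergraph.hyperedges]
    weights = list(hypergraph.weights)
    if mode == "relocate":
        k = int(round(strength * len(edges)))
        chosen = rng.choice(len(edges), size=k, replace=False) if k else []
        shift = n // 2
        for j in chosen:
            edges[j] = {(i + shift) % n for i in edges[j]}
    else:
        for j, edge in enumerate(edges):
            new_edge = set(edge)
            for i in sorted(edge):
                if rng.random() < strength:
                    outside = [v for v in range(n) if v not in new_edge]
                    if outside:
                        new_edge.remove(i)
                        new_edge.add(int(rng.choice(outside)))
            edges[j] = new_edge
    return Hypergraph(hypergraph.nodes, edges, weights, hypergraph.resolution)
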