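"""Data-driven identification and classification of transcription clusters.

A transcription cluster is a multi-way contact whose loci colocalize for
efficient transcription.  The pipeline works on read-level contacts:

1. Each locus, extended by a +/-5 kb flank (clipped to the chromosome), is
   queried for chromatin accessibility (ATAC/DNase peaks), RNA Pol II
   binding (ChIP-seq peaks), and nearby genes (gene bodies overlapping the
   flanked locus), with expression attached from an RNA-seq table.
2. A contact is a *potential* cluster if every locus is accessible and at
   least one locus binds RNA Pol II.
3. A potential cluster with >= 2 expressed genes becomes a *cluster* if the
   genes share transcription factors: a TF "binds" a gene when its motif
   table count is >= ``min_sites`` (default 3 binding sites within +/-5 kb
   of the TSS); with exactly two expressed genes a common TF must bind
   both, with three or more it must bind a strict majority.
4. A cluster is *specialized* if a common TF is a master regulator (MR), a
   TF whose motif occurs at its own encoding gene.
5. A cluster is *self-sustaining* if it contains an expressed TF-encoding
   gene whose TF also binds a gene in the same cluster, and *core* when
   that TF is additionally an MR.  TFs whose encoding gene is expressed in
   a different cluster than one they bind form the analog-independent
   class (c); TF genes expressed in no cluster are tallied genome-wide as
   class (d).

Enrichment of architectural factors (CTCF, cohesin subunits, enhancers) at
clusters, and significance of the cluster-calling criteria, are assessed
with one-sided permutation tests against randomly drawn multi-way contacts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, IntervalSet, MotifTable, MultiwayRead

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5_000
DEFAULT_MIN_SITES = 3
DEFAULT_EXPR_THRESHOLD = 1.0

STATUS_POTENTIAL = "potential"
STATUS_CLUSTER = "cluster"
STATUS_SPECIALIZED = "specialized"


@dataclass
class AnnotatedLocus:
    """One read-level locus with its multi-omic annotation."""

    locus: GenomicInterval
    flanked: GenomicInterval
    accessible: bool
    polii_bound: bool
    genes: list[tuple[str, bool]] = field(default_factory=list)  # (gene_id, expressed)
    factor_overlaps: dict[str, bool] = field(default_factory=dict)


@dataclass
class AnnotatedContact:
    """A multi-way read with per-locus annotation."""

    read_id: str
    loci: list[AnnotatedLocus]

    @property
    def order(self) -> int:
        return len(self.loci)

    @property
    def expressed_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus in self.loci:
            for gene, expressed in locus.genes:
                if expressed:
                    seen.setdefault(gene, None)
        return list(seen)

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus in self.loci:
            for gene, _ in locus.genes:
                seen.setdefault(gene, None)
        return list(seen)

    def factor_present(self, factor: str) -> bool:
        return any(locus.factor_overlaps.get(factor, False) for locus in self.loci)


@dataclass
class TranscriptionCluster:
    """A (potential) transcription cluster and its classification flags."""

    contact: AnnotatedContact
    status: str = STATUS_POTENTIAL
    expressed_genes: list[str] = field(default_factory=list)
    common_tfs: list[str] = field(default_factory=list)
    common_mrs: list[str] = field(default_factory=list)
    self_sustaining: bool = False
    core: bool = False
    self_sustaining_tfs: list[str] = field(default_factory=list)

    @property
    def read_id(self) -> str:
        return self.contact.read_id

    @property
    def order(self) -> int:
        return self.contact.order


@dataclass
class EnrichmentResult:
    factor: str
    cluster_fraction: float
    background_fraction: float
    p_value: float
    n_trials: int


@dataclass
class SelfSustainingReport:
    """Genome-wide classification of TF / gene-analog coupling.

    ``analog_independent_pairs`` holds class (c) events: (tf, index of a
    cluster expressing the TF's gene, index of a different cluster the TF
    binds in).  ``unclustered_tf_genes`` are class (d): TFs binding some
    cluster whose encoding gene is expressed in no cluster.
    """

    analog_independent_pairs: list[tuple[str, int, int]] = field(default_factory=list)
    unclustered_tf_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _flank_interval(
    iv: GenomicInterval, flank: int, chrom_sizes: Mapping[str, int] | None
) -> GenomicInterval:
    start = max(0, iv.start - flank)
    end = iv.end + flank
    if chrom_sizes is not None and iv.chrom in chrom_sizes:
        end = min(end, chrom_sizes[iv.chrom])
    return GenomicInterval(iv.chrom, start, end)


def annotate_loci(
    reads: Sequence[MultiwayRead],
    atac: IntervalSet,
    polii: IntervalSet,
    genes: IntervalSet,
    expression: Mapping[str, float],
    flank: int = DEFAULT_FLANK,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    chrom_sizes: Mapping[str, int] | None = None,
    factor_peaks: Mapping[str, IntervalSet] | None = None,
) -> list[AnnotatedContact]:
    """Annotate every locus of every read against the supplied peak sets.

    A locus is accessible (resp. Pol II-bound) iff its flanked interval
    overlaps at least one ATAC (resp. Pol II) peak by >= 1 bp.  Genes whose
    body overlaps the flanked interval are attached with an expressed flag
    (expression >= ``expr_threshold``); genes missing from the expression
    table are treated as unexpressed and logged once.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    missing_logged: set[str] = set()
    contacts = []
    for read in reads:
        loci = []
        for monomer in read.monomers:
            iv = monomer.interval
            flanked = _flank_interval(iv, flank, chrom_sizes)
            hit_genes: list[tuple[str, bool]] = []
            for gene in genes.overlapping(flanked.chrom, flanked.start, flanked.end):
                gene_id = gene.name if gene.name is not None else gene.chrom
                if gene_id not in expression and gene_id not in missing_logged:
                    logger.warning(
                        "gene %s absent from expression table; treated as unexpressed",
                        gene_id,
                    )
                    missing_logged.add(gene_id)
                expressed = expression.get(gene_id, 0.0) >= expr_threshold
                hit_genes.append((gene_id, expressed))
            factors = {}
            for name, peaks in (factor_peaks or {}).items():
                factors[name] = peaks.overlaps(flanked.chrom, flanked.start, flanked.end)
            loci.append(
                AnnotatedLocus(
                    locus=iv,
                    flanked=flanked,
                    accessible=atac.overlaps(flanked.chrom, flanked.start, flanked.end),
                    polii_bound=polii.overlaps(flanked.chrom, flanked.start, flanked.end),
                    genes=hit_genes,
                    factor_overlaps=factors,
                )
            )
        contacts.append(AnnotatedContact(read.read_id, loci))
    return contacts


# ---------------------------------------------------------------------------
# tiered cluster calling
# ---------------------------------------------------------------------------

def find_potential_clusters(
    contacts: Iterable[AnnotatedContact],
) -> list[TranscriptionCluster]:
    """Contacts (order >= 2) whose loci are all accessible with >= 1 Pol II locus."""
    out = []
    for contact in contacts:
        if contact.order < 2:
            continue
        if all(l.accessible for l in contact.loci) and any(
            l.polii_bound for l in contact.loci
        ):
            out.append(
                TranscriptionCluster(
                    contact,
                    STATUS_POTENTIAL,
                    expressed_genes=contact.expressed_genes,
                )
            )
    return out


def common_tfs(
    genes: Sequence[str], motifs: MotifTable, min_sites: int = DEFAULT_MIN_SITES
) -> list[str]:
    """TFs shared by a gene set: both genes if exactly two, strict majority if more."""
    if len(genes) < 2:
        return []
    need = 2 if len(genes) == 2 else len(genes) // 2 + 1
    shared = []
    for tf in motifs.tfs:
        bound = sum(motifs.binds(g, tf, min_sites) for g in genes)
        if bound >= need:
            shared.append(tf)
    return shared


def find_clusters(
    potential: Iterable[TranscriptionCluster],
    motifs: MotifTable,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[TranscriptionCluster]:
    """Promote potential clusters with >= 2 expressed genes sharing a TF."""
    promoted = []
    for cluster in potential:
        if len(cluster.expressed_genes) < 2:
            continue
        shared = common_tfs(cluster.expressed_genes, motifs, min_sites)
        if shared:
            cluster.status = STATUS_CLUSTER
            cluster.common_tfs = shared
            promoted.append(cluster)
    return promoted


def find_specialized(
    clusters: Iterable[TranscriptionCluster],
    motifs: MotifTable,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[TranscriptionCluster]:
    """Clusters where at least one common TF is a master regulator."""
    specialized = []
    for cluster in clusters:
        mrs = []
        for tf in cluster.common_tfs:
            if motifs.encoding_gene(tf) is None:
                logger.debug("TF %s has no mapped encoding gene; cannot be an MR", tf)
                continue
            if motifs.is_master_regulator(tf, min_sites):
                mrs.append(tf)
        if mrs:
            cluster.status = STATUS_SPECIALIZED
            cluster.common_mrs = mrs
            specialized.append(cluster)
    return specialized


def find_self_sustaining(
    clusters: Sequence[TranscriptionCluster],
    motifs: MotifTable,
    expression: Mapping[str, float] | None = None,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    min_sites: int = DEFAULT_MIN_SITES,
) -> SelfSustainingReport:
    """Flag self-sustaining and core clusters; report analog-independent classes.

    A cluster is self-sustaining when one of its expressed genes encodes a
    TF that also binds (>= ``min_sites`` motif occurrences) at least one gene
    in the same cluster; it is core when that TF is additionally a master
    regulator.  Class (c): the TF's gene is expressed in one cluster while
    the TF binds in a different cluster only.  Class (d), tallied from the
    genome-wide expression table when given: TF genes expressed nowhere in
    any cluster while the TF binds some cluster.
    """
    gene_to_tf: dict[str, list[str]] = {}
    for tf, gene in motifs.tf_gene.items():
        gene_to_tf.setdefault(gene, []).append(tf)

    # where does each TF bind (over clusters), and where is its gene expressed
    tf_binds_in: dict[str, set[int]] = {}
    tf_gene_expressed_in: dict[str, set[int]] = {}
    for idx, cluster in enumerate(clusters):
        genes = cluster.expressed_genes
        for tf in motifs.tfs:
            if any(motifs.binds(g, tf, min_sites) for g in genes):
                tf_binds_in.setdefault(tf, set()).add(idx)
        for gene in genes:
            for tf in gene_to_tf.get(gene, ()):
                tf_gene_expressed_in.setdefault(tf, set()).add(idx)

    report = SelfSustainingReport()
    for idx, cluster in enumerate(clusters):
        for gene in cluster.expressed_genes:
            for tf in gene_to_tf.get(gene, ()):
                if idx in tf_binds_in.get(tf, ()):
                    cluster.self_sustaining = True
                    if tf not in cluster.self_sustaining_tfs:
                        cluster.self_sustaining_tfs.append(tf)
                    if motifs.is_master_regulator(tf, min_sites):
                        cluster.core = True

    for tf, expressed_in in sorted(tf_gene_expressed_in.items()):
        binds_in = tf_binds_in.get(tf, set())
        for gene_idx in sorted(expressed_in):
            for bind_idx in sorted(binds_in - expressed_in):
                report.analog_independent_pairs.append((tf, gene_idx, bind_idx))

    if expression is not None:
        for tf in sorted(tf_binds_in):
            gene = motifs.encoding_gene(tf)
            if gene is None:
                continue
            expressed_genomewide = expression.get(gene, 0.0) >= expr_threshold
            if expressed_genomewide and not tf_gene_expressed_in.get(tf):
                report.unclustered_tf_genes.append(tf)
    return report


def identify_clusters(
    contacts: Sequence[AnnotatedContact],
    motifs: MotifTable,
    min_sites: int = DEFAULT_MIN_SITES,
    expression: Mapping[str, float] | None = None,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
) -> tuple[list[TranscriptionCluster], SelfSustainingReport]:
    """Run the full tiered pipeline; returns all potential clusters, annotated.

    The containment chain specialized <= cluster <= potential (and
    core <= self-sustaining <= cluster) holds by construction; statuses are
    escalated in place on the shared cluster objects.
    """
    potential = find_potential_clusters(contacts)
    clusters = find_clusters(potential, motifs, min_sites)
    find_specialized(clusters, motifs, min_sites)
    report = find_self_sustaining(
        clusters, motifs, expression, expr_threshold, min_sites
    )
    return potential, report


def cluster_table(clusters: Sequence[TranscriptionCluster]) -> pd.DataFrame:
    """One row per (potential) cluster with status, genes, TFs, MRs and flags."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "read_id": c.read_id,
                "order": c.order,
                "status": c.status,
                "expressed_genes": ",".join(c.expressed_genes),
                "common_tfs": ",".join(c.common_tfs),
                "common_mrs": ",".join(c.common_mrs),
                "self_sustaining": c.self_sustaining,
                "core": c.core,
                "enhancer_present": c.contact.factor_present("enhancer"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "order",
            "status",
            "expressed_genes",
            "common_tfs",
            "common_mrs",
            "self_sustaining",
            "core",
            "enhancer_present",
        ],
    )


def summary_table(clusters: Sequence[TranscriptionCluster]) -> pd.DataFrame:
    """Tiered counts: potential, >=1/>=2 expressed genes, common TFs, common MRs."""
    n_potential = len(clusters)
    n_ge1 = sum(len(c.expressed_genes) >= 1 for c in clusters)
    n_ge2 = sum(len(c.expressed_genes) >= 2 for c in clusters)
    n_tf = sum(bool(c.common_tfs) for c in clusters)
    n_mr = sum(bool(c.common_mrs) for c in clusters)
    return pd.DataFrame(
        {
            "tier": [
                "potential",
                "ge1_expressed_gene",
                "ge2_expressed_genes",
                "common_tfs",
                "common_mrs",
            ],
            "count": [n_potential, n_ge1, n_ge2, n_tf, n_mr],
        }
    )


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def binding_enrichment(
    clusters: Sequence[TranscriptionCluster],
    all_contacts: Sequence[AnnotatedContact],
    factor: str,
    n_trials: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """One-sided enrichment of a factor at clusters vs random contacts.

    The statistic is the fraction of contacts with >= 1 flanked locus
    overlapping a peak of ``factor`` (pre-computed during annotation).  The
    background redraws order-matched random contact samples of the same size
    ``n_trials`` times; p is the proportion of background fractions >= the
    observed cluster fraction.
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(
        np.mean([c.contact.factor_present(factor) for c in clusters])
    )
    by_order: dict[int, list[AnnotatedContact]] = {}
    for contact in all_contacts:
        by_order.setdefault(contact.order, []).append(contact)
    need = Counter(c.order for c in clusters)
    for order, count in need.items():
        pool = by_order.get(order, [])
        if not pool:
            raise ValueError(f"no contacts of order {order} to sample from")
        if count > len(pool):
            logger.warning(
                "requested %d contacts of order %d but only %d exist; "
                "sampling with replacement",
                count,
                order,
                len(pool),
            )
    background = np.empty(n_trials)
    for t in range(n_trials):
        hits = 0
        total = 0
        for order, count in need.items():
            pool = by_order[order]
            replace = count > len(pool)
            idx = rng.choice(len(pool), size=count, replace=replace)
            hits += sum(pool[i].factor_present(factor) for i in idx)
            total += count
        background[t] = hits / total
    p = float(np.mean(background >= observed))
    return EnrichmentResult(factor, observed, float(background.mean()), p, n_trials)


CRITERIA = ("ge1_gene", "ge2_genes", "common_tfs", "common_mrs")


def _criteria_flags(
    contact: AnnotatedContact, motifs: MotifTable, min_sites: int
) -> tuple[bool, bool, bool, bool]:
    genes = contact.expressed_genes
    ge1 = len(genes) >= 1
    ge2 = len(genes) >= 2
    shared = common_tfs(genes, motifs, min_sites) if ge2 else []
    has_tf = bool(shared)
    has_mr = any(motifs.is_master_regulator(tf, min_sites) for tf in shared)
    return ge1, ge2, has_tf, has_mr


def permutation_test_clusters(
    all_contacts: Sequence[AnnotatedContact],
    candidates: Sequence[TranscriptionCluster],
    motifs: MotifTable,
    min_sites: int = DEFAULT_MIN_SITES,
    n_trials: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation significance of the cluster-calling criteria, per order.

    Contacts and candidates are partitioned by order (3, 4, 5, 6+).  Per
    trial and order group, n random contacts are drawn (n = number of
    candidates of that order; with replacement, logged, if the pool is
    smaller) and the number satisfying each criterion (>=1 expressed gene,
    >=2 expressed genes, common TFs, common MRs) is counted.  The p-value
    per criterion is the proportion of trials whose background count >= the
    observed candidate count.  An "all" group pools the order groups.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def group_of(order: int) -> str | None:
        if order < 3:
            return None
        return "6+" if order >= 6 else str(order)

    flags_cache = [
        _criteria_flags(contact, motifs, min_sites) for contact in all_contacts
    ]
    pools: dict[str, list[int]] = {}
    for i, contact in enumerate(all_contacts):
        g = group_of(contact.order)
        if g is not None:
            pools.setdefault(g, []).append(i)

    observed: dict[str, np.ndarray] = {}
    n_candidates: dict[str, int] = {}
    for cand in candidates:
        g = group_of(cand.order)
        if g is None:
            continue
        genes = cand.expressed_genes
        shared = cand.common_tfs
        flags = np.array(
            [len(genes) >= 1, len(genes) >= 2, bool(shared), bool(cand.common_mrs)],
            dtype=int,
        )
        observed[g] = observed.get(g, np.zeros(4, dtype=int)) + flags
        n_candidates[g] = n_candidates.get(g, 0) + 1

    groups = sorted(observed, key=lambda g: (g == "6+", g))
    flag_matrix = np.array(flags_cache, dtype=int) if flags_cache else np.zeros((0, 4), int)
    bg_counts = {g: np.zeros((n_trials, 4), dtype=int) for g in groups}
    for g in groups:
        pool = pools.get(g, [])
        n = n_candidates[g]
        if not pool:
            raise ValueError(f"no contacts of order group {g} to sample from")
        replace = n > len(pool)
        if replace:
            logger.warning(
                "order group %s: %d candidates but only %d contacts; "
                "sampling with replacement",
                g,
                n,
                len(pool),
            )
        pool_arr = np.array(pool)
        for t in range(n_trials):
            idx = rng.choice(pool_arr, size=n, replace=replace)
            bg_counts[g][t] = flag_matrix[idx].sum(axis=0)

    rows = []
    for g in groups:
        for c_i, criterion in enumerate(CRITERIA):
            obs = int(observed[g][c_i])
            p = float(np.mean(bg_counts[g][:, c_i] >= obs))
            rows.append(
                {
                    "order": g,
                    "criterion": criterion,
                    "observed": obs,
                    "background_mean": float(bg_counts[g][:, c_i].mean()),
                    "p_value": p,
                    "n_trials": n_trials,
                }
            )
    if groups:
        total_obs = sum(observed[g] for g in groups)
        total_bg = sum(bg_counts[g] for g in groups)
        for c_i, criterion in enumerate(CRITERIA):
            obs = int(total_obs[c_i])
            rows.append(
                {
                    "order": "all",
                    "criterion": criterion,
                    "observed": obs,
                    "background_mean": float(total_bg[:, c_i].mean()),
                    "p_value": float(np.mean(total_bg[:, c_i] >= obs)),
                    "n_trials": n_trials,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["order", "criterion", "observed", "background_mean", "p_value", "n_trials"],
    )


# ---------------------------------------------------------------------------
# TF ranking
# ---------------------------------------------------------------------------

def rank_tfs(
    clusters: Sequence[TranscriptionCluster],
    motifs: MotifTable,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Rank TFs by the fraction of clusters where they bind >= 1 expressed gene."""
    if not clusters:
        raise ValueError("no clusters supplied")
    rows = []
    for tf in motifs.tfs:
        hits = sum(
            any(motifs.binds(g, tf, min_sites) for g in c.expressed_genes)
            for c in clusters
        )
        rows.append({"tf": tf, "frequency": hits / len(clusters)})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["frequency", "tf"], ascending=[False, True]
    ).reset_index(drop=True)


def tf_overlap(rank_a: pd.DataFrame, rank_b: pd.DataFrame, k: int = 10) -> float:
    """Fraction of the top-k TFs shared between two rankings."""
    top_a = set(rank_a["tf"].head(k))
    top_b = set(rank_b["tf"].head(k))
    return len(top_a & top_b) / k
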