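"""Build walks and the skew-symmetric edge set from placed annotations.

Construction reads each contig's placed, coordinate-sorted gene occurrences
as a walk; every consecutive pair becomes a directed edge (with its skew
twin).  Edge scores follow S(x|y) = mean over supporting contigs of the
alignment score of x's occurrence in the adjacency.

Two score-ratio heuristics then clean the graph:

* false edges (ratio r1, default 0.95): if some alternative adjacency x->z
  exists whose far gene never shares a contig with the far gene of x->y, and
  x scores clearly worse on the x->y side, the x occurrences realizing x->y
  are treated as misplaced paralogous hits and removed.  This repairs, e.g.,
  genomes that lack a chromosome entirely so that a gene's hits land on a
  paralogous locus of another chromosome.
* low-priority edges (ratio r2, default 0.98): when the competing far genes
  DO share a contig, the weaker adjacency's gene occurrences are only
  deprioritized — at re-annotation a competing unmarked gene wins the locus
  even at a slightly lower score.

Finally, gene- and edge-level operational filters prune promiscuous genes
(too many edges, too many distant loci), rare genes, single-exon genes and
weakly supported edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import OrientedGene, PangeneGraph, Walk, WalkStep, _canonical, flip
from .io import AlignmentHit
from .select import PlacedGene, place_annotations

log = logging.getLogger(__name__)


class BuildError(ValueError):
    pass


@dataclass
class BuildConfig:
    r1: float = 0.95
    r2: float = 0.98
    min_edge_support: int = 1
    max_gene_edges: int = 10
    max_distant_loci: int = 3
    min_gene_freq: float = 0.05
    drop_single_exon: bool = False
    locus_merge_distance: int = 100_000
    overlap_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.r1 <= 1 and 0 < self.r2 <= 1):
            raise ValueError("r1 and r2 must be in (0, 1]")
        if self.min_edge_support < 0 or self.max_gene_edges < 0 or self.max_distant_loci < 0:
            raise ValueError("thresholds must be non-negative")


#: one maximal run of placed genes on a contig (walks may be split by
#: edge pruning, hence possibly several segments per contig)
Segment = tuple[str, str, list[PlacedGene]]


def segments_from_placements(
    placements: dict[tuple[str, str], list[PlacedGene]]
) -> list[Segment]:
    return [
        (genome, contig, list(placed))
        for (genome, contig), placed in sorted(placements.items())
        if placed
    ]


def graph_from_segments(
    segments: Sequence[Segment],
    genomes: Sequence[str],
    meta: dict | None = None,
) -> PangeneGraph:
    """Assemble walks and skew-symmetric scored edges from placed genes."""
    g = PangeneGraph()
    g.meta["genomes"] = list(genomes)
    if meta:
        for k, v in meta.items():
            g.meta.setdefault(k, v)
    for genome, contig, placed in segments:
        if not placed:
            continue
        for a, b in zip(placed, placed[1:]):
            if b.tstart < a.tstart:
                raise BuildError(f"placed hits out of order on {genome}/{contig}")
            if b.tstart < a.tend:
                raise BuildError(
                    f"overlapping placed hits on {genome}/{contig}: "
                    f"{a.gene}@{a.tstart} vs {b.gene}@{b.tstart}"
                )
        steps = [WalkStep(p.hit.oriented(), p.tstart, p.tend) for p in placed]
        g.add_walk(Walk(genome, contig, steps))
        for a, b in zip(placed, placed[1:]):
            g.add_edge(
                a.hit.oriented(),
                b.hit.oriented(),
                support=(genome, contig),
                score_x=a.hit.score,
                score_y=b.hit.score,
            )
    return g


def build_graph(
    placements: dict[tuple[str, str], list[PlacedGene]],
    genomes: Sequence[str],
    cfg: BuildConfig | None = None,
    meta: dict | None = None,
) -> tuple[PangeneGraph, list[Segment]]:
    segments = segments_from_placements(placements)
    return graph_from_segments(segments, genomes, meta), segments


def edge_score(g: PangeneGraph, x: OrientedGene, y: OrientedGene) -> float:
    """S(x|y): arithmetic mean of x's placed-hit score over supporting contigs."""
    data = g.edge_data(x, y)
    if not data.support and data.n_support_hint is None:
        raise ValueError("edge has empty support")
    return g.score(x, y)


def _gene_contigs(segments: Sequence[Segment]) -> dict[str, dict[str, set[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    for genome, contig, placed in segments:
        for p in placed:
            out.setdefault(p.gene, {}).setdefault(genome, set()).add(contig)
    return out


def _never_share_contig(
    gene_contigs: dict[str, dict[str, set[str]]], u: str, w: str
) -> bool:
    """True when u and w lie on different contigs in every genome carrying
    both (genomes carrying at most one of them are ignored)."""
    cu = gene_contigs.get(u, {})
    cw = gene_contigs.get(w, {})
    for genome in cu.keys() & cw.keys():
        if cu[genome] & cw[genome]:
            return False
    return True


def _share_contig_somewhere(
    gene_contigs: dict[str, dict[str, set[str]]], u: str, w: str
) -> bool:
    cu = gene_contigs.get(u, {})
    cw = gene_contigs.get(w, {})
    return any(cu[genome] & cw[genome] for genome in cu.keys() & cw.keys())


def _mark_ratio_edges(
    g: PangeneGraph,
    segments: Sequence[Segment],
    ratio: float,
    contig_rule,
) -> list[tuple[OrientedGene, OrientedGene]]:
    """Directed views (x, y) such that some sibling x->z passes the contig
    rule on (gene(y), gene(z)) and S(x|y) < S(x|z) * ratio."""
    gene_contigs = _gene_contigs(segments)
    marked: list[tuple[OrientedGene, OrientedGene]] = []
    for x, y in g.directed_edges():
        sxy = g.score(x, y)
        for z in g.out_neighbors(x):
            if z == y or z.gene == y.gene:
                continue
            if not contig_rule(gene_contigs, y.gene, z.gene):
                continue
            if sxy < g.score(x, z) * ratio:
                marked.append((x, y))
                break
    return marked


def _steps_incident_to(
    segments: Sequence[Segment], marked: Iterable[tuple[OrientedGene, OrientedGene]]
) -> set[int]:
    """ids of PlacedGene objects of gene(x) realizing a marked adjacency x->y."""
    marked = set(marked)
    victims: set[int] = set()
    for _, _, placed in segments:
        for a, b in zip(placed, placed[1:]):
            pair = (a.hit.oriented(), b.hit.oriented())
            if pair in marked:
                victims.add(id(a))
            if (flip(pair[1]), flip(pair[0])) in marked:
                victims.add(id(b))
    return victims


def filter_false_edges(
    g: PangeneGraph,
    segments: Sequence[Segment],
    cfg: BuildConfig,
) -> tuple[PangeneGraph, list[Segment]]:
    """Remove misplaced gene occurrences behind cross-contig false edges.

    An edge x->y is false when an alternative x->z exists with gene(y) and
    gene(z) never co-resident on a contig and S(x|y) < S(x|z) * r1.  All
    placed hits of gene(x) realizing a false adjacency are deleted and the
    affected walks re-joined.
    """
    marked = _mark_ratio_edges(g, segments, cfg.r1, _never_share_contig)
    if not marked:
        return g, list(segments)
    for x, y in marked:
        data = g.edge_data(x, y)
        data.flags.add("false_edge")
        data.false_sources.add(x)
    victims = _steps_incident_to(segments, marked)
    new_segments: list[Segment] = []
    for genome, contig, placed in segments:
        kept = [p for p in placed if id(p) not in victims]
        if kept:
            new_segments.append((genome, contig, kept))
    log.info("false-edge filter: %d marked views, %d placed hits removed",
             len(marked), len(victims))
    g2 = graph_from_segments(new_segments, g.genomes(), meta=g.meta)
    return g2, new_segments


def mark_low_priority(
    g: PangeneGraph,
    segments: Sequence[Segment],
    cfg: BuildConfig,
    hit_pool: Sequence[AlignmentHit],
    selected: Iterable[str],
) -> tuple[PangeneGraph, list[Segment]]:
    """Deprioritize same-contig weaker adjacencies and re-annotate once.

    An edge x->y is low priority when an alternative x->z exists with
    gene(y) and gene(z) co-resident on some contig and S(x|y) < S(x|z) * r2.
    Placed hits of gene(x) realizing such an adjacency inherit the mark and
    lose locus competitions against unmarked genes during re-annotation.
    """
    marked = _mark_ratio_edges(g, segments, cfg.r2, _share_contig_somewhere)
    if not marked:
        return g, list(segments)
    for x, y in marked:
        data = g.edge_data(x, y)
        data.flags.add("low_priority")
        data.low_priority_sources.add(x)
    victims = _steps_incident_to(segments, marked)
    n_marked_hits = 0
    for _, _, placed in segments:
        for p in placed:
            if id(p) in victims and not p.hit.low_priority:
                p.hit.low_priority = True
                n_marked_hits += 1
    log.info("low-priority filter: %d marked views, %d hits deprioritized",
             len(marked), n_marked_hits)
    placements = place_annotations(hit_pool, selected, cfg.overlap_min)
    new_segments = segments_from_placements(placements)
    g2 = graph_from_segments(new_segments, g.genomes(), meta=g.meta)
    return g2, new_segments


def _locus_counts(segments: Sequence[Segment], merge_distance: int) -> dict[str, int]:
    """Max over genomes of the number of placed-hit clusters per gene."""
    per: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for genome, contig, placed in segments:
        for p in placed:
            per.setdefault((p.gene, genome), {}).setdefault(contig, []).append(
                (p.tstart, p.tend)
            )
    counts: dict[str, int] = {}
    for (gene, _), contigs in per.items():
        n = 0
        for ivs in contigs.values():
            ivs.sort()
            n += 1
            for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 - e0 > merge_distance:
                    n += 1
        counts[gene] = max(counts.get(gene, 0), n)
    return counts


def _drop_genes(segments: Sequence[Segment], drop: set[str]) -> list[Segment]:
    out: list[Segment] = []
    for genome, contig, placed in segments:
        kept = [p for p in placed if p.gene not in drop]
        if kept:
            out.append((genome, contig, kept))
    return out


def apply_gene_filters(
    g: PangeneGraph,
    segments: Sequence[Segment],
    cfg: BuildConfig,
    spliced_genes: set[str] | None = None,
) -> tuple[PangeneGraph, list[Segment]]:
    """Operational gene/edge filters, applied in a fixed order.

    1. genes with bidirected degree > max_gene_edges;
    2. genes placed at more than max_distant_loci distant loci (clusters of
       placed hits on one contig with gaps <= locus_merge_distance merged);
    3. genes present in fewer than min_gene_freq of the genomes;
    4. optionally, genes with no spliced alignment anywhere;
    5. edges supported by fewer than min_edge_support contigs (walks are
       split at the removed adjacency).

    Removing a gene elides its walk steps; flanking steps re-join, so new
    edges with merged support appear in the rebuilt graph.
    """
    genomes = g.genomes()
    meta = g.meta
    segments = list(segments)

    def rebuild() -> PangeneGraph:
        return graph_from_segments(segments, genomes, meta=meta)

    drop = {v for v in g.genes if g.gene_degree(v) > cfg.max_gene_edges}
    if drop:
        log.info("degree filter removed %d genes", len(drop))
        segments = _drop_genes(segments, drop)
        g = rebuild()

    loci = _locus_counts(segments, cfg.locus_merge_distance)
    drop = {v for v, n in loci.items() if n > cfg.max_distant_loci}
    if drop:
        log.info("distant-loci filter removed %d genes", len(drop))
        segments = _drop_genes(segments, drop)
        g = rebuild()

    if cfg.min_gene_freq > 0 and genomes:
        presence = g.gene_genomes()
        n = len(genomes)
        drop = {v for v in g.genes if len(presence.get(v, ())) / n < cfg.min_gene_freq}
        if drop:
            log.info("frequency filter removed %d genes", len(drop))
            segments = _drop_genes(segments, drop)
            g = rebuild()

    if cfg.drop_single_exon:
        if spliced_genes is None:
            spliced_genes = meta.get("spliced_genes", set())
        drop = {v for v in g.genes if v not in spliced_genes}
        if drop:
            log.info("single-exon filter removed %d genes", len(drop))
            segments = _drop_genes(segments, drop)
            g = rebuild()

    if cfg.min_edge_support > 1:
        weak = {
            (cx, cy)
            for cx, cy, data in g.canonical_edges()
            if data.n_support() < cfg.min_edge_support
        }
        if weak:
            log.info("support filter removed %d edges", len(weak))
            new_segments: list[Segment] = []
            for genome, contig, placed in segments:
                run: list[PlacedGene] = []
                for p in placed:
                    if run:
                        a, b = run[-1].hit.oriented(), p.hit.oriented()
                        cx, cy, _ = _canonical(a, b)
                        if (cx, cy) in weak:
                            new_segments.append((genome, contig, run))
                            run = []
                    run.append(p)
                if run:
                    new_segments.append((genome, contig, run))
            segments = new_segments
            g = rebuild()

    return g, segments
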