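"""End-to-end orchestration: alignment hits -> finalized pangenome gene graph.

Stage order: pseudogene suppression -> one protein per gene -> best hits ->
b(v) competition -> gene selection -> per-contig placement -> initial graph
-> false-edge filter -> low-priority re-annotation -> gene/edge filters.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .build import (
    BuildConfig,
    apply_gene_filters,
    build_graph,
    filter_false_edges,
    mark_low_priority,
)
from .core import PangeneGraph
from .io import AlignmentHit
from .select import (
    build_selection_state,
    choose_protein_per_gene,
    compute_b,
    filter_pseudogene_hits,
    place_annotations,
    select_genes,
)

log = logging.getLogger(__name__)


def build_pangenome_graph(
    hits: Sequence[AlignmentHit],
    genomes: Sequence[str] | None = None,
    cfg: BuildConfig | None = None,
    pseudogene_mode: str = "default",
    apply_adjustments: bool = True,
    apply_filters: bool = True,
) -> PangeneGraph:
    """Run the full annotation + graph construction pipeline.

    ``apply_adjustments`` toggles the r1/r2 score-ratio heuristics;
    ``apply_filters`` the operational gene/edge filters.  Both stay on for
    normal runs and can be switched off for controlled experiments.
    """
    cfg = cfg or BuildConfig()
    if genomes is None:
        genomes = sorted({h.genome for h in hits})
    n_in = len({h.gene for h in hits})
    hits = filter_pseudogene_hits(hits, pseudogene_mode)
    hits = choose_protein_per_gene(hits)
    state = build_selection_state(hits, genomes)
    compute_b(state, cfg.overlap_min)
    selected = select_genes(state, cfg.overlap_min)
    log.info("selection: %d genes in, %d selected", n_in, len(selected))
    spliced_genes = {h.gene for h in hits if h.n_introns >= 1}
    placements = place_annotations(hits, selected, cfg.overlap_min)
    meta = {
        "genomes": list(genomes),
        "spliced_genes": spliced_genes,
        "selected": list(selected),
    }
    g, segments = build_graph(placements, genomes, cfg, meta=meta)
    log.info("initial graph: %d genes, %d edges, %d walks",
             len(g.genes), g.n_edges(), len(g.walks))
    if apply_adjustments:
        g, segments = filter_false_edges(g, segments, cfg)
        g, segments = mark_low_priority(g, segments, cfg, hits, selected)
    if apply_filters:
        g, segments = apply_gene_filters(g, segments, cfg, spliced_genes)
    log.info("final graph: %d genes, %d edges, %d walks",
             len(g.genes), g.n_edges(), len(g.walks))
    return g
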