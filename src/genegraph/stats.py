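"""Presence/absence and copy-number summaries over a finalized graph.

Presence is counted from the walks of the final (filtered) graph, i.e. from
the tool's own per-genome annotation, not from raw alignment hits.  A gene
is *core* when present in at least a threshold fraction of the input
genomes (99% by default) and *accessory* otherwise.
"""

from __future__ import annotations

import pandas as pd

from .core import PangeneGraph

CORE = "core"
ACCESSORY = "accessory"


class PresenceMatrix:
    """Gene x genome copy-number table (walk-step counts)."""

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = table

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.table.columns)

    def copies(self, gene: str, genome: str) -> int:
        return int(self.table.at[gene, genome])

    def presence_fraction(self) -> pd.Series:
        if not self.genomes:
            return pd.Series(dtype=float)
        return (self.table > 0).sum(axis=1) / len(self.genomes)


def presence_matrix(g: PangeneGraph) -> PresenceMatrix:
    """Count gene occurrences per genome from the graph's walks."""
    genes = sorted(g.genes)
    genomes = g.genomes()
    table = pd.DataFrame(0, index=genes, columns=genomes, dtype=int)
    for w in g.walks:
        for s in w.steps:
            table.at[s.og.gene, w.genome] += 1
    return PresenceMatrix(table)


def classify_core(m: PresenceMatrix, core_threshold: float = 0.99) -> dict[str, str]:
    """Core/accessory classification at the given presence threshold."""
    if not (0 < core_threshold <= 1):
        raise ValueError("core_threshold must be in (0, 1]")
    frac = m.presence_fraction()
    return {gene: (CORE if frac.get(gene, 0.0) >= core_threshold else ACCESSORY)
            for gene in m.genes}


def pav_report(
    m: PresenceMatrix,
    g: PangeneGraph,
    min_freq: float = 0.5,
    multi_exon_only: bool = True,
) -> pd.DataFrame:
    """Genes present in at most ``min_freq`` of the genomes.

    With ``multi_exon_only`` the report is restricted to genes with a
    spliced alignment somewhere (single-exon entries are frequently
    processed pseudogenes or prediction artifacts).
    """
    frac = m.presence_fraction()
    spliced = g.meta.get("spliced_genes")
    rows = []
    for gene in m.genes:
        f = float(frac.get(gene, 0.0))
        if f > min_freq:
            continue
        if multi_exon_only and spliced is not None and gene not in spliced:
            continue
        counts = m.table.loc[gene]
        rows.append(
            {
                "gene": gene,
                "n_present": int((counts > 0).sum()),
                "fraction": f,
                "copy_min": int(counts.min()) if len(counts) else 0,
                "copy_max": int(counts.max()) if len(counts) else 0,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_present", "fraction", "copy_min", "copy_max"])


def write_presence_tsv(
    m: PresenceMatrix, classes: dict[str, str], path: str
) -> None:
    out = m.table.copy()
    out["class"] = [classes[gene] for gene in m.genes]
    out.to_csv(path, sep="\t", index_label="gene")
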