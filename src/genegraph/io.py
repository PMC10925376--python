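"""Readers and writers: miniprot-style PAF, GFA 1.1 with walks, TSV reports.

Conventions
-----------
* One PAF file corresponds to one genome (haplotype).
* All intervals are 0-based, half-open.  A "+" hit of a protein of gene v
  yields oriented gene >v, a "-" hit yields <v.
* The GFA writer emits version 1.1 with S (gene), L (adjacency) and W (walk)
  lines.  Self-defined tags: ``CN:i`` on S lines = number of genomes carrying
  the gene; ``NS:i`` on L lines = number of supporting contigs; ``SC:f`` /
  ``S2:f`` = mean source / destination alignment score of the two directed
  views of the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .core import (
    FORWARD,
    REVERSE,
    OrientedGene,
    PangeneGraph,
    Walk,
    WalkStep,
    og,
)

log = logging.getLogger(__name__)


class PafFormatError(ValueError):
    pass


class GfaFormatError(ValueError):
    pass


@dataclass
class PafOptions:
    """Parser options.

    score_tags: tag precedence for the alignment score (miniprot emits
    several score-like tags; the DP score ``AS`` is preferred).
    intron_ops: CIGAR operators counted as introns; miniprot's spliced
    dialect uses N (intron), U/V (introns with splice-site corrections).
    """

    score_tags: tuple[str, ...] = ("AS", "ms")
    intron_ops: frozenset = frozenset({"N", "U", "V"})


@dataclass
class AlignmentHit:
    """One protein-to-genome alignment record."""

    protein: str
    gene: str
    genome: str
    contig: str
    tstart: int
    tend: int
    strand: str
    score: float
    n_introns: int
    identity: float
    qcov: float
    low_priority: bool = False

    def oriented(self) -> OrientedGene:
        return OrientedGene(self.gene, FORWARD if self.strand == "+" else REVERSE)

    def length(self) -> int:
        return self.tend - self.tstart


def split_protein_name(name: str) -> tuple[str, str]:
    """Split ``<GeneID>:<ProteinID>`` into (gene, full protein name).

    A name without a colon denotes a gene with a single protein.
    """
    if not name:
        raise ValueError("empty protein name")
    if ":" in name:
        return name.split(":", 1)[0], name
    return name, name


def _count_introns(cigar: str, ops: frozenset) -> int:
    n = 0
    for ch in cigar:
        if ch in ops:
            n += 1
    return n


def parse_paf_line(
    line: str, genome: str, cfg: PafOptions, lineno: int = 0
) -> AlignmentHit:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafFormatError(f"malformed PAF at line {lineno}: expected >=12 columns, got {len(cols)}")
    try:
        qname = cols[0]
        qlen = int(cols[1])
        qstart, qend = int(cols[2]), int(cols[3])
        strand = cols[4]
        contig = cols[5]
        tstart, tend = int(cols[7]), int(cols[8])
        matches = int(cols[9])
        blocklen = int(cols[10])
    except ValueError as e:
        raise PafFormatError(f"malformed PAF at line {lineno}: {e}") from None
    if strand not in "+-":
        raise PafFormatError(f"malformed PAF at line {lineno}: bad strand {strand!r}")
    tags: dict[str, str] = {}
    for tag in cols[12:]:
        parts = tag.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    score: float | None = None
    for name in cfg.score_tags:
        if name in tags:
            score = float(tags[name])
            break
    if score is None:
        log.warning("line %d: no score tag among %s; falling back to residue matches",
                    lineno, cfg.score_tags)
        score = float(matches)
    cigar = tags.get("cg", "")
    gene, protein = split_protein_name(qname)
    identity = matches / blocklen if blocklen else 0.0
    qcov = (qend - qstart) / qlen if qlen else 0.0
    return AlignmentHit(
        protein=protein,
        gene=gene,
        genome=genome,
        contig=contig,
        tstart=tstart,
        tend=tend,
        strand=strand,
        score=score,
        n_introns=_count_introns(cigar, cfg.intron_ops),
        identity=identity,
        qcov=qcov,
    )


def read_paf(
    source: str | TextIO, genome: str, cfg: PafOptions | None = None
) -> list[AlignmentHit]:
    """Read one genome's protein-to-genome PAF alignments."""
    cfg = cfg or PafOptions()
    hits: list[AlignmentHit] = []

    def _consume(fh: TextIO) -> None:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            hits.append(parse_paf_line(line, genome, cfg, lineno=i))

    if hasattr(source, "read"):
        _consume(source)  # type: ignore[arg-type]
    else:
        with open(source) as fh:
            _consume(fh)
    return hits


# ---------------------------------------------------------------------------
# GFA 1.1
# ---------------------------------------------------------------------------

_GFA_ORIENT = {FORWARD: "+", REVERSE: "-"}
_GFA_ORIENT_REV = {"+": FORWARD, "-": REVERSE}


def write_gfa(g: PangeneGraph, path_or_fh: str | TextIO) -> None:
    """Serialize a finalized graph as GFA 1.1 (S/L/W lines)."""

    def _emit(fh: TextIO) -> None:
        fh.write("H\tVN:Z:1.1\n")
        per_gene_genomes = g.gene_genomes()
        lengths = g.meta.get("gene_lengths", {})
        for gene in sorted(g.genes):
            tags = []
            if gene in lengths:
                tags.append(f"LN:i:{lengths[gene]}")
            tags.append(f"CN:i:{len(per_gene_genomes.get(gene, ()))}")
            fh.write("\t".join(["S", gene, "*", *tags]) + "\n")
        for cx, cy, data in sorted(g.canonical_edges(), key=lambda e: (e[0], e[1])):
            tags = [f"NS:i:{data.n_support()}"]
            try:
                tags.append(f"SC:f:{data.score_src():g}")
                tags.append(f"S2:f:{data.score_dst():g}")
            except ValueError:
                pass
            fh.write(
                "\t".join(
                    ["L", cx.gene, _GFA_ORIENT[cx.orient], cy.gene,
                     _GFA_ORIENT[cy.orient], "0M", *tags]
                )
                + "\n"
            )
        for w in g.walks:
            if not w.steps:
                continue
            fh.write(
                "\t".join(
                    ["W", w.genome, "0", w.contig,
                     str(w.steps[0].start), str(w.steps[-1].end), w.walk_string()]
                )
                + "\n"
            )

    if hasattr(path_or_fh, "write"):
        _emit(path_or_fh)  # type: ignore[arg-type]
    else:
        with open(path_or_fh, "w") as fh:
            _emit(fh)


def _parse_walk_string(s: str) -> list[OrientedGene]:
    out: list[OrientedGene] = []
    token = ""
    for ch in s:
        if ch in (FORWARD, REVERSE):
            if token:
                out.append(og(token))
            token = ch
        else:
            token += ch
    if token:
        out.append(og(token))
    return out


def read_gfa(path_or_fh: str | TextIO) -> PangeneGraph:
    """Load a GFA 1.1 gene graph (S/L lines, optional W lines)."""

    def _consume(fh: TextIO) -> PangeneGraph:
        g = PangeneGraph()
        walk_specs: list[tuple[str, str, int, int, list[OrientedGene]]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            rec = cols[0]
            if rec == "H":
                for tag in cols[1:]:
                    if tag.startswith("VN:Z:"):
                        version = tag[5:]
                        if version.startswith("2"):
                            raise GfaFormatError(f"unsupported version {version}")
            elif rec == "S":
                if len(cols) < 3:
                    raise GfaFormatError(f"line {lineno}: short S-line")
                g.add_gene(cols[1])
                for tag in cols[3:]:
                    if tag.startswith("LN:i:"):
                        g.meta.setdefault("gene_lengths", {})[cols[1]] = int(tag[5:])
            elif rec == "L":
                if len(cols) < 6:
                    raise GfaFormatError(f"line {lineno}: short L-line")
                a, ao, b, bo = cols[1], cols[2], cols[3], cols[4]
                for seg in (a, b):
                    if seg not in g.genes:
                        raise GfaFormatError(f"line {lineno}: L-line references unknown segment {seg!r}")
                if ao not in _GFA_ORIENT_REV or bo not in _GFA_ORIENT_REV:
                    raise GfaFormatError(f"line {lineno}: bad orientation")
                x = OrientedGene(a, _GFA_ORIENT_REV[ao])
                y = OrientedGene(b, _GFA_ORIENT_REV[bo])
                data = g.add_edge(x, y)
                for tag in cols[6:]:
                    if tag.startswith("NS:i:"):
                        data.n_support_hint = int(tag[5:])
                    elif tag.startswith("SC:f:"):
                        data.score_src_hint = float(tag[5:])
                    elif tag.startswith("S2:f:"):
                        data.score_dst_hint = float(tag[5:])
                    else:
                        g.meta.setdefault("unknown_tags", []).append((lineno, tag))
            elif rec == "W":
                if len(cols) < 7:
                    raise GfaFormatError(f"line {lineno}: short W-line")
                genome, contig = cols[1], cols[3]
                start, end = int(cols[4]), int(cols[5])
                walk_specs.append((genome, contig, start, end, _parse_walk_string(cols[6])))
            elif rec in ("E", "G", "F", "O", "U"):
                raise GfaFormatError("unsupported version: GFA 2 record type " + rec)
        genomes: list[str] = []
        for genome, contig, start, end, ogs in walk_specs:
            if genome not in genomes:
                genomes.append(genome)
            for a, b in zip(ogs, ogs[1:]):
                if not g.has_edge(a, b):
                    raise GfaFormatError(
                        f"walk/edge inconsistency: {a.label()}->{b.label()} in walk "
                        f"{genome}/{contig} has no L-line"
                    )
                g.edge_data(a, b).support.add((genome, contig))
            # step coordinates are not stored per gene in GFA; synthesize
            # monotone placeholders inside the declared walk span
            steps = [WalkStep(x, start + i, start + i + 1) for i, x in enumerate(ogs)]
            g.add_walk(Walk(genome, contig, steps))
        if genomes:
            g.meta["genomes"] = genomes
        return g

    if hasattr(path_or_fh, "read"):
        return _consume(path_or_fh)  # type: ignore[arg-type]
    with open(path_or_fh) as fh:
        return _consume(fh)


def graphs_structurally_equal(a: PangeneGraph, b: PangeneGraph) -> bool:
    """Structural equality up to edge canonicalization and coordinates."""
    if a.genes != b.genes:
        return False
    if set((x, y) for x, y, _ in a.canonical_edges()) != set(
        (x, y) for x, y, _ in b.canonical_edges()
    ):
        return False
    wa = sorted((w.genome, w.contig, tuple(w.oriented_genes())) for w in a.walks)
    wb = sorted((w.genome, w.contig, tuple(w.oriented_genes())) for w in b.walks)
    return wa == wb


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

BUBBLE_TSV_HEADER = (
    "bubble_id\tentrance\texit\tn_interior_genes\tinterior_genes\t"
    "has_inversion\tn_distinct_walk_paths"
)


def write_bubble_tsv(bubbles: Sequence, g: PangeneGraph, path_or_fh: str | TextIO) -> None:
    """Write the bubble report; one row per generalized bibubble."""
    from .bubbles import bubble_has_inversion, count_walk_paths

    def _emit(fh: TextIO) -> None:
        fh.write(BUBBLE_TSV_HEADER + "\n")
        for i, bub in enumerate(bubbles, start=1):
            interior = ",".join(sorted(bub.interior))
            inv = bubble_has_inversion(g, bub)
            npaths = count_walk_paths(g, bub)
            fh.write(
                f"bb{i}\t{bub.entrance.label()}\t{bub.exit.label()}\t"
                f"{len(bub.interior)}\t{interior}\t{str(inv).lower()}\t{npaths}\n"
            )

    if hasattr(path_or_fh, "write"):
        _emit(path_or_fh)  # type: ignore[arg-type]
    else:
        with open(path_or_fh, "w") as fh:
            _emit(fh)
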