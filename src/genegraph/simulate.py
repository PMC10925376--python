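"""Seeded synthetic-pangenome generator with known ground truth.

The generator emulates the variation classes a gene graph is meant to
capture — gene deletions, inversions of short gene spans, tandem
duplications and cross-mapping paralogous families — at the alignment level:
it produces per-genome gene orders with coordinates and miniprot-style PAF
records, never sequence (the graph builder only consumes alignments).

Ground truth records every event, the per-genome walks, the expected copy
table and, for isolated events (kept >= ``min_event_spacing`` unaffected
genes away from other events and chromosome ends, across all genomes), the
expected bibubble: an event on span S flanked by unaffected genes a, b is
expected to surface as the bubble (>a, >b) with interior S.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .bubbles import Bibubble, canonical_bubble
from .core import FORWARD, REVERSE, OrientedGene

DEL, INV, DUP = "del", "inv", "dup"


@dataclass
class SimConfig:
    n_genes: int = 200
    n_genomes: int = 10
    n_chromosomes: int = 1
    p_del: float = 0.02
    p_inv: float = 0.01
    p_dup: float = 0.01
    inv_span: tuple[int, int] = (1, 3)
    paralog_families: int = 0
    paralog_score_ratio: float = 0.93
    score_base: int = 500
    score_noise: float = 0.01
    intergenic_gap: int = 5000
    gene_length: int = 1000
    intron_length: int = 200
    frac_single_exon: float = 0.0
    min_event_spacing: int | None = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_del, self.p_inv, self.p_dup):
            if not 0 <= p <= 1:
                raise ValueError("event probabilities must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class Event:
    genome: str
    kind: str
    chrom: str
    start_idx: int          # ancestral index within the chromosome
    genes: list[str]        # ancestral span affected
    extra_copies: int = 0   # tandem duplications only


@dataclass
class Truth:
    config: SimConfig
    genomes: list[str]
    chromosomes: dict[str, list[str]]                 # chrom -> ancestral order
    walks: dict[str, list[tuple[str, list[tuple[OrientedGene, int, int]]]]]
    events: list[Event]
    expected_bubbles: list[Bibubble]
    copy_table: dict[str, dict[str, int]]             # gene -> genome -> copies
    spliced: dict[str, bool] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def walk_specs(self) -> list[tuple[str, str, list[OrientedGene]]]:
        """(genome, contig, oriented genes) triples, e.g. for from_walks."""
        return [
            (genome, chrom, [og for og, _, _ in steps])
            for genome, per_chrom in self.walks.items()
            for chrom, steps in per_chrom
        ]


def _chromosome_split(genes: Sequence[str], n_chrom: int) -> dict[str, list[str]]:
    n = len(genes)
    per = math.ceil(n / n_chrom)
    return {
        f"chr{i + 1}": list(genes[i * per : (i + 1) * per])
        for i in range(n_chrom)
        if genes[i * per : (i + 1) * per]
    }


def simulate_pangenome(cfg: SimConfig, forced_events: Sequence[Event] | None = None) -> Truth:
    """Generate a pangenome with seeded events and full ground truth."""
    rng = random.Random(cfg.seed)
    genes = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]
    chroms = _chromosome_split(genes, cfg.n_chromosomes)
    genomes = [f"genome{i:02d}" for i in range(1, cfg.n_genomes + 1)]
    spliced = {g: rng.random() >= cfg.frac_single_exon for g in genes}

    spacing = cfg.min_event_spacing or 0
    affected: dict[str, set[int]] = {c: set() for c in chroms}
    events: list[Event] = []
    if forced_events is not None:
        events = list(forced_events)
        for ev in events:
            affected[ev.chrom].update(range(ev.start_idx, ev.start_idx + len(ev.genes)))
    else:
        p_any = cfg.p_del + cfg.p_inv + cfg.p_dup
        for genome in genomes:
            for chrom, order in chroms.items():
                i = 0
                while i < len(order):
                    u = rng.random()
                    if u >= p_any:
                        i += 1
                        continue
                    if u < cfg.p_del:
                        kind, span = DEL, 1
                    elif u < cfg.p_del + cfg.p_inv:
                        kind, span = INV, rng.randint(*cfg.inv_span)
                    else:
                        kind, span = DUP, 1
                    extra = rng.randint(1, 2) if kind == DUP else 0
                    lo, hi = i, i + span
                    ok = spacing <= lo and hi + spacing <= len(order)
                    if ok and spacing:
                        window = range(lo - spacing, hi + spacing)
                        ok = not any(j in affected[chrom] for j in window)
                    elif ok:
                        ok = not any(j in range(lo, hi) for j in affected[chrom])
                    if ok:
                        events.append(Event(genome, kind, chrom, lo, order[lo:hi], extra))
                        affected[chrom].update(range(lo, hi))
                        i = hi
                    else:
                        i += 1

    events_by_key: dict[tuple[str, str, int], Event] = {
        (ev.genome, ev.chrom, ev.start_idx): ev for ev in events
    }

    def extent(gene: str) -> int:
        return cfg.gene_length + (cfg.intron_length if spliced[gene] else 0)

    walks: dict[str, list[tuple[str, list[tuple[OrientedGene, int, int]]]]] = {}
    copy_table: dict[str, dict[str, int]] = {
        g: {gn: 0 for gn in genomes} for g in genes
    }
    for genome in genomes:
        per_chrom = []
        for chrom, order in chroms.items():
            ogs: list[OrientedGene] = []
            i = 0
            while i < len(order):
                ev = events_by_key.get((genome, chrom, i))
                if ev is None:
                    ogs.append(OrientedGene(order[i], FORWARD))
                    i += 1
                    continue
                if ev.kind == DEL:
                    i += len(ev.genes)
                elif ev.kind == DUP:
                    for _ in range(1 + ev.extra_copies):
                        ogs.append(OrientedGene(ev.genes[0], FORWARD))
                    i += len(ev.genes)
                else:  # inversion: reverse the span and flip orientations
                    for gname in reversed(ev.genes):
                        ogs.append(OrientedGene(gname, REVERSE))
                    i += len(ev.genes)
            steps = []
            pos = 0
            for x in ogs:
                e = extent(x.gene)
                steps.append((x, pos, pos + e))
                pos += e + cfg.intergenic_gap
                copy_table[x.gene][genome] += 1
            per_chrom.append((chrom, steps))
        walks[genome] = per_chrom

    expected: dict[tuple, Bibubble] = {}
    for ev in events:
        order = chroms[ev.chrom]
        lo, hi = ev.start_idx, ev.start_idx + len(ev.genes)
        if lo == 0 or hi >= len(order):
            continue  # no flank on one side: no localized bubble expected
        a, b = order[lo - 1], order[hi]
        bub = canonical_bubble(
            OrientedGene(a, FORWARD), OrientedGene(b, FORWARD), set(ev.genes)
        )
        expected[bub.key()] = bub

    paralog_pairs: list[tuple[str, str]] = []
    if cfg.paralog_families > 0:
        pool = [g for g in genes]
        rng.shuffle(pool)
        idx_of = {g: i for i, g in enumerate(genes)}
        while pool and len(paralog_pairs) < cfg.paralog_families:
            u = pool.pop()
            partner = next(
                (w for w in pool if abs(idx_of[u] - idx_of[w]) >= 10), None
            )
            if partner is None:
                break
            pool.remove(partner)
            paralog_pairs.append((u, partner))

    return Truth(
        config=cfg,
        genomes=genomes,
        chromosomes=chroms,
        walks=walks,
        events=events,
        expected_bubbles=sorted(expected.values(), key=lambda b: b.entrance.label()),
        copy_table=copy_table,
        spliced=spliced,
        paralog_pairs=paralog_pairs,
    )


# ---------------------------------------------------------------------------
# PAF emission
# ---------------------------------------------------------------------------


def _paf_line(
    gene: str,
    qlen: int,
    chrom: str,
    chrom_len: int,
    tstart: int,
    tend: int,
    strand: str,
    score: int,
    spliced_gene: bool,
    intron_len: int,
) -> str:
    blocklen = tend - tstart - (intron_len if spliced_gene else 0)
    matches = blocklen  # simulator emits clean alignments; identity 1.0
    if spliced_gene:
        half = blocklen // 2
        cg = f"{half}M{intron_len}N{blocklen - half}M"
    else:
        cg = f"{blocklen}M"
    return "\t".join(
        [
            gene,
            str(qlen),
            "0",
            str(qlen),
            strand,
            chrom,
            str(chrom_len),
            str(tstart),
            str(tend),
            str(matches),
            str(blocklen),
            "60",
            f"AS:i:{score}",
            f"cg:Z:{cg}",
        ]
    )


def emit_paf(truth: Truth) -> dict[str, str]:
    """One PAF text per genome: a record per gene occurrence, plus paralog
    cross-hits at partner loci at the family score ratio."""
    cfg = truth.config
    rng = random.Random((cfg.seed ^ 0x9E3779B9) & 0x7FFFFFFF)
    qlen = cfg.gene_length // 3
    partner: dict[str, list[str]] = {}
    for u, v in truth.paralog_pairs:
        partner.setdefault(u, []).append(v)
        partner.setdefault(v, []).append(u)

    def noisy(base: float) -> int:
        return max(1, round(base * (1 + rng.gauss(0, cfg.score_noise))))

    out: dict[str, str] = {}
    for genome in truth.genomes:
        lines: list[tuple[str, int, str]] = []
        for chrom, steps in truth.walks[genome]:
            chrom_len = (steps[-1][2] + cfg.intergenic_gap) if steps else 0
            for x, start, end in steps:
                strand = "+" if x.orient == FORWARD else "-"
                lines.append(
                    (
                        chrom,
                        start,
                        _paf_line(
                            x.gene, qlen, chrom, chrom_len, start, end, strand,
                            noisy(cfg.score_base), truth.spliced[x.gene],
                            cfg.intron_length,
                        ),
                    )
                )
                for other in partner.get(x.gene, ()):
                    lines.append(
                        (
                            chrom,
                            start,
                            _paf_line(
                                other, qlen, chrom, chrom_len, start, end, strand,
                                noisy(cfg.score_base * cfg.paralog_score_ratio),
                                truth.spliced[other], cfg.intron_length,
                            ),
                        )
                    )
        lines.sort(key=lambda t: (t[0], t[1], t[2]))
        out[genome] = "\n".join(l for _, _, l in lines) + ("\n" if lines else "")
    return out


def write_simulation(truth: Truth, outdir: str) -> None:
    """Write <genome>.paf files and truth.json into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    for genome, text in emit_paf(truth).items():
        with open(os.path.join(outdir, f"{genome}.paf"), "w") as fh:
            fh.write(text)
    doc = {
        "config": asdict(truth.config),
        "genomes": truth.genomes,
        "chromosomes": truth.chromosomes,
        "walks": {
            genome: [
                {
                    "contig": chrom,
                    "steps": [[x.label(), s, e] for x, s, e in steps],
                }
                for chrom, steps in per_chrom
            ]
            for genome, per_chrom in truth.walks.items()
        },
        "events": [asdict(ev) for ev in truth.events],
        "expected_bubbles": [
            [b.entrance.label(), b.exit.label(), sorted(b.interior)]
            for b in truth.expected_bubbles
        ],
        "copy_table": truth.copy_table,
        "spliced": truth.spliced,
        "paralog_pairs": truth.paralog_pairs,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Focused scenarios
# ---------------------------------------------------------------------------


def simulate_ortholog_pair(
    n_genomes: int = 4, first_better_in: int = 3, seed: int = 7
) -> tuple[dict[str, str], dict]:
    """Two redundant input genes ("alleles") mapping to one locus.

    Genes ALLELE_A and ALLELE_B hit the same locus in every genome; A wins
    in ``first_better_in`` genomes, B in the rest.  Flanks F1/F2 are clean.
    Exactly one of A/B should survive gene selection.
    """
    genomes = [f"genome{i:02d}" for i in range(1, n_genomes + 1)]
    qlen, glen, intron = 333, 1000, 200
    chrom_len = 20_000
    out = {}
    for i, genome in enumerate(genomes):
        a_score, b_score = (500, 480) if i < first_better_in else (480, 500)
        rows = [
            _paf_line("F1", qlen, "c1", chrom_len, 0, glen + intron, "+", 500, True, intron),
            _paf_line("ALLELE_A", qlen, "c1", chrom_len, 6000, 6000 + glen + intron, "+", a_score, True, intron),
            _paf_line("ALLELE_B", qlen, "c1", chrom_len, 6000, 6000 + glen + intron, "+", b_score, True, intron),
            _paf_line("F2", qlen, "c1", chrom_len, 12000, 12000 + glen + intron, "+", 500, True, intron),
        ]
        out[genome] = "\n".join(rows) + "\n"
    expected_winner = "ALLELE_A" if first_better_in * 2 > n_genomes else "ALLELE_B"
    return out, {"genomes": genomes, "alleles": ("ALLELE_A", "ALLELE_B"),
                 "expected_winner_majority": expected_winner}


def simulate_chromosome_loss(
    n_genomes: int = 4, n_lost: int = 2, paralog_score_ratio: float = 0.93, seed: int = 7
) -> tuple[dict[str, str], dict]:
    """A gene whose true chromosome is absent from some genomes.

    Gene GX lives on chrX between X1 and X2.  Genomes lacking chrX align GX
    to a weaker paralogous site on chrA between A1 and A2, creating spurious
    cross-chromosome adjacencies that the false-edge filter (r1) must remove.
    """
    genomes = [f"genome{i:02d}" for i in range(1, n_genomes + 1)]
    lost = set(genomes[-n_lost:]) if n_lost else set()
    qlen, glen, intron = 333, 1000, 200
    chrom_len = 20_000
    cross_score = round(500 * paralog_score_ratio)
    out = {}
    for genome in genomes:
        rows = [
            _paf_line("A1", qlen, "chrA", chrom_len, 0, glen + intron, "+", 500, True, intron),
            _paf_line("A2", qlen, "chrA", chrom_len, 6000, 6000 + glen + intron, "+", 500, True, intron),
        ]
        if genome in lost:
            rows.insert(
                1,
                _paf_line("GX", qlen, "chrA", chrom_len, 3000, 3000 + glen + intron, "+",
                          cross_score, True, intron),
            )
        else:
            rows += [
                _paf_line("X1", qlen, "chrX", chrom_len, 0, glen + intron, "+", 500, True, intron),
                _paf_line("GX", qlen, "chrX", chrom_len, 6000, 6000 + glen + intron, "+", 500, True, intron),
                _paf_line("X2", qlen, "chrX", chrom_len, 12000, 12000 + glen + intron, "+", 500, True, intron),
            ]
        out[genome] = "\n".join(rows) + "\n"
    truth_chrom = {"A1": "chrA", "A2": "chrA", "X1": "chrX", "GX": "chrX", "X2": "chrX"}
    true_edges = {frozenset(p) for p in (("A1", "A2"), ("X1", "GX"), ("GX", "X2"))}
    return out, {"genomes": genomes, "lost": sorted(lost),
                 "gene_chrom": truth_chrom, "true_edges": true_edges}
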