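"""Tiny reference graphs used across tests, docs and examples.

TOY1 — deletion:          g1/c1 = >A >B >C     g2/c2 = >A >C
TOY2 — inversion:         g1/c1 = >A >B >C     g2/c2 = >A <B >C
TOY3 — tandem CNV:        g1/c1 = >A >B >C     g2/c2 = >A >B >B >C

Each yields exactly one generalized bibubble, (>A, >C) with interior {B}.
"""

from __future__ import annotations

from .core import PangeneGraph, from_walks


def toy1() -> PangeneGraph:
    return from_walks(
        [("g1", "c1", [">A", ">B", ">C"]), ("g2", "c2", [">A", ">C"])]
    )


def toy2() -> PangeneGraph:
    return from_walks(
        [("g1", "c1", [">A", ">B", ">C"]), ("g2", "c2", [">A", "<B", ">C"])]
    )


def toy3() -> PangeneGraph:
    return from_walks(
        [("g1", "c1", [">A", ">B", ">C"]), ("g2", "c2", [">A", ">B", ">B", ">C"])]
    )


def toy_parallel() -> PangeneGraph:
    """Two alternative middle genes: >A>B>C and >A>D>C."""
    return from_walks(
        [("g1", "c1", [">A", ">B", ">C"]), ("g2", "c2", [">A", ">D", ">C"])]
    )


def chain(n: int = 3, genome: str = "g1", contig: str = "c1") -> PangeneGraph:
    """A single-genome linear chain >A1 >A2 ... >An (no variation)."""
    return from_walks([(genome, contig, [f">A{i}" for i in range(1, n + 1)])])
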