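"""Worked block-level fixtures for the trnQ-UUG repeat-tracing scenarios.

The published narrative names only a handful of the 33 locally collinear
blocks (LCBs 1, 2, 11, 12, 25, 29); the remaining block content is graphical
and not printed.  These fixtures therefore encode exactly the named blocks
in their narrated adjacencies and fill the rest of the circle with filler
blocks, which is sufficient for the traces to be well defined at gene-order
resolution.

Two scenarios are provided:

* :func:`sciadopitys_to_taxus_trace` — the tandem trnQ-UUG pair of the
  Sciadopitys-like arrangement sits between LCB 25 and LCB 1.  An inversion
  between LCB 29 and LCB 1 brings LCB 1 (with the pair) next to LCB 2,
  giving the ancestral arrangement (A22) with the gene order
  rps16–chlB–trnQ–trnQ–psbK–psbI.  A second inversion between LCB 1 and
  LCB 11, cutting between the two copies, splits the pair: one copy stays
  near rps16/chlB (LCB 2), the other near psbK/psbI (LCB 1), in opposite
  orientations — the short inverted repeat.

* :func:`cupressaceae_ancestor_to_cunninghamia_trace` — the Cupressaceae
  ancestor (A25) carries the tandem pair between LCB 1 and LCB 12 plus a
  third copy inside LCB 2.  One inversion between LCB 12 and LCB 29,
  cutting between the pair, leaves three trnQ-bearing loci (LCB 2, 1 and
  12), two copies in one orientation and one in the other.
"""

from __future__ import annotations

from .rearrangement import Inversion, SignedCircularPermutation
from .repeat_trace import (
    InternalAnchor,
    JunctionAnchor,
    RepeatConfiguration,
    RepeatCopy,
    TracedInversion,
)

__all__ = [
    "sciadopitys_to_taxus_trace",
    "cupressaceae_ancestor_to_cunninghamia_trace",
]

N_BLOCKS = 33
TRNQ = "trnQ-UUG"


def _a22_like() -> RepeatConfiguration:
    """Ancestral (A22-like) arrangement: ... 29 25 ... 2 | QQ | 1 11 ..."""
    fillers1 = [3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16, 17, 18]
    fillers2 = [19, 20, 21, 22, 23, 24, 26, 27, 28, 30, 31, 32, 33]
    order = [1, 11] + fillers1 + [29, 25] + fillers2 + [2]
    assert sorted(order) == list(range(1, N_BLOCKS + 1))
    perm = SignedCircularPermutation(order)
    copies = [
        RepeatCopy(f"{TRNQ}#1", "+", JunctionAnchor(left=2, right=1, slot=0)),
        RepeatCopy(f"{TRNQ}#2", "+", JunctionAnchor(left=2, right=1, slot=1)),
    ]
    return RepeatConfiguration.build(perm, copies)


def sciadopitys_to_taxus_trace():
    """Initial configuration and traced steps for the pair-splitting scenario.

    Returns ``(start, steps, names)`` where ``start`` is the
    Sciadopitys-like configuration (tandem pair between LCB 25 and LCB 1),
    ``steps`` are the two traced inversions, and ``names`` label the three
    stages (Sciadopitys-like, A22, Taxus-like).
    """
    from .repeat_trace import apply_inversion_traced

    a22 = _a22_like()
    # the inversion between LCB 29 and LCB 1 (an involution): applying it to
    # the ancestral arrangement recovers the Sciadopitys-like one and vice
    # versa; the cut at the copy-bearing junction keeps the pair outside
    step1 = TracedInversion(Inversion(18, N_BLOCKS), cut_slots=(0, 2))
    start = apply_inversion_traced(a22, step1)
    # inversion between LCB 1 and LCB 11, cutting between the two copies
    step2 = TracedInversion(Inversion(1, N_BLOCKS), cut_slots=(0, 1))
    names = ["Sciadopitys-like", "A22", "Taxus-like"]
    return start, [step1, step2], names


def cupressaceae_ancestor_to_cunninghamia_trace():
    """A25-like configuration and the single traced inversion.

    Returns ``(start, steps, names)``: the tandem pair sits between LCB 1
    and LCB 12, a third copy inside LCB 2; the inversion between LCB 12 and
    LCB 29 cuts between the pair.
    """
    fillers_c = [3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 14, 15, 16]
    fillers_d = [17, 18, 19, 20, 21, 22, 23, 24]
    fillers_e = [25, 26, 27, 28, 30, 31, 32, 33]
    order = [1, 12] + fillers_c + [29] + fillers_d + [2] + fillers_e
    assert sorted(order) == list(range(1, N_BLOCKS + 1))
    perm = SignedCircularPermutation(order)
    copies = [
        RepeatCopy(f"{TRNQ}#1", "+", JunctionAnchor(left=1, right=12, slot=0)),
        RepeatCopy(f"{TRNQ}#2", "+", JunctionAnchor(left=1, right=12, slot=1)),
        RepeatCopy(f"{TRNQ}#3", "+", InternalAnchor(block=2, offset=0.5)),
    ]
    start = RepeatConfiguration.build(perm, copies)
    # cut between the two tandem copies and just after LCB 29
    step = TracedInversion(Inversion(1, 16), cut_slots=(1, 0))
    names = ["A25-like", "Cunninghamia-like"]
    return start, [step], names
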