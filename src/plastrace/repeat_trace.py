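"""Tracing oriented repeat copies through inversion scenarios.

The mechanism studied here is how a plastome gains a short inverted repeat
(sIR): a gene such as trnQ-UUG first duplicates in place (a tandem repeat),
and a later inversion whose cut point falls *between* the two copies carries
one copy away in flipped orientation, leaving two dispersed copies in
opposite orientations — an sIR.

Repeat copies are modelled as zero-length oriented markers, because the
reasoning operates at gene-order (block) resolution.  A copy is anchored
either at a junction between two blocks (with a slot index when several
copies share the junction) or inside a block (with an offset fraction, to
express "inside LCB k"); internal copies travel and flip with their block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

from .rearrangement import (
    Inversion,
    InversionScenario,
    SignedCircularPermutation,
)

__all__ = [
    "RepeatCopy",
    "JunctionAnchor",
    "InternalAnchor",
    "RepeatConfiguration",
    "ArrangementClass",
    "TracedInversion",
    "apply_inversion_traced",
    "trace_scenario",
    "classify_arrangement",
    "count_repeat_loci",
    "config_to_json",
    "config_from_json",
    "scenario_from_json",
]


@dataclass(frozen=True)
class JunctionAnchor:
    """Between the blocks ``left`` and ``right`` (signed ids as read)."""

    left: int
    right: int
    slot: int = 0


@dataclass(frozen=True)
class InternalAnchor:
    """Inside block ``block`` at fractional offset ``offset`` from its start."""

    block: int
    offset: float = 0.5


@dataclass(frozen=True)
class RepeatCopy:
    """An oriented, labelled repeat copy (e.g. ``trnQ-UUG#1``)."""

    label: str
    orientation: str  # '+' or '-'
    anchor: Union[JunctionAnchor, InternalAnchor]

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


ArrangementClass = Literal[
    "tandem_forward",
    "adjacent_inverted",
    "dispersed_forward",
    "dispersed_inverted",
    "single",
    "multi_copy_mixed",
]


@dataclass(frozen=True)
class _Block:
    """Internal item: a signed block possibly carrying internal copies."""

    id: int  # signed
    internal: tuple[tuple[str, str, float], ...] = ()  # (label, orient, offset)


@dataclass(frozen=True)
class _Marker:
    """Internal item: a free-standing junction copy."""

    label: str
    orientation: str


@dataclass(frozen=True)
class RepeatConfiguration:
    """A circular block arrangement interleaved with oriented repeat copies."""

    items: tuple[Union[_Block, _Marker], ...]

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls,
        permutation: SignedCircularPermutation,
        copies: Sequence[RepeatCopy],
    ) -> "RepeatConfiguration":
        """Assemble from a permutation plus anchored copies.

        Junction anchors name the (signed) blocks flanking the copy as read
        in the permutation's stored order; several copies at one junction
        are laid out by slot index.
        """
        blocks = list(permutation.blocks)
        n = len(blocks)
        internal: dict[int, list[tuple[float, RepeatCopy]]] = {}
        at_junction: dict[int, list[tuple[int, RepeatCopy]]] = {}
        for copy in copies:
            a = copy.anchor
            if isinstance(a, InternalAnchor):
                idx = _index_of_block(blocks, a.block)
                internal.setdefault(idx, []).append((a.offset, copy))
            else:
                # wrap-junction copies (between last and first block) are
                # stored at the list tail, keyed as junction n
                for j in range(n):
                    if blocks[j] == a.left and blocks[(j + 1) % n] == a.right:
                        at_junction.setdefault(j + 1, []).append((a.slot, copy))
                        break
                else:
                    raise ValueError(
                        f"no junction {a.left}|{a.right} in permutation"
                    )
        items: list[Union[_Block, _Marker]] = []
        for j in range(n):
            for _, copy in sorted(at_junction.get(j, []), key=lambda t: t[0]):
                items.append(_Marker(copy.label, copy.orientation))
            carried = tuple(
                (c.label, c.orientation, off)
                for off, c in sorted(internal.get(j, []), key=lambda t: t[0])
            )
            items.append(_Block(blocks[j], carried))
        for _, copy in sorted(at_junction.get(n, []), key=lambda t: t[0]):
            items.append(_Marker(copy.label, copy.orientation))
        return cls(tuple(items))

    # -- views --------------------------------------------------------------

    @property
    def permutation(self) -> SignedCircularPermutation:
        return SignedCircularPermutation(
            [it.id for it in self.items if isinstance(it, _Block)]
        )

    @property
    def copies(self) -> list[RepeatCopy]:
        """All copies with their current anchors, in reading order."""
        items = self.items
        m = len(items)
        out: list[RepeatCopy] = []
        for i, it in enumerate(items):
            if isinstance(it, _Marker):
                left = _neighbour_block(items, i, -1)
                right = _neighbour_block(items, i, +1)
                slot = 0
                k = i - 1
                while k >= 0 or True:
                    prev = items[k % m]
                    if isinstance(prev, _Marker):
                        slot += 1
                        k -= 1
                    else:
                        break
                out.append(
                    RepeatCopy(
                        it.label,
                        it.orientation,
                        JunctionAnchor(left, right, slot),
                    )
                )
            else:
                for label, orient, off in it.internal:
                    out.append(
                        RepeatCopy(label, orient, InternalAnchor(it.id, off))
                    )
        return out

    def copies_with_prefix(self, prefix: str) -> list[RepeatCopy]:
        return [c for c in self.copies if c.label.startswith(prefix)]

    def __str__(self) -> str:
        parts = []
        for it in self.items:
            if isinstance(it, _Marker):
                parts.append(f"[{it.orientation}{it.label}]")
            else:
                parts.append(f"{it.id:+d}" + (
                    "{" + ",".join(f"{o}{l}" for l, o, _ in it.internal) + "}"
                    if it.internal else ""
                ))
        return " ".join(parts)


def _index_of_block(blocks: Sequence[int], signed_id: int) -> int:
    for i, b in enumerate(blocks):
        if b == signed_id or abs(b) == abs(signed_id):
            return i
    raise ValueError(f"block {signed_id} not in permutation")


def _neighbour_block(items, i: int, step: int) -> int:
    m = len(items)
    k = (i + step) % m
    while not isinstance(items[k], _Block):
        k = (k + step) % m
    return items[k].id


@dataclass(frozen=True)
class TracedInversion:
    """An inversion plus the slot choice at each copy-bearing cut junction.

    ``cut_slots = (s_i, s_j)``: at a cut junction hosting ``m`` copies there
    are ``m + 1`` gaps.  Each slot counts the copies *excluded* from the
    inverted segment — at the left cut the ``s_i`` copies nearest the
    outside (leftmost) stay out, at the right cut the ``s_j`` rightmost
    ones.  ``None`` means all copies at that junction stay outside (the gap
    nearest the segment).  Counting each side outward-in makes a traced
    inversion an involution: re-applying the same cuts restores the
    configuration.
    """

    inversion: Inversion
    cut_slots: tuple[Optional[int], Optional[int]] = (None, None)


def _flip(item):
    if isinstance(item, _Marker):
        return _Marker(item.label, "-" if item.orientation == "+" else "+")
    return _Block(
        -item.id,
        tuple(
            (l, "-" if o == "+" else "+", 1.0 - off)
            for l, o, off in reversed(item.internal)
        ),
    )


def apply_inversion_traced(
    config: RepeatConfiguration,
    inv: Union[Inversion, TracedInversion],
) -> RepeatConfiguration:
    """Apply an inversion to the blocks *and* the repeat copies.

    Blocks and junction copies inside the cut segment are order-reversed and
    orientation-flipped; internal copies flip with their block.  Copy count
    is conserved.
    """
    if isinstance(inv, Inversion):
        inv = TracedInversion(inv)
    items = config.items
    blocks_idx = [i for i, it in enumerate(items) if isinstance(it, _Block)]
    n = len(blocks_idx)
    i, j = inv.inversion.i, inv.inversion.j
    if not (0 <= i < j <= n):
        raise ValueError(f"cut points ({i}, {j}) invalid for {n} blocks")

    def junction_markers(junction: int) -> tuple[int, int]:
        """(first marker item index, marker count) at a block junction."""
        blk_item = blocks_idx[junction % n]
        first_marker = blk_item
        while first_marker - 1 >= 0 and isinstance(items[first_marker - 1], _Marker):
            first_marker -= 1
        return first_marker, blk_item - first_marker

    def check(slot: int, m: int) -> int:
        if not (0 <= slot <= m):
            raise ValueError(f"slot {slot} invalid at a junction hosting {m} copies")
        return slot

    # the segment [i, j) is inverted; each slot counts the copies staying
    # outside the segment on its own side (left cut: leftmost copies stay
    # out; right cut: rightmost copies stay out)
    first_i, m_i = junction_markers(i)
    s_i = m_i if inv.cut_slots[0] is None else check(inv.cut_slots[0], m_i)
    left = first_i + s_i
    if j == n:
        # junction n is the wrap gap before block 0 == end of the item list;
        # markers at the wrap junction sit at the list tail
        tail = len(items)
        while tail - 1 >= 0 and isinstance(items[tail - 1], _Marker):
            tail -= 1
        m_j = len(items) - tail
        s_j = m_j if inv.cut_slots[1] is None else check(inv.cut_slots[1], m_j)
        right = tail + (m_j - s_j)
    else:
        first_j, m_j = junction_markers(j)
        s_j = m_j if inv.cut_slots[1] is None else check(inv.cut_slots[1], m_j)
        right = first_j + (m_j - s_j)
    if right < left:
        raise ValueError("cut positions cross; check slot choices")
    seg = tuple(_flip(it) for it in reversed(items[left:right]))
    return RepeatConfiguration(items[:left] + seg + items[right:])


def trace_scenario(
    config: RepeatConfiguration,
    scenario: Union[InversionScenario, Sequence[TracedInversion]],
) -> list[RepeatConfiguration]:
    """Stepwise configurations: first is the input, last the final state."""
    if isinstance(scenario, InversionScenario):
        steps: Sequence[TracedInversion] = [
            TracedInversion(s) for s in scenario.steps
        ]
    else:
        steps = list(scenario)
    out = [config]
    for step in steps:
        out.append(apply_inversion_traced(out[-1], step))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _adjacent(config: RepeatConfiguration, label_a: str, label_b: str) -> bool:
    """True when no block lies between the two junction copies."""
    items = config.items
    m = len(items)
    pos = {
        it.label: i for i, it in enumerate(items) if isinstance(it, _Marker)
    }
    if label_a not in pos or label_b not in pos:
        return False  # internal copies are never junction-adjacent
    a, b = pos[label_a], pos[label_b]
    for lo, hi in ((a, b), (b, a)):
        span = range(lo + 1, hi) if hi > lo else [
            x % m for x in range(lo + 1, hi + m)
        ]
        if all(isinstance(items[x % m], _Marker) for x in span):
            return True
    return False


def _pair_class(config, ca: RepeatCopy, cb: RepeatCopy) -> ArrangementClass:
    same = ca.orientation == cb.orientation
    if _adjacent(config, ca.label, cb.label):
        return "tandem_forward" if same else "adjacent_inverted"
    return "dispersed_forward" if same else "dispersed_inverted"


def classify_arrangement(
    config: RepeatConfiguration, label_prefix: str
):
    """Classify the arrangement of the copies whose labels share a prefix.

    Returns the class for one or two copies; for three or more, returns
    ``("multi_copy_mixed", {pair: class, ...})`` with a per-pair sub-report.
    """
    copies = config.copies_with_prefix(label_prefix)
    if not copies:
        raise ValueError(f"no repeat copies with prefix {label_prefix!r}")
    if len(copies) == 1:
        return "single"
    if len(copies) == 2:
        return _pair_class(config, copies[0], copies[1])
    report = {}
    for x in range(len(copies)):
        for y in range(x + 1, len(copies)):
            report[(copies[x].label, copies[y].label)] = _pair_class(
                config, copies[x], copies[y]
            )
    return ("multi_copy_mixed", report)


def count_repeat_loci(config: RepeatConfiguration, label_prefix: str) -> int:
    """Distinct anchors hosting matching copies; a tandem cluster is one locus."""
    items = config.items
    m = len(items)
    matching = [
        i
        for i, it in enumerate(items)
        if isinstance(it, _Marker) and it.label.startswith(label_prefix)
    ]
    loci = 0
    for i in matching:
        prev = items[(i - 1) % m]
        if isinstance(prev, _Marker) and prev.label.startswith(label_prefix):
            continue  # same cluster as the previous marker
        loci += 1
    # a cluster can wrap: if every item is a marker this collapses to 1
    if matching and loci == 0:
        loci = 1
    for it in items:
        if isinstance(it, _Block):
            if any(l.startswith(label_prefix) for l, _, _ in it.internal):
                loci += 1
    return loci


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def config_to_json(config: RepeatConfiguration) -> dict:
    """Serialisable form: permutation plus anchored copies."""
    perm = config.permutation
    copies = []
    for c in config.copies:
        a = c.anchor
        if isinstance(a, JunctionAnchor):
            anchor = {"type": "junction", "left": a.left, "right": a.right,
                      "slot": a.slot}
        else:
            anchor = {"type": "internal", "block": a.block, "offset": a.offset}
        copies.append({"label": c.label, "orientation": c.orientation,
                       "anchor": anchor})
    return {"permutation": list(perm.blocks), "copies": copies}


def config_from_json(doc: dict) -> RepeatConfiguration:
    perm = SignedCircularPermutation(doc["permutation"])
    copies = []
    for c in doc["copies"]:
        a = c["anchor"]
        if a["type"] == "junction":
            anchor = JunctionAnchor(int(a["left"]), int(a["right"]),
                                    int(a.get("slot", 0)))
        elif a["type"] == "internal":
            anchor = InternalAnchor(int(a["block"]), float(a.get("offset", 0.5)))
        else:
            raise ValueError(f"unknown anchor type {a['type']!r}")
        copies.append(RepeatCopy(c["label"], c["orientation"], anchor))
    return RepeatConfiguration.build(perm, copies)


def scenario_from_json(doc: list) -> list[TracedInversion]:
    """Scenario file: list of {"i":, "j":, "slots": [s_i, s_j]} entries."""
    steps = []
    for entry in doc:
        slots = entry.get("slots", [None, None])
        steps.append(
            TracedInversion(
                Inversion(int(entry["i"]), int(entry["j"])),
                (slots[0], slots[1]),
            )
        )
    return steps
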