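import json

import pytest

from plastrace.datasets import (
    cupressaceae_ancestor_to_cunninghamia_trace,
    sciadopitys_to_taxus_trace,
)
from plastrace.rearrangement import Inversion, SignedCircularPermutation
from plastrace.repeat_trace import (
    InternalAnchor,
    JunctionAnchor,
    RepeatConfiguration,
    RepeatCopy,
    TracedInversion,
    apply_inversion_traced,
    classify_arrangement,
    config_from_json,
    config_to_json,
    count_repeat_loci,
    scenario_from_json,
    trace_scenario,
)

P = SignedCircularPermutation


def tandem_pair_config(n=6, junction=3):
    perm = P(range(1, n + 1))
    copies = [
        RepeatCopy("Q#1", "+", JunctionAnchor(junction, junction + 1, 0)),
        RepeatCopy("Q#2", "+", JunctionAnchor(junction, junction + 1, 1)),
    ]
    return RepeatConfiguration.build(perm, copies)


class TestApplyInversionTraced:
    def test_segment_without_copies_preserves_class(self):
        cfg = tandem_pair_config()
        res = apply_inversion_traced(cfg, Inversion(0, 2))
        assert classify_arrangement(res, "Q") == "tandem_forward"
        assert count_repeat_loci(res, "Q") == 1

    def test_involution_with_same_slots(self):
        cfg = tandem_pair_config()
        for slots in [(0, 0), (1, 0), (2, 0)]:
            t = TracedInversion(Inversion(3, 5), slots)
            assert (
                apply_inversion_traced(apply_inversion_traced(cfg, t), t).items
                == cfg.items
            )

    def test_copy_count_conserved(self):
        cfg = tandem_pair_config(8)
        for i in range(8):
            for j in range(i + 1, 9):
                if (i, j) == (0, 8):
                    continue
                res = apply_inversion_traced(cfg, Inversion(i, j))
                assert len(res.copies) == 2

    def test_cut_between_tandem_pair_disperses_and_inverts(self):
        cfg = tandem_pair_config()
        res = apply_inversion_traced(
            cfg, TracedInversion(Inversion(3, 5), (1, 0))
        )
        copies = res.copies_with_prefix("Q")
        assert {c.orientation for c in copies} == {"+", "-"}
        assert classify_arrangement(res, "Q") == "dispersed_inverted"
        assert count_repeat_loci(res, "Q") == 2

    def test_invalid_slot_rejected(self):
        cfg = tandem_pair_config()
        with pytest.raises(ValueError, match="slot"):
            apply_inversion_traced(
                cfg, TracedInversion(Inversion(3, 5), (5, 0))
            )

    def test_splitting_theorem_exhaustive_on_toys(self):
        """A tandem pair becomes a dispersed inverted repeat iff exactly one
        cut point separates the two copies; otherwise it stays adjacent."""
        for n in (6, 7, 8):
            jm = 3
            cfg = tandem_pair_config(n, jm)
            for i in range(n):
                for j in range(i + 1, n + 1):
                    if (i, j) == (0, n):
                        continue
                    for si in [0, 1, 2] if i == jm else [0]:
                        for sj in [0, 1, 2] if j == jm else [0]:
                            t = TracedInversion(Inversion(i, j), (si, sj))
                            res = apply_inversion_traced(cfg, t)
                            cls = classify_arrangement(res, "Q")
                            separating = sum(
                                1
                                for jj, ss in ((i, si), (j, sj))
                                if jj == jm and ss == 1
                            )
                            if separating == 1:
                                assert cls == "dispersed_inverted"
                            else:
                                assert cls == "tandem_forward"
                                assert count_repeat_loci(res, "Q") == 1


class TestTraceScenario:
    def test_empty_scenario_returns_input_only(self):
        cfg = tandem_pair_config()
        assert trace_scenario(cfg, []) == [cfg]

    def test_reversibility_of_a_whole_scenario(self):
        start, steps, _ = sciadopitys_to_taxus_trace()
        states = trace_scenario(start, steps)
        back = states[-1]
        for step in reversed(steps):
            back = apply_inversion_traced(back, step)
        assert back.items == start.items

    def test_tandem_pair_splits_into_two_inverted_loci(self):
        start, steps, names = sciadopitys_to_taxus_trace()
        states = trace_scenario(start, steps)
        assert len(states) == len(steps) + 1
        assert classify_arrangement(states[0], "trnQ") == "tandem_forward"
        assert classify_arrangement(states[1], "trnQ") == "tandem_forward"
        assert classify_arrangement(states[-1], "trnQ") == "dispersed_inverted"
        assert count_repeat_loci(states[-1], "trnQ") == 2
        # one copy lands by the block carrying rps16/chlB (LCB 2), the
        # other stays by the psbK/psbI block (LCB 1)
        anchors = {
            c.label: c.anchor for c in states[-1].copies_with_prefix("trnQ")
        }
        flanks = {
            frozenset(
                (abs(a.left), abs(a.right))
            )
            for a in anchors.values()
        }
        assert any(2 in f and 1 in f for f in flanks)
        assert any(1 in f and 11 in f for f in flanks)

    def test_three_copy_scenario_lands_in_three_blocks(self):
        start, steps, _ = cupressaceae_ancestor_to_cunninghamia_trace()
        states = trace_scenario(start, steps)
        final = states[-1]
        assert count_repeat_loci(final, "trnQ") == 3
        orients = sorted(
            c.orientation for c in final.copies_with_prefix("trnQ")
        )
        assert orients == ["+", "+", "-"] or orients == ["+", "-", "-"]
        cls = classify_arrangement(final, "trnQ")
        assert cls[0] == "multi_copy_mixed"
        # copies sit by LCB 1 and LCB 12 junctions plus inside LCB 2
        internals = [
            c
            for c in final.copies_with_prefix("trnQ")
            if isinstance(c.anchor, InternalAnchor)
        ]
        assert [abs(c.anchor.block) for c in internals] == [2]


class TestClassification:
    def test_single_copy(self):
        perm = P([1, 2, 3, 4])
        cfg = RepeatConfiguration.build(
            perm, [RepeatCopy("Q", "+", JunctionAnchor(1, 2))]
        )
        assert classify_arrangement(cfg, "Q") == "single"

    def test_adjacent_opposite_orientations(self):
        perm = P([1, 2, 3, 4])
        cfg = RepeatConfiguration.build(
            perm,
            [
                RepeatCopy("Q#1", "+", JunctionAnchor(1, 2, 0)),
                RepeatCopy("Q#2", "-", JunctionAnchor(1, 2, 1)),
            ],
        )
        assert classify_arrangement(cfg, "Q") == "adjacent_inverted"

    def test_dispersed_inverted_is_the_short_ir(self):
        perm = P([1, 2, 3, 4])
        cfg = RepeatConfiguration.build(
            perm,
            [
                RepeatCopy("Q#1", "+", JunctionAnchor(1, 2)),
                RepeatCopy("Q#2", "-", JunctionAnchor(3, 4)),
            ],
        )
        assert classify_arrangement(cfg, "Q") == "dispersed_inverted"

    def test_no_matching_prefix_errors(self):
        cfg = tandem_pair_config()
        with pytest.raises(ValueError):
            classify_arrangement(cfg, "nope")

    def test_locus_counts(self):
        cfg = tandem_pair_config()
        assert count_repeat_loci(cfg, "Q") == 1
        perm = P([1, 2, 3, 4])
        cfg2 = RepeatConfiguration.build(
            perm,
            [
                RepeatCopy("Q#1", "+", JunctionAnchor(1, 2)),
                RepeatCopy("Q#2", "+", JunctionAnchor(3, 4)),
                RepeatCopy("Q#3", "-", InternalAnchor(2)),
            ],
        )
        assert count_repeat_loci(cfg2, "Q") == 3


class TestJsonInterchange:
    def test_config_round_trip(self):
        start, _, _ = cupressaceae_ancestor_to_cunninghamia_trace()
        doc = json.loads(json.dumps(config_to_json(start)))
        back = config_from_json(doc)
        assert back.items == start.items

    def test_scenario_parsing(self):
        steps = scenario_from_json(
            [{"i": 1, "j": 5, "slots": [1, 0]}, {"i": 0, "j": 2}]
        )
        assert steps[0].inversion == Inversion(1, 5)
        assert steps[0].cut_slots == (1, 0)
        assert steps[1].cut_slots == (None, None)
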