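"""How an inversion turns a tandem repeat into a short inverted repeat.

Replays the two narrated scenarios: the tandem trnQ-UUG pair of the
Sciadopitys-like arrangement is carried next to LCB 2 by one inversion and
split into two dispersed, oppositely oriented copies by a second; and the
Cupressaceae-ancestor arrangement yields three trnQ-bearing loci after one
inversion cuts between its tandem pair.
"""

from plastrace.datasets import (
    cupressaceae_ancestor_to_cunninghamia_trace,
    sciadopitys_to_taxus_trace,
)
from plastrace.repeat_trace import (
    classify_arrangement,
    count_repeat_loci,
    trace_scenario,
)

start, steps, names = sciadopitys_to_taxus_trace()
for name, state in zip(names, trace_scenario(start, steps)):
    cls = classify_arrangement(state, "trnQ")
    print(
        f"{name:18s} loci={count_repeat_loci(state, 'trnQ')} class={cls}"
    )
    for c in state.copies_with_prefix("trnQ"):
        print(f"    {c.label} ({c.orientation}) at {c.anchor}")

print()
start, steps, names = cupressaceae_ancestor_to_cunninghamia_trace()
final = trace_scenario(start, steps)[-1]
cls = classify_arrangement(final, "trnQ")
print(f"{names[-1]}: loci={count_repeat_loci(final, 'trnQ')} class={cls[0]}")
for c in final.copies_with_prefix("trnQ"):
    print(f"    {c.label} ({c.orientation}) at {c.anchor}")
print(
    "A single cut between the two tandem copies is what flips one of them: "
    "tandem first, inversion second, short inverted repeat as the result."
)
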