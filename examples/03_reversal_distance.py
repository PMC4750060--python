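"""Reversal distance and inversion scenarios between circular gene orders.

Evolves a 33-block circular genome by a known number of random inversions,
recovers that number with the exact Hannenhalli-Pevzner distance, and
prints a minimum-length inversion scenario connecting the two orders.
"""

from plastrace.rearrangement import reversal_distance, sort_by_reversals
from plastrace.synthetic_data import evolve, random_permutation

source = random_permutation(n=33, seed=4)
history = evolve(source, k=5, seed=5)
derived = history.result

d = reversal_distance(source, derived)
print(f"planted inversions: 5, inferred reversal distance: {d}")

scenario = sort_by_reversals(source, derived)
print(f"optimal scenario ({len(scenario)} steps):")
for k, inv in enumerate(scenario.steps, 1):
    print(f"  step {k}: invert between junctions {inv.i} and {inv.j}")
replayed = scenario.replay(source)
print(f"replay reaches the derived order: {replayed == derived}")
print(
    "The distance equals the planted count (random inversions on 33 blocks "
    "almost never cancel), and the scenario is one shortest path between "
    "the two genome organisations."
)
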