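"""Relative rank and asymmetrically weighted rank, on a toy group.

Shows R = below/(n-1) and SR(eta) for each member of a small reference
group, and how eta < 1 (heavier weight on more-sober comparators) pushes
everyone's perceived standing up while eta > 1 pulls it down.
"""

import numpy as np

import ranknorms as rn
from ranknorms.ranks import ReferenceGroup

brac = np.array([0.0, 20.0, 35.0, 35.0, 60.0, 95.0])
group = ReferenceGroup(
    gender="M", location=1,
    member_ids=tuple(f"p{i}" for i in range(len(brac))),
    brac_sorted=np.sort(brac), mean_brac=float(brac.mean()),
)

print(f"group of n={group.n} (one zero-BrAC member still counts as a comparator)")
print(f"{'BrAC':>6} {'below':>6} {'above':>6} {'R':>6} "
      f"{'SR(0.2)':>8} {'SR(1)':>7} {'SR(5)':>7}")
for v in sorted(set(brac)):
    below, above = rn.comparator_counts(v, group)
    r = rn.relative_rank(v, group)
    row = [rn.weighted_rank(v, group, eta) for eta in (0.2, 1.0, 5.0)]
    print(f"{v:>6.0f} {below:>6d} {above:>6d} {r:>6.2f} "
          f"{row[0]:>8.2f} {row[1]:>7.2f} {row[2]:>7.2f}")

print("\nSR(eta=1) equals R exactly; eta=0.2 up-weights the sober comparators")
print("(everyone feels relatively more intoxicated), eta=5 the drunk ones.")
print("The tied pair at 35 counts neither member against the other.")
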