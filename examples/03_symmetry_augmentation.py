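"""Multiply a training set by its point group — for free.

Point-group operations map a molecule onto itself, so applying them to a
conformer produces new geometries with exactly the same energy: no extra
electronic-structure calculations needed.  A benzene-like hexagonal ring
has 24 operations; a meta-disubstituted ring keeps an order-4 planar group
whose operations map the four planar hydroxyl-rotamer minima onto one
another, so augmenting 1000 generic conformers plus those 4 minima and
removing geometric duplicates leaves 4004 effective samples.
"""

import densfunc as df
from densfunc.core import EnergyRecord
from densfunc.synthetic import ring_rotamer_minima

benzene = df.toy_ring("benzene")
group = df.detect_point_group(benzene.template.centered())
print(f"benzene-like ring: point group of order {group.order}")

conformers = benzene.sample_conformers(1000, seed=5)
for c in conformers:
    c.energy = EnergyRecord(float(benzene.low_energy(c)))
augmented = df.augment_dataset(conformers, group)
print(f"  1000 conformers -> {len(augmented)} augmented samples")

ring = df.toy_ring()  # resorcinol-like: O at two meta positions
minima = ring_rotamer_minima()
group4 = df.detect_point_group(minima[0].centered())
print(f"resorcinol-like ring: point group of order {group4.order}")

conformers = ring.sample_conformers(1000, seed=7) + minima
for c in conformers:
    c.energy = EnergyRecord(float(ring.low_energy(c)))
augmented = df.augment_dataset(conformers, group4)
print(f"  1000 generic + 4 rotamer minima -> {len(augmented)} effective samples")
print("  (the minima are images of one another, so 16 copies dedup to 4)")
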