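"""How different do two iridescent wings look to birds and butterflies?

Builds two synthetic co-mimic wing groups whose multilayer periods differ
by 8 nm (four noisy individuals each), then scores every cross-pair with
the receptor-noise-limited model under daylight for all five built-in
observers: the avian violet-sensitive system and the four *Heliconius*
photoreceptor complements.
"""

import numpy as np

from iriscale import builtin_visual_systems, d65, pairwise_discriminability
from iriscale.synthetic import gen_comimic_groups

group_a, group_b = gen_comimic_groups(n_per_group=4, period_delta_nm=8.0,
                                      seed=7)
illum = d65()

print("median JND over the 16 cross-pairs (1 JND = discrimination threshold)")
print(f"{'observer':>10} {'chromatic':>10} {'achromatic':>11}")
for name, system in builtin_visual_systems().items():
    results = pairwise_discriminability(group_a, group_b, system, illum)
    chrom = np.median([r.chromatic_jnd for r in results])
    achro = np.median([r.achromatic_jnd for r in results])
    print(f"{name:>10} {chrom:>10.2f} {achro:>11.2f}")

# Chromatic JNDs above 1 mean the observer can tell the wing colours
# apart. The tetrachromatic butterfly systems (heli_i, heli_iii), with
# two UV receptor classes sampling the short-wavelength edge of the
# reflectance band, separate the 8 nm period shift most easily; the
# achromatic (brightness) channel barely registers it.
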