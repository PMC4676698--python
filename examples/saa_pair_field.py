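"""Detect intermolecular interactions in a two-colour pair field.

Builds a synthetic field of 5,000 molecule pairs — emulating annealed
Cy3/Cy5-labelled 30-bp DNA duplexes whose fluorophores sit 10.2 nm apart —
jitters both channels with 20 nm-precision localization noise, and runs
spatial association analysis (SAA) in both directions.
"""

import numpy as np

from miisr import CdcSpec, compute_cdc, make_pair_field, saa_two_colour

scene = make_pair_field(n_pairs=5000, separation=10.2, precision=20.0,
                        unpaired_b_fraction=0.5, seed=1)
a, b = scene.channel("A"), scene.channel("B")

# per-channel mean precisions come from the tables themselves
spec = CdcSpec.from_tables([a, b], i_reg=0.0, cutoff_multiplier=1.65)
print(f"CDC = {compute_cdc(spec):.2f} nm "
      f"(1.65 x sqrt({spec.sigma_c[0]:.0f}^2 + {spec.sigma_c[1]:.0f}^2))")

r_ab, r_ba = saa_two_colour(a, b, spec, region=scene.region,
                            n_randomizations=20, seed=2)
for r in (r_ab, r_ba):
    print(f"{r.direction[0]} -> {r.direction[1]}: "
          f"fraction below CDC = {r.fraction_below_cdc:.3f}, "
          f"SRP (random) = {r.srp_fraction_below_cdc:.3f}, "
          f"histogram mode = {r.mode_distance:.1f} nm")

# A->B stays high (every A molecule has a partner); B->A is diluted by the
# 50% unpaired B molecules -- SAA is directional.  The mode recovers the
# true 10.2 nm separation to within one 2 nm histogram bin, and the SRP
# fraction shows how much association blind chance would produce.
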