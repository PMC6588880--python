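"""Handedness string of a six-helix transmembrane bundle.

Generates an ideal six-helix bundle whose consecutive centroid triplets
turn clockwise, clockwise, counter-clockwise, counter-clockwise when
viewed from outside the membrane, fits a TM profile from the Cα
coordinates, and prints each segment's orientation and the core
handedness string.
"""
from tmtriage import build_profile, handedness_string
from tmtriage.synth import bundle_preset, make_helix_bundle

fix = make_helix_bundle(bundle_preset("rrll", seed=1))
profile = build_profile(fix.chain_coords, fix.tm_ranges, fix.frame,
                        is_core=fix.is_core, is_coupling=fix.is_coupling)

for seg in profile.segments:
    print(f"TM{seg.index}: residues {seg.interval}  "
          f"orientation={seg.orientation.value:9s}  "
          f"centroid=({seg.centroid[0]:6.2f},{seg.centroid[1]:6.2f})")
print("handedness:", handedness_string(profile))
print("generator truth:", fix.truth_handedness)

# "RRLL" reads: triplets (1,2,3) and (2,3,4) are right-handed, (3,4,5)
# and (4,5,6) left-handed - the arrangement shared by the six-segment
# cores of the CAAX-protease-like intramembrane proteases.
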