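"""Insertion-tolerant alignment of TM profiles at segment granularity.

A six-segment reference core is aligned against two decorated variants:
one with an extra N-terminal crossing, one with two short extra
crossings inserted between core segments 1 and 2.  Both keep a
one-to-one mapping of the six core segments; the extras become gaps.
"""
from tmtriage import align_profiles, compare_handedness
from tmtriage.synth import make_abstract_profile

core_lengths = [30, 19, 22, 26, 18, 23]
core = make_abstract_profile("UDUDUD", core_lengths, "reference core")

variants = {
    "extra N-terminal segment":
        make_abstract_profile("DUDUDUD", [16] + core_lengths),
    "two inserted after segment 1":
        make_abstract_profile("UDUDUDUD",
                              [core_lengths[0], 11, 12] + core_lengths[1:]),
}

for name, variant in variants.items():
    aln = align_profiles(variant, core)
    print(f"{name}:")
    print(f"  matched pairs: {aln.pairs}")
    print(f"  unmatched in variant: {aln.gaps_a}")
    print(f"  score: {aln.score:.2f}")
    print(f"  handedness identity over matched core: "
          f"{compare_handedness(aln, variant, core):.2f}")

# Six pairs in both cases: the alignment absorbs decorations as end gaps
# (N-terminal extra) or an internal gap (inserted pair) instead of
# sliding the core out of register.
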