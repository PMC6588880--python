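"""Detecting a circular permutation between two helix bundles.

Builds a four-crossing core and a circularly permuted copy in which the
original first segment has moved to the C-terminus (so it structurally
occupies the last core position), then recovers the rotation offset.
"""
from tmtriage import detect_circular_permutation
from tmtriage.synth import make_abstract_profile, rotate_profile

exporter_like = make_abstract_profile("UDUD", [28, 22, 25, 30],
                                      "exporter-like core")
# move the first three segments to the end: the permuted chain's first
# segment corresponds to the reference's last core position
importer_like = rotate_profile(exporter_like, 3, "importer-like core")

aln = detect_circular_permutation(exporter_like, importer_like)
print("permutation offset:", aln.permutation_offset)
print("matched pairs (exporter seg, importer seg):", aln.pairs)
print("score:", round(aln.score, 2))

unrelated = make_abstract_profile("UUDDU", [35, 15, 38, 16, 33], "unrelated")
aln0 = detect_circular_permutation(exporter_like, unrelated)
print("unrelated bundle -> offset", aln0.permutation_offset,
      "score", round(aln0.score, 2))

# A true permutation aligns all four segments at the rotated register
# with a full-score alignment; for the unrelated bundle no rotation
# beats the unrotated alignment by the required margin, so the offset
# stays 0 and the score is low.
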