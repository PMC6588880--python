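"""Topology-alignment tests: insertions, circular permutation, handedness
identity over matched cores."""
import numpy as np
import pytest

from tmtriage import (align_profiles, compare_handedness,
                      detect_circular_permutation, pair_score)
from tmtriage.config import DEFAULT_CONFIG
from tmtriage.synth import (bundle_preset, make_abstract_profile,
                            make_helix_bundle, random_profile,
                            rotate_profile)
from tmtriage.geometry import build_profile

CFG = DEFAULT_CONFIG

#: a six-segment core with heterogeneous lengths, alternating topology
CORE_LENGTHS = [30, 19, 22, 26, 18, 23]


def six_core():
    return make_abstract_profile("UDUDUD", CORE_LENGTHS, "core6")


class TestAlignProfiles:
    def test_self_alignment_is_perfect_and_gap_free(self):
        p = six_core()
        aln = align_profiles(p, p, CFG)
        assert aln.pairs == tuple((i, i) for i in range(1, 7))
        assert aln.gaps_a == () and aln.gaps_b == ()
        assert aln.score == pytest.approx(6 * (CFG.w_or + CFG.w_len))

    def test_extra_nterminal_segment_is_end_gapped(self):
        # one additional N-terminal crossing flips the parity of the
        # leading segment; the six core segments still match one-to-one
        variant = make_abstract_profile("DUDUDUD", [16] + CORE_LENGTHS,
                                        "nterm-extra")
        aln = align_profiles(variant, six_core(), CFG)
        assert aln.pairs == ((2, 1), (3, 2), (4, 3), (5, 4), (6, 5), (7, 6))
        assert aln.gaps_a == (1,) and aln.gaps_b == ()

    def test_two_inserted_segments_open_an_internal_gap(self):
        # two short extra crossings between core segments 1 and 2
        lengths = [CORE_LENGTHS[0], 11, 12] + CORE_LENGTHS[1:]
        variant = make_abstract_profile("UDUDUDUD", lengths, "insert2")
        aln = align_profiles(variant, six_core(), CFG)
        assert aln.pairs == ((1, 1), (4, 2), (5, 3), (6, 4), (7, 5), (8, 6))
        assert set(aln.gaps_a) == {2, 3}

    def test_score_symmetry_and_pair_transpose(self, rng):
        for _ in range(25):
            a, b = random_profile(rng), random_profile(rng)
            f = align_profiles(a, b, CFG)
            r = align_profiles(b, a, CFG)
            assert f.score == pytest.approx(r.score)
            assert tuple((j, i) for i, j in f.pairs) == r.pairs

    def test_deleting_an_unmatched_segment_never_lowers_the_score(self, rng):
        for _ in range(25):
            a, b = random_profile(rng), random_profile(rng)
            aln = align_profiles(a, b, CFG)
            if not aln.gaps_a:
                continue
            drop = aln.gaps_a[0]
            kept = [s for s in a.segments if s.index != drop]
            orient = "".join(
                {"UP": "U", "DOWN": "D", "UNDEFINED": "P"}[s.orientation.value]
                for s in kept)
            smaller = make_abstract_profile(orient, [s.length for s in kept])
            aln2 = align_profiles(smaller, b, CFG)
            assert aln2.score >= aln.score - 1e-9

    def test_orientation_mismatch_scores_negative(self):
        a = make_abstract_profile("U", [20]).segments[0]
        b = make_abstract_profile("D", [20]).segments[0]
        assert pair_score(a, b, CFG) == pytest.approx(-CFG.w_or + CFG.w_len)

    def test_unrelated_profiles_score_low(self):
        a = make_abstract_profile("UDUDU", [20, 21, 22, 23, 24], "A")
        b = make_abstract_profile("UUDDU", [35, 15, 38, 16, 33], "B")
        aln = align_profiles(a, b, CFG)
        assert aln.score < align_profiles(a, a, CFG).score * 0.75


class TestCircularPermutation:
    def test_rotation_by_one_recovered(self, rng):
        p = random_profile(rng, n_segments=6)
        q = rotate_profile(p, 1)
        aln = detect_circular_permutation(p, q, CFG)
        assert aln.permutation_offset == 1
        assert len(aln.pairs) == 6 and aln.gaps_a == ()
        assert aln.score == pytest.approx(6 * (CFG.w_or + CFG.w_len))

    def test_all_offsets_recovered_small(self, rng):
        for n in (3, 5, 8):
            p = random_profile(rng, n_segments=n)
            for k in range(n):
                q = rotate_profile(p, k)
                aln = detect_circular_permutation(p, q, CFG)
                assert aln.permutation_offset == k, (n, k)

    def test_first_segment_occupying_last_core_position(self):
        """A four-crossing core whose first segment sits where the other
        profile's last core segment sits: one cyclic step apart."""
        macb_like = make_abstract_profile("UDUD", [28, 22, 25, 30], "exporter")
        importer_like = rotate_profile(macb_like, 3, "importer")
        # importer segment 1 is exporter segment 4's structural position
        aln = detect_circular_permutation(macb_like, importer_like, CFG)
        assert aln.permutation_offset == 3
        assert len(aln.pairs) == 4

    def test_unrelated_profiles_keep_offset_zero(self):
        a = make_abstract_profile("UDUDU", [20, 21, 22, 23, 24], "A")
        b = make_abstract_profile("UUDDU", [35, 15, 38, 16, 33], "B")
        aln = detect_circular_permutation(a, b, CFG)
        assert aln.permutation_offset == 0

    def test_margin_rule_reports_zero_unless_clear_winner(self, rng):
        """Whenever a nonzero offset is reported, its score must beat the
        unrotated alignment by more than cp_margin."""
        from tmtriage.topoalign import _gotoh, _rotated
        for _ in range(20):
            a, b = random_profile(rng), random_profile(rng)
            aln = detect_circular_permutation(a, b, CFG)
            base, _ = _gotoh(a.segments, b.segments, CFG)
            if aln.permutation_offset != 0:
                assert aln.score > base + CFG.cp_margin
            else:
                assert aln.score == pytest.approx(base)


class TestCompareHandedness:
    def test_matching_rrll_cores_have_identity_one(self):
        fix = make_helix_bundle(bundle_preset("rrll"))
        prof = build_profile(fix.chain_coords, fix.tm_ranges, fix.frame)
        aln = align_profiles(prof, prof, CFG)
        assert compare_handedness(aln, prof, prof, CFG) == pytest.approx(1.0)
        assert aln.handedness_identity == pytest.approx(1.0)

    @staticmethod
    def _prof_from_points(pts):
        """Alternating U/D profile with prescribed in-plane centroids."""
        import numpy as np
        from tmtriage.geometry import (Orientation, TMProfile, TMSegment,
                                       default_frame)
        from tmtriage.intervals import ResidueInterval
        segs = []
        start = 1
        for i, (x, y) in enumerate(pts):
            segs.append(TMSegment(
                index=i + 1,
                interval=ResidueInterval(start, start + 19),
                axis=np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0]),
                centroid=np.array([float(x), float(y), 0.0]),
                orientation=Orientation.UP if i % 2 == 0
                else Orientation.DOWN))
            start += 24
        return TMProfile(segments=tuple(segs), frame=default_frame())

    def test_half_matching_labels(self):
        from tmtriage.geometry import handedness_string
        # a: two clockwise turns ("RR"); b: clockwise then counter ("RL")
        a = self._prof_from_points([(0, 10), (8, 6), (8, -6), (0, -10)])
        b = self._prof_from_points([(0, 10), (8, 6), (8, -6), (16, -2)])
        assert str(handedness_string(a)) == "RR"
        assert str(handedness_string(b)) == "RL"
        aln = align_profiles(a, b, CFG)
        assert len(aln.pairs) == 4
        assert compare_handedness(aln, a, b, CFG) == pytest.approx(0.5)

    def test_x_positions_excluded_from_denominator(self):
        # both profiles share one clean triplet; the second triplet is
        # collinear (X) in both, so the denominator is 1
        import numpy as np
        from tmtriage.geometry import (Orientation, TMProfile, TMSegment,
                                       default_frame)
        from tmtriage.intervals import ResidueInterval

        def prof(pts):
            segs = []
            start = 1
            for i, (x, y) in enumerate(pts):
                segs.append(TMSegment(
                    index=i + 1,
                    interval=ResidueInterval(start, start + 19),
                    axis=np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0]),
                    centroid=np.array([float(x), float(y), 0.0]),
                    orientation=Orientation.UP if i % 2 == 0
                    else Orientation.DOWN))
                start += 24
            return TMProfile(segments=tuple(segs), frame=default_frame())

        # points: clean clockwise turn then three collinear points
        a = prof([(0, 10), (8, 6), (8, -6), (8, -20)])
        aln = align_profiles(a, a, CFG)
        assert compare_handedness(aln, a, a, CFG) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        a = make_abstract_profile("UD", [20, 20])
        aln = align_profiles(a, a, CFG)
        with pytest.raises(ValueError):
            compare_handedness(aln, a, a, CFG)

    def test_all_degenerate_positions_rejected(self):
        import numpy as np
        from tmtriage.geometry import (Orientation, TMProfile, TMSegment,
                                       default_frame)
        from tmtriage.intervals import ResidueInterval
        segs = []
        for i in range(3):
            segs.append(TMSegment(
                index=i + 1,
                interval=ResidueInterval(1 + 24 * i, 20 + 24 * i),
                axis=np.array([0.0, 0.0, 1.0]),
                centroid=np.array([10.0 * i, 0.0, 0.0]),
                orientation=Orientation.UP))
        a = TMProfile(segments=tuple(segs), frame=default_frame())
        aln = align_profiles(a, a, CFG)
        with pytest.raises(ValueError):
            compare_handedness(aln, a, a, CFG)
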