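"""Segment-level topology alignment of TM profiles.

Two helix bundles are compared as ordered sequences of segments, scored by
membrane-crossing orientation agreement and length similarity.  The
alignment is semi-global (unmatched leading/trailing segments are free)
with an affine penalty for internal gaps, which makes inserted segments —
an extra N-terminal helix, a pair of helices inserted between two core
positions — cheap to accommodate while still favouring matched cores.

Circular permutations are detected by aligning one profile against every
cyclic rotation of the other's segment order and keeping the best-scoring
rotation, provided it beats the unrotated alignment by a margin.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .config import DEFAULT_CONFIG, ToolConfig
from .geometry import Orientation, TMProfile, TMSegment, triplet_handedness

_NEG = float("-inf")


@dataclass(frozen=True)
class TopologyAlignment:
    """Matched segment pairs between two profiles.

    ``pairs`` holds (segment_index_in_A, segment_index_in_B) using each
    segment's chain ordinal; the pairs are strictly increasing in both
    profiles' alignment order (for a circular permutation, B's order is
    its rotated order).  ``permutation_offset`` k means B's segment
    sequence was rotated so that its (k+1)-th segment aligns first; 0
    means no rotation.  ``handedness_identity`` is the fraction of
    matched-core triplet labels equal between the two profiles (None when
    not computable).
    """

    pairs: tuple[tuple[int, int], ...]
    gaps_a: tuple[int, ...]
    gaps_b: tuple[int, ...]
    score: float
    permutation_offset: int = 0
    handedness_identity: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "gaps_a", tuple(self.gaps_a))
        object.__setattr__(self, "gaps_b", tuple(self.gaps_b))
        if self.handedness_identity is not None and \
                not 0.0 <= self.handedness_identity <= 1.0:
            raise ValueError("handedness_identity must be in [0, 1]")


def pair_score(a: TMSegment, b: TMSegment,
               config: ToolConfig = DEFAULT_CONFIG) -> float:
    """Score of matching two segments: orientation agreement plus length
    similarity.

    Orientation contributes +w_or when both segments cross the membrane
    the same way, -w_or when they cross opposite ways, and 0 when either
    is UNDEFINED (an in-plane helix carries no crossing direction).
    Length contributes w_len * (1 - |lA - lB| / max(lA, lB)).
    """
    if (a.orientation is Orientation.UNDEFINED
            or b.orientation is Orientation.UNDEFINED):
        s_or = 0.0
    elif a.orientation is b.orientation:
        s_or = 1.0
    else:
        s_or = -1.0
    la, lb = a.length, b.length
    s_len = 1.0 - abs(la - lb) / max(la, lb)
    return config.w_or * s_or + config.w_len * s_len


def _gotoh(segs_a: Sequence[TMSegment], segs_b: Sequence[TMSegment],
           config: ToolConfig) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Semi-global affine-gap DP over two segment sequences.

    Returns (score, pairs) with pairs as 0-based positions into the given
    sequences.  End gaps are free; internal gap runs cost
    g_open + (k-1) * g_ext.  DP values are (score, -gap_opens) tuples so
    that among equal-scoring alignments the one with fewest internal gap
    runs wins; remaining ties are resolved by a fixed traceback
    preference (match > gap-in-A > gap-in-B > fresh start), which makes
    the output fully deterministic.
    """
    n, m = len(segs_a), len(segs_b)
    s = [[pair_score(a, b, config) for b in segs_b] for a in segs_a]
    go, ge = config.g_open, config.g_ext

    NEGV = (_NEG, 0)
    # M: ends matching (i, j); X: ends skipping B_j internally;
    # Y: ends skipping A_i internally.  1-based indices, row 0/col 0 pads.
    M = [[NEGV] * (m + 1) for _ in range(n + 1)]
    X = [[NEGV] * (m + 1) for _ in range(n + 1)]
    Y = [[NEGV] * (m + 1) for _ in range(n + 1)]
    ptrM = [[None] * (m + 1) for _ in range(n + 1)]
    ptrX = [[None] * (m + 1) for _ in range(n + 1)]
    ptrY = [[None] * (m + 1) for _ in range(n + 1)]

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: predecessor covers (i-1, j-1) in any state,
            # or the alignment starts here (free leading gaps).
            cand = (
                ((M[i - 1][j - 1][0], M[i - 1][j - 1][1]), "M"),
                ((Y[i - 1][j - 1][0], Y[i - 1][j - 1][1]), "Y"),
                ((X[i - 1][j - 1][0], X[i - 1][j - 1][1]), "X"),
                ((0.0, 0), "start"),
            )
            best, tag = cand[0]
            for v, t in cand[1:]:
                if v > best:
                    best, tag = v, t
            M[i][j] = (best[0] + s[i - 1][j - 1], best[1])
            ptrM[i][j] = tag

            # X: B_j skipped internally (after at least one match)
            open_v = (M[i][j - 1][0] - go, M[i][j - 1][1] - 1)
            ext_v = (X[i][j - 1][0] - ge, X[i][j - 1][1])
            cross_v = (Y[i][j - 1][0] - go, Y[i][j - 1][1] - 1)
            X[i][j], ptrX[i][j] = max(
                (open_v, "M"), (ext_v, "X"), (cross_v, "Y"),
                key=lambda c: c[0])

            # Y: A_i skipped internally
            open_v = (M[i - 1][j][0] - go, M[i - 1][j][1] - 1)
            ext_v = (Y[i - 1][j][0] - ge, Y[i - 1][j][1])
            cross_v = (X[i - 1][j][0] - go, X[i - 1][j][1] - 1)
            Y[i][j], ptrY[i][j] = max(
                (open_v, "M"), (ext_v, "Y"), (cross_v, "X"),
                key=lambda c: c[0])

    # free trailing gaps: the alignment may end at any match cell
    best_val = (0.0, 0)
    best_cell = None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] > best_val:
                best_val = M[i][j]
                best_cell = (i, j)
    if best_cell is None:
        return 0.0, ()

    pairs: list[tuple[int, int]] = []
    state = "M"
    i, j = best_cell
    while True:
        if state == "M":
            pairs.append((i - 1, j - 1))
            nxt = ptrM[i][j]
            i, j = i - 1, j - 1
            if nxt == "start":
                break
            state = nxt
        elif state == "X":
            nxt = ptrX[i][j]
            j -= 1
            state = nxt
        else:  # Y
            nxt = ptrY[i][j]
            i -= 1
            state = nxt
        if i == 0 or j == 0:
            break
    pairs.reverse()
    return best_val[0], tuple(pairs)


def _identity_from_pairs(segs_a: Sequence[TMSegment],
                         segs_b: Sequence[TMSegment],
                         pos_pairs: Sequence[tuple[int, int]],
                         A: TMProfile, B: TMProfile,
                         config: ToolConfig) -> Optional[float]:
    if len(pos_pairs) < 3:
        return None
    try:
        matched_a = [segs_a[i] for i, _ in pos_pairs]
        matched_b = [segs_b[j] for _, j in pos_pairs]
        return _handedness_identity(matched_a, matched_b, A, B, config)
    except ValueError:
        return None


def _handedness_identity(matched_a: Sequence[TMSegment],
                         matched_b: Sequence[TMSegment],
                         A: TMProfile, B: TMProfile,
                         config: ToolConfig) -> float:
    labels_a = [triplet_handedness(x.centroid, y.centroid, z.centroid,
                                   A.frame, config.degeneracy_tol,
                                   config.handedness_convention)
                for x, y, z in zip(matched_a, matched_a[1:], matched_a[2:])]
    labels_b = [triplet_handedness(x.centroid, y.centroid, z.centroid,
                                   B.frame, config.degeneracy_tol,
                                   config.handedness_convention)
                for x, y, z in zip(matched_b, matched_b[1:], matched_b[2:])]
    pairs = [(a, b) for a, b in zip(labels_a, labels_b)
             if a != "X" and b != "X"]
    if not pairs:
        raise ValueError("all matched triplets are degenerate (X); "
                         "handedness identity undefined")
    return sum(a == b for a, b in pairs) / len(pairs)


def _alignment_from_positions(segs_a: Sequence[TMSegment],
                              segs_b: Sequence[TMSegment],
                              score: float,
                              pos_pairs: Sequence[tuple[int, int]],
                              A: TMProfile, B: TMProfile,
                              offset: int,
                              config: ToolConfig) -> TopologyAlignment:
    matched_a = {i for i, _ in pos_pairs}
    matched_b = {j for _, j in pos_pairs}
    pairs = tuple((segs_a[i].index, segs_b[j].index) for i, j in pos_pairs)
    gaps_a = tuple(seg.index for k, seg in enumerate(segs_a)
                   if k not in matched_a)
    gaps_b = tuple(seg.index for k, seg in enumerate(segs_b)
                   if k not in matched_b)
    identity = _identity_from_pairs(segs_a, segs_b, pos_pairs, A, B, config)
    return TopologyAlignment(pairs=pairs, gaps_a=gaps_a, gaps_b=gaps_b,
                             score=score, permutation_offset=offset,
                             handedness_identity=identity)


def align_profiles(A: TMProfile, B: TMProfile,
                   config: ToolConfig = DEFAULT_CONFIG) -> TopologyAlignment:
    """Optimal semi-global alignment of two profiles' segment sequences."""
    score, pos_pairs = _gotoh(A.segments, B.segments, config)
    return _alignment_from_positions(A.segments, B.segments, score,
                                     pos_pairs, A, B, 0, config)


def _rotated(segs: Sequence[TMSegment], r: int) -> list[TMSegment]:
    """Rotate a segment sequence right by r: element (i - r) mod n moves
    to position i, so the original r-th-from-the-end segment leads."""
    n = len(segs)
    return [segs[(i - r) % n] for i in range(n)]


def detect_circular_permutation(A: TMProfile, B: TMProfile,
                                config: ToolConfig = DEFAULT_CONFIG,
                                ) -> TopologyAlignment:
    """Best alignment of A against every cyclic rotation of B's segments.

    Rotation reorders B's segment sequence without renumbering the
    segments (their chain ordinals are metadata of B's own chain).  The
    unrotated alignment wins unless some rotation beats its score by more
    than ``cp_margin``; among qualifying rotations the best score wins,
    ties going to the smallest offset.  The reported offset k means: B
    matches A after B's last k segments are moved to the front — i.e. B
    looks like A with its first k segments cyclically moved to the end.
    """
    m = len(B.segments)
    results: list[tuple[float, int, tuple[tuple[int, int], ...],
                        list[TMSegment]]] = []
    for r in range(m):
        segs_b = _rotated(B.segments, r)
        score, pos_pairs = _gotoh(A.segments, segs_b, config)
        results.append((score, r, pos_pairs, segs_b))

    base_score = results[0][0]
    best = results[0]
    for res in results[1:]:
        if res[0] > best[0]:
            best = res
    if best[1] != 0 and best[0] <= base_score + config.cp_margin:
        best = results[0]
    score, r, pos_pairs, segs_b = best
    return _alignment_from_positions(A.segments, segs_b, score, pos_pairs,
                                     A, B, r, config)


def compare_handedness(aln: TopologyAlignment, A: TMProfile, B: TMProfile,
                       config: ToolConfig = DEFAULT_CONFIG) -> float:
    """Fraction of equal handedness labels over the matched segments.

    Triplet labels are computed over the matched segments of each profile
    in alignment order; positions where either label is X are excluded
    from the denominator.  Requires >= 3 matched pairs and at least one
    non-degenerate position.
    """
    if len(aln.pairs) < 3:
        raise ValueError("need >= 3 matched pairs to compare handedness")
    by_index_a = {s.index: s for s in A.segments}
    by_index_b = {s.index: s for s in B.segments}
    matched_a = [by_index_a[i] for i, _ in aln.pairs]
    matched_b = [by_index_b[j] for _, j in aln.pairs]
    return _handedness_identity(matched_a, matched_b, A, B, config)
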