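"""Transmembrane segment geometry: axes, orientations, triplet handedness.

Given Cα coordinates, a membrane normal and the residue ranges of the
membrane-spanning segments, this module computes the descriptors used to
compare polytopic helix bundles at segment granularity:

* the axis and centroid of each segment (principal direction of its Cα);
* its membrane-crossing orientation (UP along the normal, DOWN against it,
  or UNDEFINED for near-in-plane helices such as amphipathic coupling
  helices);
* the chirality label (R/L/X) of every triplet of consecutive segments,
  obtained as the turn sense of the three projected centroids viewed along
  the membrane normal.

The concatenated triplet labels give a compact handedness string for a
bundle — e.g. "RRLL" for a six-segment core whose first two triplets turn
clockwise (viewed from the +normal side) and last two counter-clockwise.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import DEFAULT_CONFIG, ToolConfig
from .intervals import ResidueInterval

#: (residue_number, xyz) pairs, chain order
ChainCoords = Sequence[tuple[int, np.ndarray]]

_COINCIDE_TOL = 1e-8  # Å; projected centroids closer than this are degenerate


@dataclass(frozen=True)
class MembraneFrame:
    """A membrane reference frame: unit normal (towards the designated
    "outside") and a point on the bilayer mid-plane."""

    normal: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        if n.shape != (3,) or o.shape != (3,):
            raise ValueError("normal and origin must be 3-vectors")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "origin", o)

    @classmethod
    def from_vector(cls, normal: Sequence[float],
                    origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "MembraneFrame":
        """Build a frame from an arbitrary non-zero vector (normalised here)."""
        n = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("membrane normal must be non-zero")
        return cls(n / norm, np.asarray(origin, dtype=float))

    def flipped(self) -> "MembraneFrame":
        return MembraneFrame(-self.normal, self.origin)

    def project(self, point: np.ndarray) -> np.ndarray:
        """Project a point onto the membrane mid-plane."""
        p = np.asarray(point, dtype=float)
        return p - np.dot(p - self.origin, self.normal) * self.normal


def default_frame() -> MembraneFrame:
    """+z normal with origin at the coordinate origin (the usual convention
    for membrane-oriented structures)."""
    return MembraneFrame(np.array([0.0, 0.0, 1.0]), np.zeros(3))


class Orientation(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class TMSegment:
    """One membrane-spanning segment with its fitted geometry.

    ``index`` is the ordinal along the chain (1-based, N- to C-terminus).
    ``axis`` is the unit principal direction oriented N→C.
    """

    index: int
    interval: ResidueInterval
    axis: np.ndarray
    centroid: np.ndarray
    orientation: Orientation
    is_core: bool = True
    is_coupling_helix: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        c = np.asarray(self.centroid, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-6:
            raise ValueError("segment axis must be a unit vector")
        object.__setattr__(self, "axis", a)
        object.__setattr__(self, "centroid", c)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class TMProfile:
    """An ordered bundle of TM segments sharing one membrane frame."""

    segments: tuple[TMSegment, ...]
    frame: MembraneFrame
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        ivs = [s.interval for s in self.segments]
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError("segments must be in chain order and "
                                 "non-overlapping")

    def __len__(self) -> int:
        return len(self.segments)

    def core_segments(self) -> tuple[TMSegment, ...]:
        return tuple(s for s in self.segments if s.is_core)


@dataclass(frozen=True)
class HandednessString:
    """Per-consecutive-triplet chirality labels of a profile (R/L/X)."""

    labels: str

    def __post_init__(self) -> None:
        if any(ch not in "RLX" for ch in self.labels):
            raise ValueError("handedness labels must be over {R, L, X}")

    def __str__(self) -> str:
        return self.labels

    def __len__(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def fit_helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the axis of a helical segment from its Cα positions.

    Returns ``(axis, centroid)``.  The centroid is the mean position.
    For a regular helix the second differences of consecutive positions
    are exactly perpendicular to the helix axis, so the axis is taken as
    the null direction (smallest right singular vector) of the
    second-difference matrix — exact for ideal helices of any partial
    turn, and a least-squares estimate under coordinate noise.  When the
    second differences are degenerate (nearly collinear points) the
    dominant principal direction of the centred points is used instead.
    The sign is chosen so the axis points from the N- towards the
    C-terminus.  Requires at least 5 points with non-zero spread.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array")
    if len(pts) < 5:
        raise ValueError(f"need >= 5 Cα to fit a helix axis, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    u0, s0, vt0 = np.linalg.svd(centred, full_matrices=False)
    if s0[0] < 1e-9:
        raise ValueError("cannot fit an axis: points are coincident")
    second_diff = np.diff(pts, n=2, axis=0)
    u, s, vt = np.linalg.svd(second_diff, full_matrices=False)
    if s[1] > 1e-9 * max(1.0, s[0]):
        axis = vt[2]
    else:
        # degenerate curvature (collinear points): fall back to the
        # principal direction of the positions themselves
        axis = vt0[0]
    if np.dot(pts[-1] - pts[0], axis) < 0:
        axis = -axis
    return axis, centroid


def segment_orientation(axis: np.ndarray, frame: MembraneFrame,
                        orientation_min_cos: float = DEFAULT_CONFIG.orientation_min_cos,
                        ) -> Orientation:
    """UP/DOWN/UNDEFINED from the cosine between axis and membrane normal."""
    c = float(np.dot(axis, frame.normal))
    if c > orientation_min_cos:
        return Orientation.UP
    if c < -orientation_min_cos:
        return Orientation.DOWN
    return Orientation.UNDEFINED


def _flip_label(label: str) -> str:
    return {"R": "L", "L": "R", "X": "X"}[label]


def triplet_handedness(c1: np.ndarray, c2: np.ndarray, c3: np.ndarray,
                       frame: MembraneFrame,
                       degeneracy_tol: float = DEFAULT_CONFIG.degeneracy_tol,
                       convention: str = DEFAULT_CONFIG.handedness_convention,
                       ) -> str:
    """Chirality label of three consecutive segment centroids.

    The centroids are projected onto the membrane plane; with
    ``d1 = c2' - c1'`` and ``d2 = c3' - c2'``, the normalised turn sense is
    ``s = normal · (d1 × d2) / (|d1| |d2|)``.  Under convention C1 a
    clockwise progression viewed from the +normal side (s < 0) is
    right-handed (R), counter-clockwise is L, and |s| <= degeneracy_tol
    is degenerate (X).  Convention C2 flips every label.
    """
    p1, p2, p3 = (frame.project(c) for c in (c1, c2, c3))
    for a, b in ((p1, p2), (p2, p3), (p1, p3)):
        if np.linalg.norm(b - a) < _COINCIDE_TOL:
            raise ValueError("projected centroids coincide; "
                             "handedness undefined")
    d1 = p2 - p1
    d2 = p3 - p2
    h = float(np.dot(frame.normal, np.cross(d1, d2)))
    s = h / (np.linalg.norm(d1) * np.linalg.norm(d2))
    if s > degeneracy_tol:
        label = "L"
    elif s < -degeneracy_tol:
        label = "R"
    else:
        label = "X"
    if convention == "C2":
        label = _flip_label(label)
    return label


def handedness_string(profile: TMProfile, core_only: bool = True,
                      config: ToolConfig = DEFAULT_CONFIG) -> HandednessString:
    """Concatenated triplet labels over consecutive (core) segments.

    With ``core_only`` (the default) non-core segments — coupling helices,
    decorations — are skipped, so the string describes the conserved core
    arrangement.  Requires at least 3 qualifying segments.
    """
    segs = profile.core_segments() if core_only else profile.segments
    if len(segs) < 3:
        raise ValueError(f"need >= 3 {'core ' if core_only else ''}segments "
                         f"for a handedness string, got {len(segs)}")
    labels = []
    for a, b, c in zip(segs, segs[1:], segs[2:]):
        labels.append(triplet_handedness(
            a.centroid, b.centroid, c.centroid, profile.frame,
            degeneracy_tol=config.degeneracy_tol,
            convention=config.handedness_convention))
    return HandednessString("".join(labels))


def build_profile(chain_coords: ChainCoords,
                  tm_ranges: Sequence[ResidueInterval],
                  frame: MembraneFrame | None = None,
                  *,
                  is_core: Sequence[bool] | None = None,
                  is_coupling: Sequence[bool] | None = None,
                  label: str = "",
                  config: ToolConfig = DEFAULT_CONFIG) -> TMProfile:
    """Fit a :class:`TMProfile` from coordinates and TM residue ranges.

    ``chain_coords`` holds (residue_number, position) pairs for the Cα of
    one chain.  Ranges may arrive in any order; the profile is sorted to
    chain order, and the per-range flags follow their range.  Each range
    must have Cα coordinates for at least 80% of its residues (and at
    least 5 in absolute terms).
    """
    if frame is None:
        frame = default_frame()
    nseg = len(tm_ranges)
    if nseg == 0:
        raise ValueError("at least one TM range is required")
    flags_core = list(is_core) if is_core is not None else [True] * nseg
    flags_coupling = (list(is_coupling) if is_coupling is not None
                      else [False] * nseg)
    if len(flags_core) != nseg or len(flags_coupling) != nseg:
        raise ValueError("flag lists must match the number of ranges")

    order = sorted(range(nseg), key=lambda i: tm_ranges[i].start)
    by_resnum = {num: np.asarray(xyz, dtype=float) for num, xyz in chain_coords}

    segments = []
    for ordinal, i in enumerate(order, start=1):
        rng = tm_ranges[i]
        pts = [by_resnum[r] for r in rng.residues() if r in by_resnum]
        if len(pts) < max(5, int(np.ceil(0.8 * rng.length))):
            raise ValueError(
                f"TM range {rng} has only {len(pts)} Cα of {rng.length} "
                f"residues (need >= 80% and >= 5)")
        axis, centroid = fit_helix_axis(np.array(pts))
        segments.append(TMSegment(
            index=ordinal, interval=rng, axis=axis, centroid=centroid,
            orientation=segment_orientation(axis, frame,
                                            config.orientation_min_cos),
            is_core=flags_core[i], is_coupling_helix=flags_coupling[i]))
    return TMProfile(segments=tuple(segments), frame=frame, label=label)
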