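"""Ground-truthed synthetic inputs for every other module.

Two generators:

* :func:`make_helix_bundle` builds ideal Cα helix bundles with prescribed
  in-plane centroid positions and up/down orientation pattern, together
  with the analytically known orientation and handedness truth;
* :func:`make_partition_scenario` builds a chain record plus alignment
  hits with prescribed true domains, boundary jitter, decoys, fragment
  hits and unknown-residue runs, together with the truth triage outcome.

All randomness flows through each spec's seed, so identical specs give
byte-identical outputs.  At zero noise the analysis modules must
reproduce the generator truth exactly — the closed-loop property the
test-suite leans on.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, ToolConfig
from .geometry import (MembraneFrame, Orientation, TMProfile, TMSegment,
                       default_frame)
from .intervals import ResidueInterval, check_sorted_disjoint
from .partition import (AlignmentHit, ChainRecord, Method, PartitionResult,
                        partition_chain)

#: plane angles (degrees) of ring-placed helices whose consecutive-triplet
#: turn senses are clockwise, clockwise, counter-clockwise, counter-clockwise
#: when viewed from +normal — i.e. handedness "RRLL" under convention C1,
#: the pattern of the six-segment intramembrane-protease-like core.
RRLL_ANGLES = (90.0, 30.0, -30.0, -90.0, -60.0, 150.0)

#: four helices progressing clockwise: both triplets right-handed ("RR"),
#: the pattern of the four-segment ABC-transporter TMD core.
RR_ANGLES = (90.0, 30.0, -30.0, -90.0)


@dataclass(frozen=True)
class BundleSpec:
    """Recipe for an ideal Cα helix bundle.

    Helix i is placed with its axis vertical (±z per
    ``orientation_pattern``: U rises with residue number, D descends,
    P lies in the membrane plane) at ring position
    ``ring_radius * (cos a_i, sin a_i)`` for angle ``a_i`` (degrees) from
    ``angular_order``.  Canonical α-helix geometry: 1.5 Å rise and 100°
    twist per residue on a 2.3 Å helical radius.
    """

    n_segments: int
    ring_radius: float = 12.0
    helix_length: int = 22
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_radius: float = 2.3
    angular_order: Optional[tuple[float, ...]] = None
    orientation_pattern: Optional[str] = None
    core_flags: Optional[tuple[bool, ...]] = None
    coupling_flags: Optional[tuple[bool, ...]] = None
    loop_gap: int = 4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.helix_length < 5:
            raise ValueError("helix_length must be >= 5")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        ang = self.angles()
        if len(set(ang)) != len(ang):
            raise ValueError("angular positions must be distinct")
        if len(ang) != self.n_segments:
            raise ValueError("angular_order length must equal n_segments")
        if len(self.pattern()) != self.n_segments:
            raise ValueError("orientation_pattern length must equal "
                             "n_segments")
        if any(ch not in "UDP" for ch in self.pattern()):
            raise ValueError("orientation_pattern must be over {U, D, P}")

    def angles(self) -> tuple[float, ...]:
        if self.angular_order is not None:
            return tuple(self.angular_order)
        # default: evenly spaced counter-clockwise around the ring
        return tuple(i * 360.0 / self.n_segments
                     for i in range(self.n_segments))

    def pattern(self) -> str:
        if self.orientation_pattern is not None:
            return self.orientation_pattern
        return "".join("U" if i % 2 == 0 else "D"
                       for i in range(self.n_segments))


@dataclass(frozen=True)
class BundleFixture:
    """A generated bundle: coordinates, ranges, frame and analytic truth."""

    spec: BundleSpec
    chain_coords: tuple[tuple[int, np.ndarray], ...]
    tm_ranges: tuple[ResidueInterval, ...]
    is_core: tuple[bool, ...]
    is_coupling: tuple[bool, ...]
    frame: MembraneFrame
    truth_orientations: tuple[Orientation, ...]
    truth_handedness: str


def signed_area_turn_labels(points: Sequence[Sequence[float]],
                            degeneracy_tol: float = 0.0,
                            convention: str = "C1") -> str:
    """Triplet turn labels of 2-D points from the signed parallelogram area.

    Independent closed-form rule used as the generator's analytic truth:
    for consecutive points p1, p2, p3 the z-component of
    (p2 - p1) × (p3 - p2), normalised by the segment lengths, is positive
    for a counter-clockwise turn (label L under C1) and negative for a
    clockwise turn (label R).
    """
    pts = [np.asarray(p, dtype=float)[:2] for p in points]
    labels = []
    for p1, p2, p3 in zip(pts, pts[1:], pts[2:]):
        d1, d2 = p2 - p1, p3 - p2
        cross = d1[0] * d2[1] - d1[1] * d2[0]
        s = cross / (np.linalg.norm(d1) * np.linalg.norm(d2))
        if s > degeneracy_tol:
            lab = "L"
        elif s < -degeneracy_tol:
            lab = "R"
        else:
            lab = "X"
        if convention == "C2":
            lab = {"R": "L", "L": "R", "X": "X"}[lab]
        labels.append(lab)
    return "".join(labels)


def _ideal_helix(n_res: int, rise: float, twist_deg: float,
                 radius: float) -> np.ndarray:
    """Right-handed ideal helix along +z, centred on the z axis."""
    j = np.arange(n_res, dtype=float)
    phi = np.deg2rad(twist_deg) * j
    z = rise * (j - (n_res - 1) / 2.0)
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])


# rotation by pi about the x axis: reverses z without mirroring the helix
_FLIP = np.diag([1.0, -1.0, -1.0])
# maps +z to +x (rotation about y): used for in-plane helices
_INPLANE = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def make_helix_bundle(spec: BundleSpec) -> BundleFixture:
    """Generate an ideal bundle and its analytic truth.

    Raises ValueError when two helices would clash (in-plane centroid
    distance below twice the helix radius).
    """
    angles = spec.angles()
    pattern = spec.pattern()
    centres = [np.array([spec.ring_radius * math.cos(math.radians(a)),
                         spec.ring_radius * math.sin(math.radians(a)),
                         0.0]) for a in angles]
    for i in range(len(centres)):
        for j in range(i + 1, len(centres)):
            if np.linalg.norm((centres[i] - centres[j])[:2]) \
                    < 2 * spec.helix_radius:
                raise ValueError(
                    f"helices {i + 1} and {j + 1} overlap: centroid "
                    f"distance < {2 * spec.helix_radius:.1f} Å")

    rng = np.random.default_rng(spec.seed)
    coords: list[tuple[int, np.ndarray]] = []
    ranges: list[ResidueInterval] = []
    resnum = 1
    for i, (centre, ch) in enumerate(zip(centres, pattern)):
        helix = _ideal_helix(spec.helix_length, spec.rise_per_residue,
                             spec.twist_per_residue, spec.helix_radius)
        if ch == "D":
            helix = helix @ _FLIP.T
        elif ch == "P":
            # in-plane helix sitting below the membrane centre
            helix = helix @ _INPLANE.T
            centre = centre + np.array([0.0, 0.0, -12.0])
        helix = helix + centre
        if spec.noise_sigma > 0:
            helix = helix + rng.normal(0.0, spec.noise_sigma, helix.shape)
        start = resnum
        for k in range(spec.helix_length):
            coords.append((resnum, helix[k]))
            resnum += 1
        ranges.append(ResidueInterval(start, resnum - 1))
        resnum += spec.loop_gap

    is_core = (tuple(spec.core_flags) if spec.core_flags is not None
               else tuple(ch != "P" for ch in pattern))
    is_coupling = (tuple(spec.coupling_flags)
                   if spec.coupling_flags is not None
                   else tuple(ch == "P" for ch in pattern))
    truth_orient = tuple(
        Orientation.UP if ch == "U"
        else Orientation.DOWN if ch == "D"
        else Orientation.UNDEFINED
        for ch in pattern)
    core_centres = [c for c, core in zip(centres, is_core) if core]
    truth_hand = signed_area_turn_labels([c[:2] for c in core_centres])
    return BundleFixture(
        spec=spec,
        chain_coords=tuple(coords),
        tm_ranges=tuple(ranges),
        is_core=is_core,
        is_coupling=is_coupling,
        frame=default_frame(),
        truth_orientations=truth_orient,
        truth_handedness=truth_hand,
    )


def bundle_preset(name: str, seed: int = 0,
                  noise_sigma: float = 0.0) -> BundleSpec:
    """Named bundle recipes.

    ``rrll``: six-helix core with handedness RRLL (the shared core of the
    intramembrane protease pair).  ``rr``: four-helix core with handedness
    RR (the ABC transporter TMD core).  ``rr_coupling``: the same four-helix
    core plus an in-plane coupling helix between core segments 2 and 3.
    ``ring``: six helices evenly spaced counter-clockwise (handedness LLLL).
    """
    if name == "rrll":
        return BundleSpec(n_segments=6, angular_order=RRLL_ANGLES,
                          orientation_pattern="UDUDUD", seed=seed,
                          noise_sigma=noise_sigma)
    if name == "rr":
        return BundleSpec(n_segments=4, angular_order=RR_ANGLES,
                          orientation_pattern="UDUD", seed=seed,
                          noise_sigma=noise_sigma)
    if name == "rr_coupling":
        # coupling helix placed between the 2nd and 3rd core segments,
        # in the plane, below the membrane (cytoplasmic side)
        return BundleSpec(n_segments=5,
                          angular_order=(90.0, 30.0, 0.0, -30.0, -90.0),
                          orientation_pattern="UDPUD",
                          helix_length=12,
                          seed=seed, noise_sigma=noise_sigma)
    if name == "ring":
        return BundleSpec(n_segments=6, seed=seed, noise_sigma=noise_sigma)
    raise ValueError(f"unknown bundle preset: {name!r}")


# --------------------------------------------------------------------------
# abstract profiles (no coordinates) for topology-alignment studies
# --------------------------------------------------------------------------

def make_abstract_profile(orientations: str,
                          lengths: Sequence[int],
                          label: str = "",
                          ring_radius: float = 12.0,
                          is_core: Sequence[bool] | None = None,
                          loop_gap: int = 4) -> TMProfile:
    """Build a TMProfile directly from an orientation pattern and segment
    lengths, with centroids evenly spaced counter-clockwise on a ring.

    Intended for alignment studies where only segment order, orientation
    and length matter; the ring centroids make handedness computable but
    carry no particular meaning.
    """
    n = len(orientations)
    if len(lengths) != n:
        raise ValueError("lengths must match orientation pattern")
    flags = list(is_core) if is_core is not None else [True] * n
    frame = default_frame()
    segs = []
    start = 1
    for i, (ch, ln) in enumerate(zip(orientations, lengths)):
        angle = 2 * math.pi * i / max(n, 3)
        centroid = np.array([ring_radius * math.cos(angle),
                             ring_radius * math.sin(angle), 0.0])
        if ch == "U":
            axis = np.array([0.0, 0.0, 1.0])
            orient = Orientation.UP
        elif ch == "D":
            axis = np.array([0.0, 0.0, -1.0])
            orient = Orientation.DOWN
        else:
            axis = np.array([1.0, 0.0, 0.0])
            orient = Orientation.UNDEFINED
        segs.append(TMSegment(index=i + 1,
                              interval=ResidueInterval(start, start + ln - 1),
                              axis=axis, centroid=centroid, orientation=orient,
                              is_core=flags[i]))
        start += ln + loop_gap
    return TMProfile(segments=tuple(segs), frame=frame, label=label)


def random_profile(rng: np.random.Generator,
                   n_segments: Optional[int] = None,
                   label: str = "") -> TMProfile:
    """A random abstract profile: 3-12 segments, random U/D orientations,
    random lengths between 15 and 40 residues."""
    n = int(n_segments) if n_segments is not None \
        else int(rng.integers(3, 13))
    orient = "".join(rng.choice(["U", "D"]) for _ in range(n))
    lengths = [int(rng.integers(15, 41)) for _ in range(n)]
    return make_abstract_profile(orient, lengths, label=label)


def rotate_profile(profile: TMProfile, k: int,
                   label: str = "") -> TMProfile:
    """A circularly permuted copy: the first k segments are moved to the
    C-terminus, as in a genuine circular-permutation event.

    The new chain's segments are renumbered in their new order and given
    fresh sequential residue intervals of the same lengths; orientations
    and centroids (the preserved 3-D arrangement) are kept.
    """
    n = len(profile.segments)
    k = k % n
    order = list(profile.segments[k:]) + list(profile.segments[:k])
    segs = []
    start = 1
    for i, old in enumerate(order):
        ln = old.length
        segs.append(TMSegment(index=i + 1,
                              interval=ResidueInterval(start, start + ln - 1),
                              axis=old.axis, centroid=old.centroid,
                              orientation=old.orientation,
                              is_core=old.is_core,
                              is_coupling_helix=old.is_coupling_helix))
        start += ln + 4
    return TMProfile(segments=tuple(segs), frame=profile.frame, label=label)


# --------------------------------------------------------------------------
# partition scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionScenario:
    """Recipe for a triage scenario with known truth.

    ``true_domains`` are the intended non-overlapping domain intervals;
    evidence hits are emitted at those boundaries ± ``hit_noise`` residues
    of jitter, along with ``decoys`` low-scoring overlapping hits and
    ``fragments`` low-reference-coverage hits.
    """

    chain_id: str
    chain_length: int
    true_domains: tuple[tuple[str, ResidueInterval], ...] = ()
    hit_noise: int = 0
    decoys: int = 0
    fragments: int = 0
    unknown_runs: tuple[ResidueInterval, ...] = ()
    tm_runs: tuple[ResidueInterval, ...] = ()
    method: Method = Method.XRAY
    synthetic_flag: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        ivs = sorted(iv for _, iv in self.true_domains)
        check_sorted_disjoint(tuple(ivs), "true_domains")
        for _, iv in self.true_domains:
            if iv.end > self.chain_length:
                raise ValueError(f"true domain {iv} outside chain")


@dataclass(frozen=True)
class ScenarioFixture:
    chain: ChainRecord
    hits: tuple[AlignmentHit, ...]
    truth: PartitionResult


def _domain_hits(spec: PartitionScenario, jitter: int,
                 rng: np.random.Generator) -> list[AlignmentHit]:
    hits = []
    for i, (dom_id, iv) in enumerate(spec.true_domains):
        start, end = iv.start, iv.end
        if jitter > 0:
            start = int(np.clip(start + rng.integers(-jitter, jitter + 1),
                                1, spec.chain_length))
            end = int(np.clip(end + rng.integers(-jitter, jitter + 1),
                              1, spec.chain_length))
            if end < start:
                start, end = end, start
        hits.append(AlignmentHit(
            ref_domain_id=dom_id,
            query_intervals=(ResidueInterval(start, end),),
            ref_length=iv.length,
            ref_coverage=0.95,
            score=100.0 - 5.0 * i,
        ))
    return hits


def make_partition_scenario(spec: PartitionScenario,
                            config: ToolConfig = DEFAULT_CONFIG,
                            ) -> ScenarioFixture:
    """Generate the chain record, evidence hits and truth outcome.

    The truth is the triage result of the noiseless configuration (zero
    boundary jitter, same decoys and fragments), so at ``hit_noise == 0``
    the pipeline output must equal the truth exactly.
    """
    chain = ChainRecord(
        chain_id=spec.chain_id,
        length=spec.chain_length,
        unknown_mask=frozenset(
            r for iv in spec.unknown_runs for r in iv.residues()),
        tm_annotations=tuple(sorted(spec.tm_runs)),
        method=spec.method,
        synthetic_flag=spec.synthetic_flag,
    )

    # decoys and fragments are deterministic in the seed and identical in
    # the noiseless and jittered variants
    rng_extra = np.random.default_rng(spec.seed)
    extras: list[AlignmentHit] = []
    for i in range(spec.decoys):
        if not spec.true_domains:
            break
        _, target = spec.true_domains[int(rng_extra.integers(
            0, len(spec.true_domains)))]
        span = min(40, target.length)
        start = int(rng_extra.integers(target.start,
                                       max(target.start,
                                           target.end - span + 1) + 1))
        end = min(start + span - 1, spec.chain_length)
        extras.append(AlignmentHit(
            ref_domain_id=f"decoy{i + 1}",
            query_intervals=(ResidueInterval(start, end),),
            ref_length=span, ref_coverage=0.9,
            score=float(rng_extra.integers(5, 20))))
    for i in range(spec.fragments):
        start = int(rng_extra.integers(1, max(2, spec.chain_length - 25)))
        end = min(start + 24, spec.chain_length)
        extras.append(AlignmentHit(
            ref_domain_id=f"frag{i + 1}",
            query_intervals=(ResidueInterval(start, end),),
            ref_length=120, ref_coverage=0.35,
            score=float(rng_extra.integers(20, 40))))

    rng_jit = np.random.default_rng(spec.seed + 1)
    hits = tuple(_domain_hits(spec, spec.hit_noise, rng_jit) + extras)
    clean = tuple(_domain_hits(spec, 0, np.random.default_rng(spec.seed + 1))
                  + extras)
    truth = partition_chain(chain, clean, config)
    return ScenarioFixture(chain=chain, hits=hits, truth=truth)


def make_outcome_records(total: int,
                         n_single: int, n_multi: int,
                         n_part_special: int, n_all_special: int,
                         n_tm: int, n_xray: int, n_em: int,
                         ) -> list[tuple[PartitionResult, ChainRecord]]:
    """Construct a synthetic collection of triage outcomes with prescribed
    category counts, for exercising :func:`summarize_outcomes`.

    Records are laid out deterministically by position: the first
    ``n_single`` chains carry one assignment, the next ``n_multi`` two;
    special-architecture tags are attached to the first ``n_part_special``
    assigned chains and to ``n_all_special`` unassigned chains;
    TM annotations and determination methods are assigned positionally.
    The counts must be mutually consistent (e.g. part-special cannot
    exceed the number of assigned chains).
    """
    from .partition import (ArchitectureTag, DomainAssignment, Outcome,
                            PartitionResult)

    n_assigned = n_single + n_multi
    if n_assigned > total or n_part_special > n_assigned:
        raise ValueError("inconsistent category counts")
    if n_assigned + n_all_special > total:
        raise ValueError("inconsistent special-architecture counts")
    if max(n_tm, n_xray + n_em) > total:
        raise ValueError("inconsistent method/TM counts")

    records = []
    length = 250
    for i in range(total):
        if i < n_xray:
            method = Method.XRAY
        elif i < n_xray + n_em:
            method = Method.EM
        else:
            method = Method.OTHER
        tm = (ResidueInterval(30, 52),) if i < n_tm else ()
        chain = ChainRecord(chain_id=f"c{i:04d}", length=length,
                            tm_annotations=tm, method=method)

        tags: set[ArchitectureTag] = set()
        if i < n_single:
            hit = AlignmentHit("ref", (ResidueInterval(1, 240),), 240,
                               0.95, 50.0)
            assignments = (DomainAssignment("ref", hit.query_intervals, hit),)
            tags.add(ArchitectureTag.SINGLE_DOMAIN)
        elif i < n_assigned:
            h1 = AlignmentHit("refA", (ResidueInterval(1, 120),), 120,
                              0.95, 50.0)
            h2 = AlignmentHit("refB", (ResidueInterval(121, 240),), 120,
                              0.95, 45.0)
            assignments = (
                DomainAssignment("refA", h1.query_intervals, h1),
                DomainAssignment("refB", h2.query_intervals, h2))
            tags.add(ArchitectureTag.MULTI_DOMAIN)
        else:
            assignments = ()
        if i < n_part_special or n_assigned <= i < n_assigned + n_all_special:
            tags.add(ArchitectureTag.FRAGMENT)
        if tm:
            tags.add(ArchitectureTag.TM_CONTAINING)

        gaps = (ResidueInterval(241, 250),) if not assignments else ()
        outcome = Outcome.FLAGGED if (tags & {ArchitectureTag.FRAGMENT}
                                      or not assignments) \
            else Outcome.AUTO_ACCEPTED
        from .partition import Reason
        reasons = frozenset() if outcome is Outcome.AUTO_ACCEPTED \
            else frozenset({Reason.UNASSIGNABLE})
        result = PartitionResult(
            chain_id=chain.chain_id, assignments=assignments, gaps=gaps,
            outcome=outcome, reasons=reasons,
            architecture_tags=frozenset(tags))
        records.append((result, chain))
    return records
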