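"""Tool-wide configuration.

Every threshold used by the partition, geometry and topology-alignment
modules lives here, with defaults, so that a single object (optionally
loaded from a YAML file) controls the whole pipeline.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

_CONVENTIONS = ("C1", "C2")


@dataclass(frozen=True)
class ToolConfig:
    """Thresholds and weights for partition triage and TM topology descriptors.

    Partition triage
    ----------------
    min_cover_frac:
        Minimum fraction of classifiable (non-masked) residues that must be
        covered by accepted domain assignments for a chain to be
        auto-accepted ("complete or nearly so").
    gap_max:
        An unassigned, unmasked run of at least this many residues counts
        as a potentially novel region and blocks auto-acceptance.
    overlap_tol_residues / overlap_tol_frac:
        A candidate hit may overlap already-accepted residues by at most
        this many residues AND at most this fraction of its own length;
        the overlapping residues are trimmed from the incoming hit.
    conflict_score_ratio:
        A rejected hit whose score is at least this ratio of an accepted
        hit it overlaps (beyond tolerance) signals comparable competing
        parses, i.e. inconsistent boundaries.
    min_ref_coverage:
        Below this reference coverage a hit is discarded outright.
    fragment_coverage:
        Hits covering less than this fraction of their reference domain
        are set aside as fragment evidence (not used for assignment).
    min_domain_len:
        Hits shorter than this many query residues are discarded.
    peptide_max_len:
        Chains shorter than this with no domain assignment are tagged
        as peptides.

    TM geometry
    -----------
    orientation_min_cos:
        |cos| threshold between a segment axis and the membrane normal
        separating UP/DOWN from UNDEFINED (default 0.5, i.e. 60 degrees).
    degeneracy_tol:
        Threshold on the normalised turn-sense value below which a
        consecutive-triplet handedness label is X (degenerate).
    handedness_convention:
        "C1": clockwise progression of projected centroids viewed from
        the +normal side is right-handed (R). "C2" flips every label.

    Topology alignment
    ------------------
    w_or, w_len:
        Weights of the orientation-agreement and length-similarity terms
        of the segment pair score.
    g_open, g_ext:
        Affine penalty for internal (not terminal) gaps: a run of k
        skipped segments costs g_open + (k - 1) * g_ext.  Inserting an
        even number of segments preserves the up/down parity of the
        remainder, so only the length term can pay for an internal gap;
        the defaults keep g_open + g_ext below w_len so that inserted
        segments shorter than about half their displaced counterpart
        are gapped rather than mis-paired.
    cp_margin:
        A cyclic rotation must beat the unrotated alignment score by more
        than this margin to be reported as a circular permutation.
    """

    # partition triage
    min_cover_frac: float = 0.90
    gap_max: int = 30
    overlap_tol_residues: int = 10
    overlap_tol_frac: float = 0.25
    conflict_score_ratio: float = 0.8
    min_ref_coverage: float = 0.3
    fragment_coverage: float = 0.5
    min_domain_len: int = 20
    peptide_max_len: int = 20
    # TM geometry
    orientation_min_cos: float = 0.5
    degeneracy_tol: float = 0.05
    handedness_convention: str = "C1"
    # topology alignment
    w_or: float = 2.0
    w_len: float = 2.0
    g_open: float = 0.75
    g_ext: float = 0.25
    cp_margin: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_cover_frac", "overlap_tol_frac", "conflict_score_ratio",
                     "min_ref_coverage", "fragment_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gap_max", "min_domain_len", "peptide_max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.overlap_tol_residues < 0:
            raise ValueError("overlap_tol_residues must be >= 0")
        if not 0.0 <= self.orientation_min_cos < 1.0:
            raise ValueError("orientation_min_cos must be in [0, 1)")
        if self.degeneracy_tol < 0:
            raise ValueError("degeneracy_tol must be >= 0")
        if self.handedness_convention not in _CONVENTIONS:
            raise ValueError(
                f"handedness_convention must be one of {_CONVENTIONS}")
        for name in ("w_or", "w_len", "g_open", "g_ext", "cp_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes: Any) -> "ToolConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ToolConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ToolConfig":
        """Load a config from a YAML key-value file; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


DEFAULT_CONFIG = ToolConfig()
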