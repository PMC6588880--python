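"""Closed residue intervals, 1-based, following PDB residue-numbering habits."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class ResidueInterval:
    """A closed interval of residue indices: ``start <= i <= end``, 1-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}-{self.end}: need 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def overlaps(self, other: "ResidueInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersection_length(self, other: "ResidueInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "ResidueInterval":
        """Parse ``"12-45"`` (or a bare ``"12"`` for a single residue)."""
        text = text.strip()
        if "-" in text:
            a, b = text.split("-", 1)
            return cls(int(a), int(b))
        return cls(int(text), int(text))


def parse_interval_list(text: str) -> tuple[ResidueInterval, ...]:
    """Parse a comma-separated interval list like ``"1-100,150-200"``.

    An empty string or the placeholder ``"-"`` yields an empty tuple.
    """
    text = text.strip()
    if not text or text == "-" or text.lower() in {"na", "none"}:
        return ()
    return tuple(ResidueInterval.parse(part) for part in text.split(","))


def format_interval_list(intervals: Iterable[ResidueInterval]) -> str:
    parts = [str(iv) for iv in intervals]
    return ",".join(parts) if parts else "-"


def total_length(intervals: Iterable[ResidueInterval]) -> int:
    return sum(iv.length for iv in intervals)


def residues_of(intervals: Iterable[ResidueInterval]) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(iv.residues())
    return out


def intervals_from_residues(residues: Iterable[int]) -> tuple[ResidueInterval, ...]:
    """Collapse a residue-index set into maximal sorted runs."""
    idx = sorted(set(residues))
    if not idx:
        return ()
    runs: list[ResidueInterval] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append(ResidueInterval(start, prev))
        start = prev = i
    runs.append(ResidueInterval(start, prev))
    return tuple(runs)


def check_sorted_disjoint(intervals: Sequence[ResidueInterval],
                          what: str = "intervals") -> None:
    """Raise ValueError unless intervals are sorted and pairwise disjoint."""
    for a, b in zip(intervals, intervals[1:]):
        if b.start <= a.end:
            raise ValueError(f"{what} must be sorted and non-overlapping: "
                             f"{a} then {b}")
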