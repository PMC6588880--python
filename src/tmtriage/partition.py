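"""Domain-partition triage: from alignment evidence to accept-or-flag decisions.

A structure-classification pipeline accepts an automatic domain parse for a
protein chain when the evidence hits cover the chain completely (or nearly
so) and do not overlap with each other.  Chains for which no such parse
exists are flagged for manual curation, with a reason taxonomy:

* ``INCONSISTENT_BOUNDARIES`` — comparable, mutually incompatible parses
  exist, so no consistent set of domain boundaries can be chosen;
* ``NOVEL_REGION`` — a sizeable region has no detectable similarity to the
  reference domain set;
* ``UNASSIGNABLE`` — the problematic content is not an evolutionary domain
  at all (unknown residues, fragments of known domains, synthetic
  constructs).

This module implements that logic deterministically over
:class:`AlignmentHit` evidence, plus architecture tagging (peptide /
fragment / synthetic / single- vs multi-domain / TM-containing) and the
aggregation of many outcomes into a curation summary table.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import DEFAULT_CONFIG, ToolConfig
from .intervals import (ResidueInterval, check_sorted_disjoint,
                        intervals_from_residues, residues_of, total_length)


class Method(enum.Enum):
    """Structure-determination method of a deposition."""
    XRAY = "XRAY"
    EM = "EM"
    NMR = "NMR"
    OTHER = "OTHER"


class Outcome(enum.Enum):
    AUTO_ACCEPTED = "AUTO_ACCEPTED"
    FLAGGED = "FLAGGED"


class Reason(enum.Enum):
    INCONSISTENT_BOUNDARIES = "INCONSISTENT_BOUNDARIES"
    NOVEL_REGION = "NOVEL_REGION"
    UNASSIGNABLE = "UNASSIGNABLE"


class ArchitectureTag(enum.Enum):
    PEPTIDE = "PEPTIDE"
    FRAGMENT = "FRAGMENT"
    SYNTHETIC = "SYNTHETIC"
    SINGLE_DOMAIN = "SINGLE_DOMAIN"
    MULTI_DOMAIN = "MULTI_DOMAIN"
    TM_CONTAINING = "TM_CONTAINING"


#: Tags marking non-domain ("special architecture") content.
SPECIAL_TAGS = frozenset({ArchitectureTag.PEPTIDE, ArchitectureTag.FRAGMENT,
                          ArchitectureTag.SYNTHETIC})


class RejectReason(enum.Enum):
    TOO_SHORT = "TOO_SHORT"          # below min_domain_len
    FRAGMENT = "FRAGMENT"            # covers too little of its reference domain
    LOW_COVERAGE = "LOW_COVERAGE"    # below min_ref_coverage: dropped outright
    OVERLAP = "OVERLAP"              # displaced by a higher-priority hit


@dataclass(frozen=True)
class ChainRecord:
    """Per-chain metadata needed for triage decisions."""

    chain_id: str
    length: int
    unknown_mask: frozenset[int] = frozenset()
    tm_annotations: tuple[ResidueInterval, ...] = ()
    method: Method = Method.OTHER
    synthetic_flag: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chain length must be >= 1")
        object.__setattr__(self, "unknown_mask", frozenset(self.unknown_mask))
        object.__setattr__(self, "tm_annotations", tuple(self.tm_annotations))
        for i in self.unknown_mask:
            if not 1 <= i <= self.length:
                raise ValueError(f"masked residue {i} outside chain "
                                 f"1-{self.length}")
        for iv in self.tm_annotations:
            if iv.end > self.length:
                raise ValueError(f"TM annotation {iv} outside chain "
                                 f"1-{self.length}")
        check_sorted_disjoint(self.tm_annotations, "tm_annotations")


@dataclass(frozen=True)
class AlignmentHit:
    """One piece of evidence mapping a reference domain onto the query.

    ``query_intervals`` may hold several intervals (discontinuous domains).
    ``ref_coverage`` is the fraction of the reference domain covered by the
    alignment; ``score`` is any non-negative higher-is-better quantity.
    """

    ref_domain_id: str
    query_intervals: tuple[ResidueInterval, ...]
    ref_length: int
    ref_coverage: float
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "query_intervals", tuple(self.query_intervals))
        if not self.query_intervals:
            raise ValueError("hit needs at least one query interval")
        check_sorted_disjoint(self.query_intervals, "query_intervals")
        if self.ref_length < 1:
            raise ValueError("ref_length must be >= 1")
        if not 0.0 <= self.ref_coverage <= 1.0:
            raise ValueError("ref_coverage must be in [0, 1]")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def total_query_length(self) -> int:
        return total_length(self.query_intervals)

    def query_residues(self) -> set[int]:
        return residues_of(self.query_intervals)


@dataclass(frozen=True)
class DomainAssignment:
    """An accepted (possibly trimmed) placement of a reference domain."""

    ref_domain_id: str
    query_intervals: tuple[ResidueInterval, ...]
    source_hit: AlignmentHit
    trimmed_residues: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "query_intervals", tuple(self.query_intervals))
        check_sorted_disjoint(self.query_intervals, "query_intervals")
        if not 0 <= self.trimmed_residues <= self.source_hit.total_query_length:
            raise ValueError("trimmed_residues out of range")


@dataclass(frozen=True)
class PartitionResult:
    """The triage outcome for one chain."""

    chain_id: str
    assignments: tuple[DomainAssignment, ...]
    gaps: tuple[ResidueInterval, ...]
    outcome: Outcome
    reasons: frozenset[Reason] = frozenset()
    architecture_tags: frozenset[ArchitectureTag] = frozenset()
    covered_frac: float = 0.0
    conflict: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", tuple(self.assignments))
        object.__setattr__(self, "gaps", tuple(self.gaps))
        object.__setattr__(self, "reasons", frozenset(self.reasons))
        object.__setattr__(self, "architecture_tags",
                           frozenset(self.architecture_tags))
        if self.outcome is Outcome.AUTO_ACCEPTED and self.reasons:
            raise ValueError("auto-accepted results carry no reasons")
        tags = self.architecture_tags
        if (ArchitectureTag.SINGLE_DOMAIN in tags
                and ArchitectureTag.MULTI_DOMAIN in tags):
            raise ValueError("SINGLE_DOMAIN and MULTI_DOMAIN are exclusive")


@dataclass(frozen=True)
class FilteredHits:
    """Outcome of evidence filtering: usable hits plus set-aside evidence."""

    kept: tuple[AlignmentHit, ...]
    rejected: tuple[tuple[AlignmentHit, RejectReason], ...]

    @property
    def fragment_hits(self) -> tuple[AlignmentHit, ...]:
        return tuple(h for h, r in self.rejected if r is RejectReason.FRAGMENT)


# --------------------------------------------------------------------------
# pipeline operations
# --------------------------------------------------------------------------

def filter_hits(hits: Sequence[AlignmentHit],
                config: ToolConfig = DEFAULT_CONFIG) -> FilteredHits:
    """Drop hits that cannot support a domain assignment.

    A hit is kept when it is long enough (``min_domain_len``) and covers
    enough of its reference domain (``fragment_coverage``).  Hits covering
    less than ``fragment_coverage`` but at least ``min_ref_coverage`` of the
    reference are retained separately as FRAGMENT evidence: they cannot
    place a domain, but their existence matters for architecture tagging.
    Hits below ``min_ref_coverage`` are discarded as noise.
    """
    kept: list[AlignmentHit] = []
    rejected: list[tuple[AlignmentHit, RejectReason]] = []
    for hit in hits:
        if hit.ref_coverage < config.min_ref_coverage:
            rejected.append((hit, RejectReason.LOW_COVERAGE))
        elif hit.ref_coverage < config.fragment_coverage:
            rejected.append((hit, RejectReason.FRAGMENT))
        elif hit.total_query_length < config.min_domain_len:
            rejected.append((hit, RejectReason.TOO_SHORT))
        else:
            kept.append(hit)
    return FilteredHits(kept=tuple(kept), rejected=tuple(rejected))


def _priority_key(hit: AlignmentHit) -> tuple:
    # greedy order: best score, then longest, then lexicographic id
    return (-hit.score, -hit.total_query_length, hit.ref_domain_id)


def resolve_overlaps(hits: Sequence[AlignmentHit],
                     config: ToolConfig = DEFAULT_CONFIG,
                     ) -> tuple[tuple[DomainAssignment, ...], bool]:
    """Greedy non-overlapping selection of hits, trimming small overlaps.

    Hits are taken in deterministic priority order (score desc, length
    desc, reference id).  A hit is accepted when its overlap with already
    accepted residues is at most ``overlap_tol_residues`` AND at most
    ``overlap_tol_frac`` of its own length; the overlapping residues are
    trimmed from the incoming (lower-priority) hit.

    Returns the assignments plus a conflict flag: True when some rejected
    hit scores at least ``conflict_score_ratio`` of an accepted hit it
    overlaps beyond the tolerance — the signature of comparable competing
    parses for which no consistent boundary set exists.
    """
    order = sorted(hits, key=_priority_key)
    occupied: set[int] = set()
    accepted: list[tuple[DomainAssignment, AlignmentHit, set[int]]] = []
    rejected: list[AlignmentHit] = []
    for hit in order:
        res = hit.query_residues()
        overlap = len(res & occupied)
        within_tol = (overlap <= config.overlap_tol_residues
                      and overlap <= config.overlap_tol_frac * len(res))
        if within_tol:
            remaining = res - occupied
            if not remaining:
                rejected.append(hit)
                continue
            asn = DomainAssignment(
                ref_domain_id=hit.ref_domain_id,
                query_intervals=intervals_from_residues(remaining),
                source_hit=hit,
                trimmed_residues=overlap,
            )
            accepted.append((asn, hit, remaining))
            occupied |= remaining
        else:
            rejected.append(hit)

    conflict = False
    for hit in rejected:
        res = hit.query_residues()
        for asn, acc_hit, acc_res in accepted:
            overlap = len(res & acc_res)
            beyond_tol = (overlap > config.overlap_tol_residues
                          or overlap > config.overlap_tol_frac * len(res))
            if beyond_tol and acc_hit.score > 0 and \
                    hit.score >= config.conflict_score_ratio * acc_hit.score:
                conflict = True
                break
        if conflict:
            break

    assignments = tuple(asn for asn, _, _ in accepted)
    # report assignments in chain order, not acceptance order
    assignments = tuple(sorted(assignments,
                               key=lambda a: a.query_intervals[0].start))
    return assignments, conflict


def compute_coverage(assignments: Sequence[DomainAssignment],
                     chain: ChainRecord,
                     ) -> tuple[float, tuple[ResidueInterval, ...]]:
    """Coverage fraction over classifiable residues, and the gap intervals.

    The denominator excludes masked (unknown) residues; gaps are maximal
    runs of residues that are neither assigned nor masked.  A chain whose
    residues are all masked is defined to be fully covered.
    """
    assigned: set[int] = set()
    for asn in assignments:
        for iv in asn.query_intervals:
            if iv.end > chain.length:
                raise ValueError(f"assignment {iv} exceeds chain length "
                                 f"{chain.length}")
        assigned |= residues_of(asn.query_intervals)
    masked = set(chain.unknown_mask)
    classifiable = chain.length - len(masked)
    if classifiable == 0:
        return 1.0, ()
    covered = len(assigned - masked)
    uncovered = [i for i in range(1, chain.length + 1)
                 if i not in assigned and i not in masked]
    return covered / classifiable, intervals_from_residues(uncovered)


def decide_outcome(chain: ChainRecord,
                   assignments: Sequence[DomainAssignment],
                   covered_frac: float,
                   gaps: Sequence[ResidueInterval],
                   conflict_flag: bool,
                   config: ToolConfig = DEFAULT_CONFIG) -> PartitionResult:
    """Accept the parse automatically, or flag the chain with reasons.

    Auto-acceptance requires near-complete coverage, no gap of
    ``gap_max`` or more residues, and no boundary conflict.  Reasons for
    flagged chains: conflicts give INCONSISTENT_BOUNDARIES; large gaps on
    a natural chain give NOVEL_REGION; failures explained by synthetic or
    masked/short-gap content alone give UNASSIGNABLE.
    """
    big_gap = any(g.length >= config.gap_max for g in gaps)
    accepted = (covered_frac >= config.min_cover_frac
                and not big_gap
                and not conflict_flag)
    if accepted:
        return PartitionResult(
            chain_id=chain.chain_id, assignments=tuple(assignments),
            gaps=tuple(gaps), outcome=Outcome.AUTO_ACCEPTED,
            covered_frac=covered_frac, conflict=False)

    reasons: set[Reason] = set()
    if conflict_flag:
        reasons.add(Reason.INCONSISTENT_BOUNDARIES)
    if big_gap and not chain.synthetic_flag:
        reasons.add(Reason.NOVEL_REGION)
    # synthetic content, or a coverage shortfall made only of masked
    # residues and sub-threshold gaps, is unassignable rather than novel
    if chain.synthetic_flag or not reasons:
        reasons.add(Reason.UNASSIGNABLE)
    return PartitionResult(
        chain_id=chain.chain_id, assignments=tuple(assignments),
        gaps=tuple(gaps), outcome=Outcome.FLAGGED,
        reasons=frozenset(reasons), covered_frac=covered_frac,
        conflict=conflict_flag)


def classify_architecture(result: PartitionResult,
                          chain: ChainRecord,
                          config: ToolConfig = DEFAULT_CONFIG,
                          *,
                          fragment_only_evidence: bool = False,
                          ) -> PartitionResult:
    """Attach architecture tags to a triage result.

    ``fragment_only_evidence`` is True when the only evidence for the chain
    was fragment-rejected hits (the chain looks like a fragment of a known
    domain rather than a full domain).
    """
    tags: set[ArchitectureTag] = set(result.architecture_tags)
    n = len(result.assignments)
    if chain.length < config.peptide_max_len and n == 0:
        tags.add(ArchitectureTag.PEPTIDE)
    if chain.synthetic_flag:
        tags.add(ArchitectureTag.SYNTHETIC)
    if n == 0 and fragment_only_evidence:
        tags.add(ArchitectureTag.FRAGMENT)
    if n == 1:
        tags.add(ArchitectureTag.SINGLE_DOMAIN)
    elif n >= 2:
        tags.add(ArchitectureTag.MULTI_DOMAIN)
    if chain.tm_annotations:
        tags.add(ArchitectureTag.TM_CONTAINING)
    return replace(result, architecture_tags=frozenset(tags))


def partition_chain(chain: ChainRecord,
                    hits: Sequence[AlignmentHit],
                    config: ToolConfig = DEFAULT_CONFIG) -> PartitionResult:
    """Run the full triage pipeline for one chain."""
    filtered = filter_hits(hits, config)
    assignments, conflict = resolve_overlaps(filtered.kept, config)
    covered_frac, gaps = compute_coverage(assignments, chain)
    result = decide_outcome(chain, assignments, covered_frac, gaps,
                            conflict, config)
    fragment_only = (not filtered.kept) and bool(filtered.fragment_hits)
    return classify_architecture(result, chain, config,
                                 fragment_only_evidence=fragment_only)


# --------------------------------------------------------------------------
# curation summary
# --------------------------------------------------------------------------

#: Categories reported by :func:`summarize_outcomes`, in output order.
SUMMARY_CATEGORIES = (
    "any_unclassifiable_region",
    "all_special_architecture",
    "part_special_architecture",
    "any_domain_assigned",
    "single_domain_only",
    "multi_domain",
    "tm_containing",
    "xray",
    "em",
)


@dataclass(frozen=True)
class CurationSummary:
    """Counts and integer percentages over a collection of triage outcomes."""

    total_chains: int
    counts: Mapping[str, int]
    percentages: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "percentages", dict(self.percentages))
        for cat, c in self.counts.items():
            if not 0 <= c <= self.total_chains:
                raise ValueError(f"count for {cat} out of range")


def percentage(count: int, total: int) -> int:
    """Integer percentage with round-half-up, computed exactly."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (200 * count + total) // (2 * total)


def _category_flags(result: PartitionResult, chain: ChainRecord) -> dict[str, bool]:
    special = bool(result.architecture_tags & SPECIAL_TAGS)
    has_asn = bool(result.assignments)
    return {
        "any_unclassifiable_region": special or bool(chain.unknown_mask),
        "all_special_architecture": special and not has_asn,
        "part_special_architecture": special and has_asn,
        "any_domain_assigned": has_asn,
        "single_domain_only": len(result.assignments) == 1,
        "multi_domain": len(result.assignments) >= 2,
        "tm_containing": ArchitectureTag.TM_CONTAINING in result.architecture_tags,
        "xray": chain.method is Method.XRAY,
        "em": chain.method is Method.EM,
    }


def summarize_outcomes(records: Iterable[tuple[PartitionResult, ChainRecord]],
                       ) -> CurationSummary:
    """Aggregate triage outcomes into per-category counts and percentages.

    The input order is irrelevant; identical collections give identical
    summaries.  Raises ValueError on empty input.
    """
    counts = {cat: 0 for cat in SUMMARY_CATEGORIES}
    total = 0
    for result, chain in records:
        total += 1
        for cat, flag in _category_flags(result, chain).items():
            if flag:
                counts[cat] += 1
    if total == 0:
        raise ValueError("summarize_outcomes needs at least one record")
    pct = {cat: percentage(c, total) for cat, c in counts.items()}
    return CurationSummary(total_chains=total, counts=counts, percentages=pct)
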