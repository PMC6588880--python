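"""Unit and property tests of the evidence-partition triage rules."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtriage import (AlignmentHit, ArchitectureTag, ChainRecord,
                      DomainAssignment, Method, Outcome, Reason,
                      ResidueInterval, ToolConfig, classify_architecture,
                      compute_coverage, decide_outcome, filter_hits,
                      partition_chain, resolve_overlaps, summarize_outcomes)
from tmtriage.config import DEFAULT_CONFIG
from tmtriage.partition import RejectReason, percentage


def hit(dom, start, end, score=50.0, cov=0.95, ref_len=None):
    iv = ResidueInterval(start, end)
    return AlignmentHit(dom, (iv,), ref_len or iv.length, cov, score)


# ---------------------------------------------------------------- filter

class TestFilterHits:
    def test_good_hit_kept(self, cfg):
        f = filter_hits([hit("d1", 1, 150, cov=0.95)], cfg)
        assert len(f.kept) == 1 and not f.rejected

    def test_short_hit_removed(self, cfg):
        f = filter_hits([hit("d1", 1, 15)], cfg)
        assert not f.kept
        assert f.rejected[0][1] is RejectReason.TOO_SHORT

    def test_fragment_coverage_removed_with_reason(self, cfg):
        f = filter_hits([hit("d1", 1, 60, cov=0.30)], cfg)
        assert not f.kept
        assert f.rejected[0][1] is RejectReason.FRAGMENT
        assert f.fragment_hits

    def test_very_low_coverage_dropped_outright(self, cfg):
        f = filter_hits([hit("d1", 1, 60, cov=0.1)], cfg)
        assert f.rejected[0][1] is RejectReason.LOW_COVERAGE
        assert not f.fragment_hits


# ---------------------------------------------------------------- overlaps

class TestResolveOverlaps:
    def test_disjoint_hits_both_accepted(self, cfg):
        asn, conflict = resolve_overlaps(
            [hit("a", 1, 100), hit("b", 120, 200)], cfg)
        assert len(asn) == 2 and not conflict

    def test_large_overlap_rejected_and_conflicting(self, cfg):
        # comparable scores, 41-residue overlap: boundaries are inconsistent
        asn, conflict = resolve_overlaps(
            [hit("A", 1, 120, score=100), hit("B", 80, 200, score=95)], cfg)
        assert [a.ref_domain_id for a in asn] == ["A"]
        assert conflict

    def test_weak_competitor_is_not_a_conflict(self, cfg):
        asn, conflict = resolve_overlaps(
            [hit("A", 1, 120, score=100), hit("B", 80, 200, score=20)], cfg)
        assert [a.ref_domain_id for a in asn] == ["A"]
        assert not conflict

    def test_small_overlap_trimmed(self, cfg):
        asn, conflict = resolve_overlaps(
            [hit("A", 1, 120, score=100), hit("B", 115, 230, score=95)], cfg)
        assert not conflict
        b = next(a for a in asn if a.ref_domain_id == "B")
        assert b.query_intervals == (ResidueInterval(121, 230),)
        assert b.trimmed_residues == 6

    def test_score_tie_broken_by_length_then_id(self, cfg):
        # same score and span: lexicographically smaller id wins the region
        asn, _ = resolve_overlaps(
            [hit("b", 1, 100, score=50), hit("a", 1, 100, score=50)], cfg)
        assert asn[0].ref_domain_id == "a"

    def test_zero_tolerance_gives_strict_disjointness(self):
        cfg0 = DEFAULT_CONFIG.replace(overlap_tol_residues=0,
                                      overlap_tol_frac=0.0)
        asn, _ = resolve_overlaps(
            [hit("A", 1, 120, score=100), hit("B", 115, 230, score=95)],
            cfg0)
        assert [a.ref_domain_id for a in asn] == ["A"]


# ---------------------------------------------------------------- coverage

class TestCoverage:
    def test_full_cover(self):
        chain = ChainRecord("c", 100)
        h = hit("a", 1, 100)
        frac, gaps = compute_coverage(
            [DomainAssignment("a", h.query_intervals, h)], chain)
        assert frac == 1.0 and gaps == ()

    def test_partial_cover_gap_reported(self):
        chain = ChainRecord("c", 150)
        h = hit("a", 1, 100)
        frac, gaps = compute_coverage(
            [DomainAssignment("a", h.query_intervals, h)], chain)
        assert frac == pytest.approx(100 / 150, abs=1e-9)
        assert gaps == (ResidueInterval(101, 150),)

    def test_masked_residues_excluded_from_denominator(self):
        chain = ChainRecord("c", 150, unknown_mask=frozenset(range(101, 151)))
        h = hit("a", 1, 100)
        frac, gaps = compute_coverage(
            [DomainAssignment("a", h.query_intervals, h)], chain)
        assert frac == 1.0 and gaps == ()

    def test_assignment_beyond_chain_is_an_error(self):
        chain = ChainRecord("c", 90)
        h = hit("a", 1, 100)
        with pytest.raises(ValueError):
            compute_coverage([DomainAssignment("a", h.query_intervals, h)],
                             chain)


# ---------------------------------------------------------------- outcome

class TestDecideOutcome:
    def _run(self, chain, hits, cfg=DEFAULT_CONFIG):
        return partition_chain(chain, hits, cfg)

    def test_full_cover_auto_accepted(self, cfg):
        res = self._run(ChainRecord("c", 100), [hit("a", 1, 100)])
        assert res.outcome is Outcome.AUTO_ACCEPTED and not res.reasons

    def test_large_gap_flags_novel_region(self, cfg):
        res = self._run(ChainRecord("c", 200), [hit("a", 1, 100)])
        assert res.outcome is Outcome.FLAGGED
        assert res.reasons == {Reason.NOVEL_REGION}

    def test_conflict_flags_inconsistent_boundaries(self, cfg):
        res = self._run(ChainRecord("c", 200),
                        [hit("A", 1, 120, score=100),
                         hit("B", 80, 200, score=95)])
        assert res.outcome is Outcome.FLAGGED
        assert Reason.INCONSISTENT_BOUNDARIES in res.reasons

    def test_synthetic_chain_is_unassignable_not_novel(self, cfg):
        res = self._run(ChainRecord("c", 120, synthetic_flag=True), [])
        assert res.reasons == {Reason.UNASSIGNABLE}

    def test_short_gaps_only_do_not_flag(self, cfg):
        # 20-residue tail gap: below gap_max and within min_cover_frac
        res = self._run(ChainRecord("c", 220), [hit("a", 1, 200)])
        assert res.outcome is Outcome.AUTO_ACCEPTED


# ---------------------------------------------------------------- tags

class TestArchitectureTags:
    def test_short_unassigned_chain_is_peptide(self, cfg):
        res = partition_chain(ChainRecord("c", 12), [])
        assert ArchitectureTag.PEPTIDE in res.architecture_tags

    def test_two_assignments_multi_domain(self, cfg):
        res = partition_chain(ChainRecord("c", 200),
                              [hit("a", 1, 100), hit("b", 101, 200)])
        assert ArchitectureTag.MULTI_DOMAIN in res.architecture_tags
        assert ArchitectureTag.SINGLE_DOMAIN not in res.architecture_tags

    def test_single_domain_with_tm_annotation(self, cfg):
        chain = ChainRecord("c", 100,
                            tm_annotations=(ResidueInterval(30, 52),))
        res = partition_chain(chain, [hit("a", 1, 100)])
        assert {ArchitectureTag.SINGLE_DOMAIN, ArchitectureTag.TM_CONTAINING} \
            <= res.architecture_tags

    def test_fragment_only_evidence_tagged(self, cfg):
        res = partition_chain(ChainRecord("c", 80),
                              [hit("a", 1, 60, cov=0.35)])
        assert ArchitectureTag.FRAGMENT in res.architecture_tags


# ---------------------------------------------------------------- summary

class TestSummary:
    def test_percentage_round_half_up(self):
        assert percentage(1, 200) == 1       # 0.5 rounds up
        assert percentage(119, 2298) == 5
        assert percentage(1335, 2298) == 58
        assert percentage(802, 2298) == 35   # 34.90 rounds to 35

    def test_degenerate_single_record(self):
        res = partition_chain(
            ChainRecord("c", 100, tm_annotations=(ResidueInterval(10, 30),),
                        method=Method.XRAY),
            [hit("a", 1, 100)])
        chain = ChainRecord("c", 100,
                            tm_annotations=(ResidueInterval(10, 30),),
                            method=Method.XRAY)
        s = summarize_outcomes([(res, chain)])
        assert s.percentages["tm_containing"] == 100
        assert s.percentages["xray"] == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_outcomes([])

    def test_permutation_invariance(self, rng):
        from tmtriage import make_outcome_records
        records = make_outcome_records(50, 10, 5, 8, 4, 6, 30, 15)
        s1 = summarize_outcomes(records)
        order = rng.permutation(len(records))
        s2 = summarize_outcomes([records[i] for i in order])
        assert s1 == s2


# ---------------------------------------------------------------- properties

@st.composite
def hit_lists(draw):
    n = draw(st.integers(1, 6))
    hits = []
    for i in range(n):
        start = draw(st.integers(1, 150))
        length = draw(st.integers(20, 120))
        score = draw(st.integers(1, 100))
        hits.append(hit(f"d{i}", start, min(start + length, 300),
                        score=float(score)))
    return hits


@settings(derandomize=True, max_examples=60)
@given(hit_lists())
def test_partition_is_deterministic_and_disjoint(hits):
    """Identical inputs give identical parses; accepted assignments are
    disjoint; every residue is assigned, gap or masked exactly once."""
    chain = ChainRecord("c", 300, unknown_mask=frozenset(range(290, 301)))
    r1 = partition_chain(chain, hits)
    r2 = partition_chain(chain, list(reversed(hits)))
    assert r1 == r2

    seen: set[int] = set()
    for a in r1.assignments:
        res = set()
        for iv in a.query_intervals:
            res |= set(iv.residues())
        assert not (res & seen)
        seen |= res
    gap_res = {i for g in r1.gaps for i in g.residues()}
    masked = set(chain.unknown_mask)
    assert not (seen & gap_res) and not (seen & masked) \
        and not (gap_res & masked)
    assert len(seen) + len(gap_res) + len(masked) == chain.length


@settings(derandomize=True, max_examples=60)
@given(hit_lists())
def test_dominated_hit_never_changes_the_parse(hits):
    """Adding a strictly dominated hit (lower score, sub-interval of an
    existing hit) leaves the accepted set unchanged."""
    chain = ChainRecord("c", 300)
    base = partition_chain(chain, hits)
    h0 = hits[0]
    dominated = AlignmentHit("zzz_dom", h0.query_intervals,
                             h0.ref_length, h0.ref_coverage,
                             h0.score * 0.5)
    withdom = partition_chain(chain, list(hits) + [dominated])
    assert [a.ref_domain_id for a in base.assignments] == \
        [a.ref_domain_id for a in withdom.assignments]
    assert [a.query_intervals for a in base.assignments] == \
        [a.query_intervals for a in withdom.assignments]
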