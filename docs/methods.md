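# Methods

This note documents the models and conventions behind tmtriage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the known limits of each method.

## 1. Partition triage

### Model

A chain is a 1-based closed residue range.  Evidence is a set of
alignment hits, each mapping a reference domain onto one or more query
intervals with a reference-coverage fraction and a score.  The pipeline
is four deterministic steps:

1. **Filtering.**  A hit is usable when it spans at least
   `min_domain_len` (20) query residues and covers at least
   `fragment_coverage` (0.5) of its reference domain.  Hits covering
   between `min_ref_coverage` (0.3) and 0.5 of the reference are kept
   aside as *fragment evidence*: they cannot place a domain, but a chain
   whose only evidence is fragments is itself tagged FRAGMENT.  Below
   0.3 a hit is treated as noise.
2. **Overlap resolution.**  Hits are taken greedily in the order
   (score desc, total length desc, reference id asc) — fully
   deterministic, no randomness anywhere in the module.  An incoming hit
   may overlap already-claimed residues by at most
   `overlap_tol_residues` (10) residues *and* `overlap_tol_frac` (0.25)
   of its own length; the overlap is trimmed from the incoming hit, so
   accepted assignments are strictly disjoint.  Alignments fray at their
   edges; bounded trimming absorbs that without letting a hit be eaten.
3. **Coverage.**  covered_frac = assigned residues / (chain length −
   masked residues).  Masked (unknown/unresolved) residues are excluded
   from both numerator and denominator and from gaps; a fully masked
   chain counts as fully covered.  Gaps are maximal unassigned, unmasked
   runs.
4. **Outcome.**  AUTO_ACCEPTED iff covered_frac ≥ `min_cover_frac`
   (0.90), every gap is shorter than `gap_max` (30), and no conflict was
   seen.  Otherwise FLAGGED with reasons:
   * INCONSISTENT_BOUNDARIES — some rejected hit overlapped an accepted
     one beyond tolerance while scoring ≥ `conflict_score_ratio` (0.8)
     of its score: two comparable, incompatible parses exist.
   * NOVEL_REGION — a gap of ≥ `gap_max` residues on a natural chain:
     a region without detectable similarity to the reference set.
   * UNASSIGNABLE — the failure is explained by non-domain content:
     the chain is a synthetic construct, or the shortfall consists only
     of masked residues and sub-threshold gaps.  Synthetic chains take
     this reason instead of NOVEL_REGION because their uncovered
     content has no evolutionary history to discover.

`min_cover_frac = 0.90` and `gap_max = 30` quantify "complete or nearly
so": short linkers and frayed termini should not flag a chain, while
anything long enough to be a small domain (≈30+ residues) should.
`peptide_max_len = 20` bounds the PEPTIDE tag.

### Summary statistics

`summarize_outcomes` counts nine per-chain predicates (unclassifiable
content, entirely/partly special architecture, any/single/multi domain
assignment, TM-containing, X-ray, EM) and reports round-half-up integer
percentages, computed exactly in integer arithmetic.  "Unclassifiable
content" means special-architecture tags (peptide/fragment/synthetic) or
masked residues; it is the union of the entirely- and partly-special
categories.  Published curation tables often mix truncation and rounding
in their printed percentages, so a single convention cannot reproduce
every printed figure; round-half-up is used throughout.

## 2. TM geometry

### Membrane frame

A unit normal pointing toward the designated outside plus a point on the
mid-plane.  Default: +z with origin at the coordinate origin, the
convention of membrane-oriented structure databases where figures place
the membrane horizontally.  All descriptors transform correctly under
rigid motion applied jointly to coordinates and frame, and flipping the
normal flips every chirality label — view-side dependence is explicit,
not hidden.

### Axis fitting

The centroid is the mean Cα position.  For a regular helix the second
differences of consecutive Cα positions are exactly perpendicular to the
helix axis, so the axis is estimated as the null direction (smallest
right singular vector) of the second-difference matrix.  This is exact
for ideal helices of any partial turn — the dominant principal direction
of the positions is not, because the unclosed turn couples radial and
axial covariances by a few milliradians — and behaves as a least-squares
estimate under coordinate noise (≈1–2° error at σ = 0.3 Å over 20
residues).  Nearly collinear inputs (no curvature signal) fall back to
the principal direction.  The sign follows the chain: axis · (last −
first) > 0.  At least 5 Cα are required, and a range must have
coordinates for ≥ 80% of its residues.  Kinked helices are not split; a
broken TM helix should be supplied as two ranges.

### Orientation

UP if axis·normal > `orientation_min_cos` (0.5, i.e. within 60° of the
normal), DOWN if < −0.5, else UNDEFINED.  UNDEFINED marks near-in-plane
helices such as amphipathic coupling helices, which do not cross the
membrane and carry no crossing direction.

### Triplet handedness

Project the three consecutive centroids onto the membrane plane; with
d1, d2 the two step vectors, s = n·(d1×d2)/(|d1||d2|) is the normalised
turn sense (the sine of the turn angle).  |s| ≤ `degeneracy_tol` (0.05,
≈3° of turn) is labelled X; collinear centroids are degenerate rather
than chiral.  Convention C1 calls a clockwise progression viewed from
the +normal side right-handed; `handedness_convention: C2` flips every
label globally, because which side a curator "views from" is itself a
convention that may need calibrating against a known example.  Whether a
published handedness was judged from centroids, axis tilts or visual
inspection is generally unknowable; centroid turn sense is this
package's operationalisation.

## 3. Topology alignment

Segments are compared as ordered sequences; geometry enters only through
orientation and length, because the arguments this supports are made at
segment granularity.  Pair score: `w_or`·(+1 same crossing direction,
−1 opposite, 0 if either UNDEFINED) + `w_len`·(1 − |ℓA−ℓB|/max(ℓA,ℓB)).
The alignment is semi-global (free end gaps) with affine internal gaps:
a run of k skipped segments costs `g_open` + (k−1)·`g_ext`.

Defaults: `w_or` = 2.0, `w_len` = 2.0, `g_open` = 0.75, `g_ext` = 0.25.
The ratio matters more than the scale.  Inserting an even number of TM
segments preserves the up/down parity of everything downstream, so an
out-of-register ("slid") alignment keeps the full orientation reward and
loses only length similarity — at most `w_len` per pair.  For an
internal insertion ever to be gapped rather than mis-paired, the
two-segment gap cost `g_open + g_ext` must sit below `w_len`; the
defaults (1.0 < 2.0) make the gap optimal whenever the inserted segments
are shorter than about half of the core segment they would displace.
Ties are broken toward fewest internal gap runs, then by a fixed
deterministic traceback preference, so outputs are bit-for-bit
reproducible.

### Circular permutation

`detect_circular_permutation` aligns A against every cyclic rotation of
B's segment order (rotation reorders the sequence; each segment keeps
its own chain ordinal) and keeps the best rotation only if it beats the
unrotated score by more than `cp_margin` (0.5); otherwise offset 0 is
reported.  A genuine permutation of an n-segment bundle typically gains
a full pair weight (≈4) over the best unrotated alignment, far above the
margin.

**Identifiability limit.**  A bundle whose orientation pattern is
rotationally symmetric and whose lengths nearly repeat (e.g. U,D,U,D
with lengths 35,40,35,39) is almost invariant under the rotation; the
true offset then improves the score by less than the margin and the
detector deliberately reports 0.  At segment granularity such a
permutation is genuinely near-unobservable; full-coordinate
superposition, which this package does not attempt, would be needed.

### Handedness identity

Over the matched segments of each profile, in alignment order, triplet
labels are computed per profile and compared position-wise; X positions
are excluded from the denominator.  Requires ≥ 3 matched pairs and at
least one non-degenerate position.

## 4. Synthetic generators

`make_helix_bundle` builds ideal Cα helices (1.5 Å rise, 100° twist,
2.3 Å radius) with vertical axes at prescribed in-plane positions, plus
optional in-plane helices for coupling-helix geometry, Gaussian
coordinate noise, and analytic truth: orientations from the pattern and
handedness from the 2-D signed-area rule applied to the prescribed
centroid positions — an independent closed form, not a call into the
geometry module.  `make_partition_scenario` emits hits at true domain
boundaries ± jitter plus seeded decoys and fragment hits, with truth
computed on the noiseless configuration, so at zero noise pipeline
output must equal truth exactly (the closed-loop property the tests
enforce).  All randomness flows through the spec seed; identical specs
give byte-identical outputs.

What the generators do **not** emulate: real helices kink, tilt and
bend; membrane normals are estimated, not exact; real alignment evidence
has correlated errors, paralog confusion and score distributions far
messier than fixed decoy scores.  Passing the closed-loop tests shows
the descriptors and decision rules are implemented exactly as specified,
not that the thresholds are optimal on real curation data.

## 5. Problem sizes and numerical choices

The shipped analyses are desk-scale by design: 2298 synthetic outcome
records for the summary statistics, 100 random profiles × all offsets
(~700 alignments) for circular-permutation recovery, 1000 random
triplets for the chirality oracle, 25 scenarios for boundary recovery;
everything completes in seconds.  Degenerate inputs are errors, not
silent defaults: < 5 Cα per range, coincident points, coincident
projected centroids, fewer than 3 core segments for a handedness string,
empty record lists.  Percentages use exact integer round-half-up;
chirality comparisons near zero turn sense are cushioned by
`degeneracy_tol`; DP tie-breaks are fixed and documented above.

## 6. Out of scope

TM segment prediction, membrane placement optimisation, β-barrels,
residue-level structure alignment and superposition scores, homology
verdicts, and classification-hierarchy maintenance.  The toolkit
produces the descriptors on which such judgements rest.
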