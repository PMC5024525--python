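# Methods

This note documents the models and procedures implemented in censatkit, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not emulate.

## Tandem-repeat detection

The detector follows the classic two-phase design for satellite finding:
cheap period seeding followed by alignment verification.

**Seeding.** Exact 5-mer matches vote for candidate periods: for every 5-mer
occurrence, the distances to its next two occurrences (3–750 bp) are
recorded at the left position. Votes at one distance are grouped into runs
(split when consecutive votes are more than max(period, 24) bp apart); a run
becomes a candidate when it spans ≥ 1.6 periods and carries at least
max(5, period/4) votes. Voting on the next *two* occurrences guards against
5-mers duplicated inside one monomer, which would otherwise siphon votes
away from the fundamental period.

**Verification.** Each candidate region (padded by one to two periods) is
aligned against tandem repetitions of a consensus by wraparound dynamic
programming: columns index consensus positions modulo the period, the
starting phase is free, and the alignment is locally trimmed at both ends
(Smith–Waterman-style zero floor). Integer weights — match +1, mismatch −1,
indel −2 — make traceback comparisons exact. The within-row wraparound gap
moves are computed with a prefix-max scan over a doubled column array, so
each row costs O(period) vector work. The consensus is seeded by majority
vote over in-phase rows starting at the first seed vote, then refined (up to
twice) from the alignment columns; deletion-majority columns are dropped and
the final consensus is stored as its lexicographically smallest rotation,
purely for determinism (the wraparound score is rotation-invariant).

**Filters.** An array is reported when score ≥ 200, copy number
(aligned span / period) ≥ 2, period ≤ 750 bp, percent matches ≥ 80 and
percent indels ≤ 5, with the percentages taken over all alignment columns.
Because a pure array also verifies at integer multiples of its period, calls
whose period is ≈ k× (k ≥ 2, within 3 %) that of an overlapping
shorter-period call are discarded as multimer harmonics, and remaining calls
(near-)wholly contained in a higher-scoring call are dropped. Without this,
one locus would be counted at 109 bp and again at 218 bp.

The local trimming means an array boundary can extend a few bases into
flanking sequence when those bases happen to match the cyclic consensus
continuation; coordinates are therefore exact only up to such chance
matches.

## Monomer clustering

One representative monomer — the array consensus, weighted by the array's
copy number — is kept per array; monomers of 50 bp or less are discarded.
Similarity uses the best local alignment of each monomer against the
*doubled* sequence of the other (both orientations), which absorbs any
rotation of the repeat phase. Scoring is +1/−2 with affine gaps (−4 open,
−2 extend); significance uses the Karlin–Altschul form
E = m·n·2^(−(λS − ln K)/ln 2) with λ = 1.28, K = 0.46 (the ungapped
constants for +1/−2 nucleotide scoring — configuration, recorded in the run
provenance) and effective search space = query length × total dimer database
length. An edge requires identity ≥ 75 % over the aligned span *and*
E ≤ 1e−5; clusters are connected components (single linkage). Cluster
"counts" sum member copy weights rather than counting arrays, which is what
makes the totals comparable to monomer-copy abundances; modal length is the
count-weighted mode. Ties (equal totals, equal modal frequency) break toward
the lexicographically smallest representative monomer.

## Characterization

* **Star MSA** against the modal-length monomer with affine-gap global
  alignments (+2/−1, −4 open, −1 extend); pairwise insertions are merged
  into shared gap columns. Monomers deviating more than 50 % from the modal
  length are rejected. This is adequate for satellite monomers, whose length
  variation is small; it is not a general MSA.
* **Consensus**: per-column majority, ties broken in the fixed order
  A < C < G < T; gap-majority columns are dropped.
* **Logos**: column information = 2 − H bits with H the log2 Shannon entropy
  of the column's base frequencies; letter heights are frequency × info.
  A small-sample correction (3 / (2 ln2 n)) exists behind a flag but
  defaults off so column values stay analytically checkable.
* **Genome scan**: seed 11-mer matches against the doubled consensus (both
  strands) are merged into regions, each region is wraparound-aligned, and
  every pass of the alignment through the consensus yields one monomer hit.
  Hits are kept at E ≤ 1e−5 (scored per hit against the consensus) and
  resolved greedily by descending score, then leftmost, so retained hits
  never overlap. Minus-strand hits are reported in consensus orientation.
* **Digestion**: IUPAC patterns are expanded to regexes, every (possibly
  overlapping) site is cut at its fixed offset, and fragments always
  partition the input. Sequences are treated as linear. Ladder analysis
  estimates the main interval as the modal nearest-neighbor rung spacing
  (anchored at zero, weighted by rung multiplicity), ignoring spacings
  below 80 % of the most abundant rung — on a tandem-array digest the
  dominant low rung is the monomer itself, and the guard keeps arbitrary
  terminal fragments from fabricating a spurious short interval. Rungs
  within 2 % (or 2 bp) of an integer multiple of the interval are "main",
  everything else "off-ladder".

## Karyotype metrics

Profiles are ordered intensity samples; intensity integration is plain
summation (no interpolation) because profiles are the package's atomic
input. Constriction DNA in Mb apportions a fixed haploid genome size
(default 484 Mb) by stain-intensity fractions, so summed per-chromosome Mb
exactly equals genome size × global constriction intensity fraction. These
are model-based estimates: chromosome condensation varies with preparation,
so absolute Mb values inherit that uncertainty. Arm ratios are measured from
each terminus to the *nearer* edge of the centromeric interval (configurable
to the midpoint); class boundaries default to the Levan-convention values
1.7 / 3.0 / 7.0, and the terminal class merges telocentric with acrocentric.
A zero-length short arm maps to the terminal class; an interval covering the
whole chromosome leaves the class undefined.

## Slot-blot quantification

Each species' signals are divided by its loading-control intensity, taken
only at the highest load where total-DNA staining is reliable. Walking from
the highest load down, a load is saturated when its signal ratio to the next
dilution is below dilution-factor × (1 − 0.3); the 0.3 tolerance is a
configuration default (recorded per run) since real blots show which rows
were used but not the criterion. The lowest load is unsaturated by
convention when above the detection floor (2 × a background estimate,
default 0). Folds are per-dilution ratios to the intermediate reference —
restricted to dilutions where the reference itself is unsaturated —
averaged arithmetically over the top two unsaturated loads (a geometric-mean
option exists), then divided by the final reference's value so the final
reference is exactly 1. Species below the detection floor at all loads are
reported as not detected (fold 0 with a flag) rather than given a numeric
estimate. The pairwise fold-range helper brackets a fold by matching each
unsaturated signal of the weaker species to the log-log-interpolated load of
the stronger species giving equal signal, refusing to extrapolate outside
the observed linear range.

## Ancestral reconstruction

Linear-change parsimony ignores branch lengths and requires a binary rooted
tree; polytomies are resolved left-comb with zero-length branches
(`resolve_polytomies`), which preserves the minimum cost because the
inserted node can absorb any split of the change. The post-order pass
propagates Farris intervals — intersection at zero added cost, or the gap
between disjoint child intervals at a cost equal to the gap — and yields the
exact minimum of Σ|Δ| (verified against exhaustive enumeration over
tip-value states, which is sufficient because an optimal labeling exists
with all states drawn from the tip values). The pre-order pass reports the
interval per node plus a point assignment: the root takes its interval
midpoint, every other node the interval point nearest its parent. The
interval is the honest answer; the point is a convenience.

Squared-change parsimony minimizes Σ(Δ)² (each term divided by branch length
in weighted mode) via Gauss–Seidel sweeps of the mean-of-neighbors
stationarity condition, iterated to a maximum update below 1e−10. Unweighted
is the default; weighted mode requires strictly positive branch lengths and
its root estimate is the GLS phylogenetic mean, unbiased under Brownian
motion (checked over 1,000 simulated replicates).

Binning uses three edges (default 0.5 / 2.0 / 8.0, chosen so the seven
fire-ant species fall into the four observed level groups ≈0 | 1 | 3.2–4.2 |
10.9–13.1; the exact published edges are unstated) with values exactly on an
edge assigned to the lower bin. The shipped fire-ant tree fixture encodes
the accepted topology — *S. indagatrix* outgroup; (*geminata*, *aurea*)
sister to (*daguerrei*, (*invicta*, *macdonaghi*, *richteri*)) — with the
terminal trio resolved arbitrarily through a zero-length branch and tip
folds (12, 12, 12, 4.2, 3.2, 1, 0.001) relative to *S. geminata*; branch
lengths are nominal, as linear parsimony ignores them.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* of the study's inputs: tandem
arrays of a shared monomer at species-specific copy numbers with per-copy
substitutions and single-base indels (matching the observed ±1–13 bp
monomer length variation; multi-base indels are out of scope), polymorphic
restriction-site loss for off-ladder fragments, intensity profiles with a
dimmer constriction whose totals follow per-chromosome DNA shares,
saturating dilution series with multiplicative log-normal noise, and
Brownian/jump characters on trees. They do **not** emulate read-level
sequencing artifacts or assembly collapse of repeats (real assemblies
under-represent satellites), 2-D blot or microscope images, probe-affinity
differences from sequence divergence, or chromatin-level features. Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated generative model, not robustness to assembly collapse or imaging
artifacts.

Every generator draws all randomness from a single integer-seeded
`numpy.random.Generator`, so fixed seeds give byte-identical outputs.
Coordinates are 0-based half-open throughout.

## Problem sizes and defaults

The benchmark (`scripts/acceptance.py`, also exercised in the test suite)
uses a 200-kb single-scaffold genome carrying ~300 copies of a random
109 bp monomer at 5 % per-copy substitution divergence split over four
arrays, plus a 139 bp satellite at 30 copies — enough copies for the
abundance ranking to be unambiguous while keeping a full run around ten
seconds. The 5 % divergence default is a free parameter of the generator,
not an estimate of real within-family divergence (real monomer identities
span roughly 70–99 %); it sits well inside the detector's ≥ 80 % match
filter so that recovery failures indicate bugs, not borderline parameter
choices. Unit tests use smaller genomes (15–40 kb) for speed.

## Known limitations

* The detector seeds periods from exact 5-mer spacings; extremely diverged
  arrays (adjacent-copy identity well below ~80 %) or monomers whose
  internal structure starves the fundamental period of votes can be missed —
  such arrays would also fail the percent-match filter by design.
* E-values use fixed ungapped Karlin–Altschul constants for the configured
  scoring; they are a consistent significance scale, not calibrated
  gapped-alignment statistics.
* Array boundaries are exact only up to chance matches in the flanks (see
  above), so copy numbers carry a sub-copy uncertainty.
* The star MSA assumes near-equal-length inputs and will not produce good
  alignments for structurally heterogeneous repeat families.
* Squared-change solutions are iterative; on pathological trees (very deep
  chains) the 1e−10 update threshold may be reached before full
  convergence in the last digits.
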