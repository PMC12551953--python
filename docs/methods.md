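# Methods

## The model

`indelfold` quantifies how an insertion/deletion variant located *outside*
an RNA-binding-protein (RBP) binding site changes binding affinity through
RNA secondary structure. Protein binding is modelled as a base-pairing
constraint: the bound site must be single-stranded. For a sequence with
ensemble (partition-function) free energy `G_none` and constrained free
energy `G_constraint` (site forced unpaired), the energetic cost of exposing
the site is

    dG = G_constraint − G_none  ≥ 0.

For two alleles differing by one indel — the longer l-allele and the shorter
s-allele — the binding preference at a site present on both alleles is

    ddG = dG_l − dG_s.

Positive ddG means the protein prefers the s-allele. Direct protein–RNA
contact energies cancel in ddG because the site sequence is identical on
both alleles; what remains is purely the structural (accessibility) effect
of the indel. Physiological relevance is judged against thermal energy
k_BT ≈ 0.616 kcal/mol at 37 °C (`indelfold.constants.KT_KCAL_MOL`, computed
from the gas constant).

Because an indel is a priori equally likely to stabilise either allele, the
mean ddG over many loci is ~0 and the interesting quantity is the
*standard deviation* of ddG, aggregated by indel–site distance or indel
size. Purifying selection shows up as one cohort's SD curve lying below
another's with separated bootstrap confidence intervals.

## Folding engines

Two engines implement one contract (sequence, optional single-stranded
interval → ensemble free energy in kcal/mol at 310.15 K):

* `nearest_neighbor` — ViennaRNA (`RNA.fold_compound(...).pf()`) with the
  default Turner 2004 parameter set at 37 °C; constrained positions are
  forced unpaired with `hc_add_up` hard constraints. Engine model options
  (dangling ends etc.) are left at ViennaRNA defaults and recorded in run
  metadata via the engine name and version.
* `toy` — a built-in simplified model: every canonical pair (AU, UA, GC,
  CG, GU, UG) contributes a fixed energy ε = −1.0 kcal/mol, hairpin loops
  enclose at least 3 unpaired nucleotides, pseudoknots are excluded, and

      Z(i,j) = Z(i+1,j) + Σ_k e^(−ε/kT) · Z(i+1,k−1) · Z(k+1,j)

  is computed exactly in O(n³) (numba-compiled; ~1.5 ms at n = 150).

The toy model exists so that every energy the test suite relies on can be
validated against an independent brute-force enumeration of all
pseudoknot-free structures (`enumerate_structures`, guarded to ≤ 20 nt).
The two agree to < 1e-9 kcal/mol on hundreds of random constrained
sequences. The toy engine's ddG values are smaller in magnitude than
nearest-neighbor values (a single pair energy replaces the full loop-based
model), so toy-engine SD curves sit below k_BT; all qualitative behaviour
(dG ≥ 0, symmetry of ddG, decay with distance, growth with indel size)
matches, which is what the tests assert. Swapping engines changes ddG
values but never the geometry of a sweep (site count, distances,
identities).

ΔG non-negativity is asserted at a tolerance of 1e-6 kcal/mol to absorb
external-engine floating point; the toy engine is exact to ~1e-12.

## Coordinates, geometry, conventions

* All internal coordinates are 0-based, half-open; 1-based closed
  coordinates appear only in file IO and reports.
* An indel is always a deletion relative to the l-allele; an insertion
  polymorphism is handled by splicing the inserted bases into the transcript
  so the insertion-carrying sequence becomes the l-allele.
* VCF anchor bases (shared leading base of REF/ALT) are stripped: the indel
  size is |len(REF) − len(ALT)| and the anchor is not part of the deleted
  interval.
* Distance between indel and site counts the nucleotides strictly between
  the deletion junction and the site, so an adjacent site is at distance 0.
  The convention is symmetric for sites 5' of the indel (counted from the
  deletion start). Sites that overlap the deleted interval have no s-allele
  counterpart and are excluded.
* Synthetic-indel construction on a 150-nt fragment: deletions of size 1–5
  remove the 3' end of the central window (1-based 51–100), so all sizes
  share the junction at position 100; 7-nt sites sweep the adjacent
  downstream window (101–150), giving 44 sites at distances 0–43 that are
  aligned across indel sizes. For longer fragments the junction stays at
  min(100, L−50), which preserves this layout at L = 150 and leaves a
  larger 3' flank at L = 250 for the end-effect robustness check.
* Natural-indel runs center the deletion junction at floor(length/2) of the
  extracted fragment and sweep a 50-nt window starting at the junction,
  clipped to end 20 nt before the fragment end.
* The synthetic-near-natural construction places the synthetic junction
  20 nt 5' of the documented indel position (25 is available as
  configuration; reported offsets differ between 20 and 25 in the source
  data descriptions and we default to 20).
* Within a sweep the unconstrained free energy of each allele is folded
  once and shared across all constrained folds (2 + 2·44 engine calls per
  pair instead of 4·44); this is enforced by a call-counting test.

## Site identification within binding regions

CLIP-style experiments resolve binding to ~25-nt regions containing a 7-nt
element. The element is located by affinity-weighted, structure-corrected
occupancy:

    a_i = e^(−dG_i / kT)      accessibility of the 7-mer at start i
    K_i = s(m_i) · a_i        association strength; s from a 7-mer table
    p_i = c·K_i / (1 + c·K_i) single-site binding isotherm

with the concentration c set per allele to the sequence's effective
dissociation constant, defined as 1 / Σ_i K_i. Occupancies of the two
alleles are summed over shared 7-mers (indel-destroyed 7-mers excluded) and
the maximum wins, 5'-most on ties. **This occupancy model is this package's
concrete design choice**: the published analyses that motivated it delegate
to external binding software whose internals are not restated anywhere we
could verify against, so no numeric agreement with that software is claimed.
The model is, however, exactly rescaling-invariant (multiplying the affinity
table by a constant leaves every p_i unchanged), monotone in concentration
and affinity, and recovers planted ground-truth sites (below).

Control regions are produced by shifting real regions 300 nt toward the 5'
end; regions closer than 300 nt to the transcript start are skipped with a
logged reason.

## Synthetic data: what it emulates and what it does not

The generators stand in for the real inputs (dbSNP indels, Ensembl
transcripts, CLIP binding regions, an RNAcompete affinity table):

* **Fragments** — i.i.d. uniform ACGU, 150 nt, 4000 per cohort by default
  (the headline study conditions). "Human-like" fragments default to the
  same uniform composition, with `base_probs` exposed, because arbitrary
  human transcript regions were found to behave like uniform-random
  sequence in this statistic.
* **Affinity table** — s(m) = exp(β·countU(m) + ε_m), ε_m ~ N(0, σ²), over
  all 16 384 7-mers; β = 1 by default. This captures the one property that
  matters for a U-rich single-stranded binder (monotone U preference), not
  the fine structure of a measured RNAcompete table.
* **Binding-region fixtures** — a 25-nt region whose flanks are C, carrying
  a planted U7 element at a random offset, embedded in a U/C-rich,
  purine-poor background (A/C/G/U = 0.05/0.55/0.05/0.35). The composition
  emulates the weakly structured, pyrimidine-rich context of U-rich
  3'UTR elements. Low purine content is essential to the fixture's purpose
  of providing a *recoverable* ground truth: every A/G in the fragment is a
  pairing partner for the planted U run, and a strongly structured context
  would systematically bury the full U7 window (constraining all seven
  hotspot positions costs more than constraining a partially overlapping
  window), making "the planted site" ill-defined as a ground truth.
* **Variant files** — dbSNP-style VCF with anchor-base REF/ALT deletions of
  sizes 1–5, in transcript coordinates.
* **Purifying selection** — a hard-threshold filter: a variant whose |ddG|
  at the reference site exceeds τ survives with probability r (defaults
  τ = k_BT, r = 0). This operationalises "deleterious variants are purged"
  just strongly enough for recovery tests; real selection is neither hard
  nor single-site.

Consequently, passing tests demonstrate internal correctness and
recoverability of the selection/identification logic under controlled
conditions; they do not demonstrate anything about mutation-process biases,
real 3'UTR composition, isoform structure, or the actual strength of
selection in human populations.

## Statistics

* Dispersion is the sample SD (n−1); the normalization is a package choice.
* Confidence intervals are percentile bootstrap (2.5/97.5 for level 0.95)
  over 5000 resamples by default; percentile (rather than BCa) is the
  simplest method consistent with "bootstrap CI". Groups larger than
  20 000 observations are subsampled without replacement to 20 000 before
  bootstrapping.
* Curve cells with n < 2 are dropped with a log entry.
* Category comparisons are CI-separation verdicts (`a_lower` /
  `b_lower` / `overlap`), not hypothesis tests.
* All randomness flows from one seed through `numpy.random.SeedSequence`
  spawn keys, one substream per stage and group, so results are
  bit-reproducible and adding a stage never perturbs another stage's draws.
  Group values are sorted before resampling so statistics are invariant to
  observation order.

## Problem sizes and scenario emulations

Pipeline scenario defaults use 200 fragments, 1000 bootstrap resamples and
indel sizes {1, 3, 5}; the package-level acceptance checks use 500-fragment
cohorts. These sizes give CI-separable signals for every effect the package
asserts while keeping a full run in minutes on one CPU; the generator
defaults (4000 fragments, 5000 resamples) remain the study conditions for
real use.

Two scenario-level emulations deserve flagging. The `fig6`-style contrast
(fragments near functional binding sites) is emulated by halving the
selection threshold, encoding the expectation that selection is strongest
where disruption is most costly. The natural-vs-shifted-control scenario
applies selection only at identified natural sites. Both are design choices
of the synthetic world, documented here, not measurements.

## Degenerate inputs and numerical edges

* Empty sequences, out-of-bounds constraints/sites/indels, and non-ACGU
  characters raise typed errors (`errors` module).
* Sequences with no positive-affinity accessible 7-mer raise
  `DegenerateAffinityError` from `effective_kd`; regions whose shared
  7-mers are all destroyed by the indel raise `NoSharedSiteError`.
* Binding regions are clipped to the fragment; remnants shorter than 7 nt
  are skipped (`SkipRegion`), as are variants without flank for a centered
  fragment and regions too close to the 5' end for a shifted control.
* Site-identification ties break to the 5'-most start (strict `>` during
  the scan), making results deterministic and order-independent.

## Known limitations

* The toy engine's absolute energies are not comparable to thermodynamic
  values; only orderings and signs are.
* Multi-allelic variants and complex (non-left-anchored) indels are
  rejected rather than normalised.
* Genomic→transcript projection, genome-build conversion and live database
  retrieval are out of scope; variants must arrive in transcript space.
* Joint occupancy of overlapping sites, protein concentration dependence
  beyond the single-site isotherm, and cooperative binding are not
  modelled.
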