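# Methods

## Scope and data model

The pipeline estimates the deleterious mutation load of breed populations
from mitochondrial protein-coding sequence. Its unit of data is a
`CodonAlignment`: equal-length, frame-aligned coding sequences (the 13
vertebrate mito protein-coding genes concatenated in canonical H-strand
order: ND1, ND2, COX1, COX2, ATP8, ATP6, COX3, ND3, ND4L, ND4, ND5, ND6,
CYTB) with one breed label per sample. Bovine mitochondrial CDS are
length-conserved, so no alignment is performed: per-gene length equality is
enforced at concatenation and a violation is an error directing the user to
an external aligner. Terminal stop codons are trimmed — complete stops
(TAA/TAG/AGA/AGG under the mito code) as a whole codon, incomplete stops
(length ≡ 1 or 2 mod 3 at the 3′ end, completed by polyadenylation in situ)
by truncation to frame. Gene-name synonyms (COI/COX1, ATPase 6/ATP6, cytb,
NADH dehydrogenase subunit n, …) are resolved through a fixed table;
unmatched names fail loudly rather than fuzzy-matching, because a silent
misassignment would corrupt the concatenation.

## PBL distances

Pairwise nonsynonymous (dN) and synonymous (dS) distances use the
Pamilo–Bianchi–Li degeneracy-class framework with per-class Kimura
2-parameter correction. Conventions that the published method leaves open
are fixed as follows:

- **Degeneracy classes.** A codon position is 4-fold when all three
  single-base alternatives are sense and synonymous, 0-fold when none is,
  2-fold otherwise; changes creating a stop codon count as nonsynonymous.
  Under the vertebrate mito code the 60 sense codons partition their 180
  positions into 116 / 32 / 32 (0- / 2- / 4-fold).
- **Mixed-degeneracy sites.** Each position's class is taken from each
  sequence's own codon and the two classifications averaged: a site 2-fold
  in one sequence and 4-fold in the other contributes 0.5 to L2 and 0.5 to
  L4, and an observed difference splits its tally likewise. L values are
  therefore half-integral in general.
- **Routing at 2-fold sites.** The tally at a 2-fold site is routed by the
  synonymy of the single-base change (synonymous → S2, nonsynonymous → V2),
  so the rare synonymous transversion is counted as synonymous (the
  Li-1993-style refinement). At 0- and 4-fold sites S/V is the plain
  transition/transversion split. Under the mito code no position is
  synonymous *only* via transversion (checked by enumeration), so this
  choice matters only in multi-hit codon contexts.
- **Multi-hit codons.** Differences are compared site-by-site with no
  pathway enumeration (unlike Nei–Gojobori); this is the degeneracy
  framework's native convention. Small deviations from other software on
  rare multi-hit codons are expected and accepted.
- **Exclusions.** Codons containing gaps/ambiguity or that are stops in
  either sequence are excluded pairwise.
- **Saturation.** Outside the K2P log domain the affected distance is
  flagged invalid, not raised: population averaging excludes and counts
  invalid pairs (intraspecific mito data essentially never saturate; a
  whole-breed failure would be disproportionate). Note the K2P transition
  component A can be legitimately (slightly) negative when transversions
  dominate; it is not clamped.

The implementation precomputes per-genetic-code lookup tables over ordered
codon pairs, so a pairwise comparison is a vectorised table sum; the test
suite checks it against an independent brute-force per-site oracle to
1e-12 on a thousand random pairs. Distances are pure elementary-function
arithmetic with a fixed summation order and reproduce across platforms to
1e-12.

## Load summary per breed

πN and πS are unweighted means of valid pairwise dN and dS over all
n(n−1)/2 within-breed pairs (identical copies count as distinct
individuals, as in standard diversity estimators — duplicating every
sequence rescales π by 2(n−1)/(2n−1), it is not invariant). ωP = πN/πS.
The interspecies ωS is computed once from the pooled
ingroup-vs-outgroup comparison (means of pairwise dN and dS over all
ingroup × outgroup pairs, then the ratio) and shared by all breeds,
matching a single cow-vs-bison species contrast; a per-breed variant is
available behind a flag. δ = (ωP − ωS)/ωP is ≤ 1 by construction; negative
values (ωP < ωS) are reported with a flag, not clamped — they are a
diagnostic, not an error.

**Inclusion filters.** A breed enters the analysis with more than four
samples (n ≥ 5) and at least one synonymous and one nonsynonymous
segregating change, classified by the same PBL routing. Excluded breeds
are reported with the failed criterion.

**Bootstrap.** Uncertainty comes from resampling codon columns (the
estimator's natural unit, preserving within-codon dependence) with
replacement, 100 replicates by default. The same resampled column set is
applied to the breed alignment and to the pooled outgroup comparison, so
replicate ωP and ωS covary and the δ replicates absorb their common
sampling noise. Replicates with no synonymous signal (πS = 0, dS = 0) or
no nonsynonymous signal (ωP = 0, which leaves δ undefined) are dropped and
counted; more than 50% degenerate replicates is an error. SEs are sample
standard deviations across surviving replicates.

## Breed age

Age is the within-breed coalescence distance divided by the mitochondrial
rate μ = 2.043 × 10⁻⁸ substitutions/site/year (configurable; interpreted
per site per year, the only reading consistent with Kyr-scale breed ages).
The coalescence distance is estimated from the K2P nucleotide distance
matrix over all aligned sites (pairwise deletion of ambiguous sites) by one
of two estimators, recorded in every output row:

- `upgma_root` (default): root height of the average-linkage (UPGMA) tree —
  the natural choice for an ultrametric intraspecific genealogy;
- `half_mean_pairwise`: half the mean off-diagonal distance.

Both reduce to d/2 for two sequences. This is a deliberate, documented
stand-in for Bayesian coalescent inference of the root time: the
downstream use is only distance/rate → years, which the distance estimator
preserves, and the method tag prevents silent conflation with model-based
ages. UPGMA merge order is deterministic given the input row order. No
MCMC, no calibration uncertainty intervals.

## Age–load association

The headline statistic is Pearson's r between breed age and δ on
log10–log10 axes, with the two-sided p from t = r√((n−2)/(1−r²)) on n−2
degrees of freedom; Spearman's rank correlation (average ranks for ties,
same t approximation) and the untransformed-scale results are always
co-reported, since published practice plots log–log without stating the
correlation scale. Breeds with δ ≤ 0 cannot be log-transformed and are
dropped from the log-scale correlation with an explicit count. Breeds are
not phylogenetically independent samples; this caveat is stated, not
modelled.

## Synthetic cohorts

The simulator exists so every estimator can be checked against known truth.

- **Genealogies.** Per breed, a Kingman-coalescent topology whose node
  heights are rescaled so the root-to-tip height equals the requested
  value exactly (ultrametric, branch lengths in subs/site). Exact
  rescaling is what makes "breed age" a controlled input.
- **Substitution process.** Continuous-time per-codon process: each of the
  nine single-base neighbours is proposed at relative rate κ (transitions)
  or 1 (transversions), weighted 1 for synonymous and ω for nonsynonymous
  changes. Proposals creating stops carry the nonsynonymous weight and are
  rejected when drawn (time advances, nothing changes) — simpler than
  renormalising the rate matrix and adequate at mitochondrial stop
  density; realized substitutions per site therefore run a hair below the
  nominal branch length. Rates are normalised so one unit of branch length
  is one expected substitution per nucleotide site at the root
  composition. Every realized substitution is logged into the emitted
  truth record.
- **Study layout.** All breeds share one uniformly drawn sense-codon
  ancestral sequence; the outgroup evolves from it along a single branch
  of `outgroup_depth` with `omega_div`; each breed's samples evolve over
  an independent genealogy with that breed's `omega_poly`. The implied
  true deleterious fraction is 1 − ω_div/ω_poly.
- **Default conditions** mirror the study scale: 18 breeds × 10 samples,
  3,743 codons (11,229 bp), genealogy heights log-spaced over
  1.7 × 10⁻⁴ … 7 × 10⁻³ subs/site (the 8.3–340 Kyr age range at the
  default μ), ω_poly decaying log-linearly with height from 0.6 to 0.15
  (young breeds loaded, old breeds purged), ω_div = 0.1 at outgroup depth
  0.05 subs/site, κ = 10 (mammalian mito transition bias).
- **What it does not emulate:** shared haplogroup structure between breeds
  (each genealogy is independent), selection dynamics (ω values are
  imposed rates, not evolved), indels, sequencing error, rate variation
  along the genome. Passing recovery tests therefore demonstrates
  estimator correctness under the model, not robustness to annotation or
  alignment artefacts in real GenBank data.
- A fixture writer emits each simulated sample as a minimal valid GenBank
  flat file (13 CDS features, ND6 reverse-complemented on the minus
  strand, breed source qualifier, per-gene TAA stops), so the extraction
  stage is round-trip tested against simulator truth.

Determinism: one `SeedSequence` spawns independent streams for the root
sequence, the outgroup and each breed, so identical configs (including
seed) give byte-identical outputs.

## Problem sizes used in the checks

The recovery checks run at the full study scale (18 breeds × 10 samples ×
3,743 codons, 100 bootstrap replicates — about a minute on one CPU); the
oracle-equivalence check uses 1,000 random pairs of up to 100 codons; the
UPGMA height recovery uses 50 independent genealogies of 8 samples at
10,000 codons (30 kb) and height 0.002 subs/site, where the median
relative error is well under the 30% acceptance bound (~5–18% in
practice). Unit tests use smaller cohorts (hundreds of codons) chosen to
keep the full suite fast while still exercising every code path.

## Known limitations

- The distance-based age estimator is downwardly/upwardly noisy for very
  shallow genealogies (few segregating sites) and is not a substitute for
  model-based coalescent dating when absolute ages matter.
- Very young simulated breeds can fail the inclusion filter (no
  nonsynonymous variant at 11 kb scale) — visible in the worked example,
  and a faithful reflection of the filter's behaviour on real shallow
  cohorts.
- ωS from a single outgroup branch includes the ingroup-side polymorphism
  contribution (tiny at species-level depths, ~2% here).
- No rate-variation-across-sites correction and no ML codon models: the
  pipeline implements counting estimators only.
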