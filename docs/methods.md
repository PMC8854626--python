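# Methods

## Chain model

An α-chain architecture is an ordered, gap-free tiling of residues
1..L by segments of four kinds: one non-collagenous (NC) amino terminus,
alternating collagenous regions and NC interruptions, and one NC
carboxyl terminus. Collagenous segments must be a whole number of
Gly-Xaa-Yaa triplets and begin on the Gly slot. All coordinates are
1-based inclusive (HGVS convention); cDNA position 1 is the A of the
initiator ATG, and residue *r* occupies cDNA positions 3(r−1)+1..3r.

Within each local collagenous region of G Gly residues, position classes
are assigned per Gly ordinal: 1 and G are `nc_boundary`; G−2 and G−1 are
`carboxyl_end`; 2 and 3 are `amino_end`; the rest `central`. When the
ranges overlap (regions with ≤6 Gly) precedence is
boundary > carboxyl_end > amino_end > central: trimerisation nucleates
at the carboxyl terminus and zips toward the amino end, so the
carboxyl-side label is the biologically prior one, and boundary status
is the primary stratifier of the whole analysis. Regions with one or two
Gly are therefore all boundary. A boundary Gly also carries a *side*
flag: the last Gly of a region sits on the amino side of the following
NC segment, the first Gly on the carboxyl side of the preceding one; a
single-Gly region (adjacent to both) is reported as amino. Only Gly
residues are classified as boundary — whether adjacency should extend to
the preceding Yaa residue is left out deliberately.

The molecular-location feature splits the CDS at exon 20: a variant in
exons 1–20 is in the "amino block". When only a protein-level
description is available the exon is taken from the first base of the
codon — a deterministic convention that can misassign a variant whose
codon straddles an exon junction (at most the last codon of an exon).

## Variant scope

Only single-nucleotide missense substitutions of collagenous Gly are in
scope; deletions, insertions, duplications, intronic descriptions and
multi-nucleotide variants are rejected at parse time, and a cDNA/protein
pair that maps to different codons is a hard error rather than a silent
preference for one description. The destabilisation dichotomy — mild
{Ala, Ser, Cys}, high {Arg, Val, Glu, Asp, Trp} — exactly covers the
residues reachable from Gly codons by one substitution (verified by
enumeration in the tests), so the classifier never sees a residue it
cannot place.

## Splice screen

Variants within 3 bases of an internal exon junction (the three terminal
exonic bases on either side; CDS start and end are termini, not
junctions) are screened. The scorer is the constrained maximum-entropy
model over splice windows: the distribution of maximal entropy whose
per-position and adjacent-pair nucleotide marginals match a set of
aligned true sites. On this chain-structured constraint set the model
factorizes over adjacent pairs, so the 23-mer acceptor window is handled
by transfer-matrix message passing rather than 4²³ enumeration. Fitting
is iterative proportional scaling to a marginal deviation below 1e-6
(cap 10,000 sweeps; in practice two). Contexts absent from training keep
probability zero — the maximum-likelihood limit — which makes the score
of a never-seen window −∞; callers treat that as "very weak site", which
is conservative for the exclusion rule below.

Scores are log₂(p_model/p_background) with a factorized background
(uniform by default). A variant is excluded when the mutant window
scores more than 15% below wild type, strictly:
drop = (wt − mut)/|wt|, affected iff drop > 0.15. Using |wt| keeps the
rule directional when the wild-type score is negative, where a plain
ratio would flip sign. Window geometry is the standard 9-mer donor
(3 exonic + 6 intronic) and 23-mer acceptor (20 intronic + 3 exonic);
since only exonic SNVs are in scope, intronic context must come from a
supplied context sequence, and shipped tests exercise the trainer on
generated sites only.

## Survival stage

Free-text records pass a case-insensitive keyword screen per endpoint
(kidney: renal, failure, ESRD, ESRF, ESKD, ESKF, transplant, dialysis;
hearing: hearing, hypoacusia, deaf, sensorineural, audio). The hearing
endpoint mirrors the kidney inclusion/exclusion rules exactly — an
assumption, flagged here, since "age at hearing-loss diagnosis" is a
reporting age, not an onset age.

Each family contributes once: the mean event age across affected males
(a reported range contributes its midpoint; a lone reported median is
taken as the value), or censoring at the *latest* last-seen age among
males when no event is reported (maximum rather than mean — the family
is known event-free up to its most recent report). Families with only
affected females, families whose males carry more than one
COL4A3–COL4A5 variant, and splice-flagged variants are excluded, each
with a machine-readable reason in the run manifest, which must reconcile
(families read = analyzed + excluded).

Estimation: Kaplan–Meier product-limit with Greenwood variance and
log-transformed pointwise 95% bounds (S·exp(±z·σ̂), σ̂² = Σ d/(n(n−d))),
median = first time the estimate reaches 0.5, median CI by inverting the
pointwise band; unreached bounds serialize as "ND". Group comparison by
the log-rank test; covariate effects by Cox proportional hazards with
Efron tie handling and a likelihood-ratio test of the overall model.
Reference levels: not-adjacent, mild substitution, exons 1–20, central
position. The numerical engine is `lifelines`; hand product-limit
computations and a from-scratch score-test identity serve as oracles in
the tests. The local-region subgroup drops boundary families and swaps
the boundary covariate for amino-end/carboxyl-end indicators — only the
covariate set changes, never the aggregation.

## Haematuria stage

Unrelated heterozygous carriers, one row each, outcome taken as given
(phenotype coding happens upstream). The genes are pooled without a gene
main effect; individuals carrying multiple qualifying variants are
excluded like multi-variant families. Fitting is maximum likelihood
(statsmodels Logit, Newton to 1e-8); the null log-likelihood uses its
closed form n₁ln p̂ + n₀ln(1−p̂). Perfect or quasi-separation — expected
when a stratum with a strong protective effect has a handful of events —
raises a distinct error; the pipeline reports such sub-models as
`not_fitted` with the reason rather than printing meaningless Wald
statistics. An empty term list fits the intercept-only model, whose MLE
is the logit of the observed prevalence. McFadden's pseudo-R² is
1 − ℓ_model/ℓ_null, clamped at 0 against solver round-off.

## Population stage

`expected_boundary_fraction` enumerates every single-base substitution
of every collagenous Gly codon, keeps missense outcomes (non-Gly,
non-stop), weights each by a neighbour-dependent rate keyed on
(5′ base, ref, alt, 3′ base), and returns the boundary rate mass over
the total — a ratio, invariant to global rescaling. The bundled rate
table is parametric: transition/transversion ratio 4 and a 10-fold boost
for CpG-context transitions (C>T before G and its strand complement),
the field-standard germline pattern dominated by methyl-CpG
deamination; any externally transcribed table loads through the same
file format. Tables are strand-symmetrized at load (averaged with the
reverse complement) unless declared `#stranded`, since coding-strand
context meets mostly strand-symmetric published tables. Splice-window
exclusion inside the expectation is off by default and exposed as a
sensitivity (on the bundled chain it shifts the expectation by under
half a percentage point).

The observed-vs-expected comparison is the exact binomial test by
direct pmf summation; the over-representation question is one-sided
("greater") by default with both sidedness options exposed. Carrier
prevalence sums per-variant carriers (hem + het + hom; each homozygous
female is one individual) under a rare-variant no-co-occurrence
approximation, over a declared male+female population.

## Synthetic data

Generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical inputs give identical outputs.

* **Architecture**: 23 collagenous regions (collagen IV chains carry
  21–26 interruptions), triplets per region 2 + Poisson(18) so boundary
  Gly come to ≈1/10 of collagenous Gly (the chain-level ratio of
  boundary to other Gly), interruptions uniform 2–12 residues, a
  27-residue amino terminus and 229-residue NC1, 53 exons of ≥12 nt cut
  at random. The shipped `synthetic_col4a5_like` files are one such draw
  and are labelled synthetic: real interruption coordinates are not
  bundled, so no conclusion about the real chains follows from them —
  what passing tests show is that the *method* is correct at the study's
  geometry.
* **CDS**: random Gly codons at Gly slots, random non-Gly sense codons
  elsewhere; translation therefore has Gly exactly at architecture Gly
  positions and no stops.
* **Registry**: per family, a variant drawn with boundary carriers at
  15% (the study's carrier mix), then an event time from an exponential
  proportional-hazards model — reference median 26 years, default log
  hazard ratios −0.8 (boundary), +0.7 (high destabilisation), 0
  (molecular location) — censored by an independent Uniform(10, 80)
  last-seen age (≈20% censoring). The *family-level* time is the PH
  draw; the 1–3 male records report ages whose mean equals it, so the
  record-level aggregation recovers the PH quantity exactly and Cox
  estimates are unbiased for the generating log-HRs. Real registries add
  within-family heterogeneity and reporting error that this deliberately
  omits.
* **Cohort**: features sampled as above; outcome Bernoulli with logit
  −2.41 − 1.25·boundary + 0.94·high + 0.24·carboxyl-block (study-scale
  defaults).
* **Allele table**: draws proportional to per-site mutational
  opportunity; each draw lands hemizygous male or heterozygous female
  with the X-chromosome share of each sex; homozygotes are not simulated
  (rare-variant regime).
* **Splice training**: i.i.d. draws from declared per-position weight
  matrices (canonical GT/AG-consensus donor and polypyrimidine-tract
  acceptor shapes), retained for trainer validation.

## Problem sizes and numerical choices

The default test run uses 300-family registries (100 replicates for CI
coverage), 3,000-individual cohorts (10 replicates for recovery, 100 for
coverage), 5,000 null replicates for log-rank calibration at n=60/group,
and sub-minute enumeration oracles; the whole suite runs in about three
minutes on one CPU. The acceptance script uses the same sizes with a
1,000-replicate calibration. Recovery-style checks with a sampling SE
near their tolerance (the ±0.3 band on coefficients whose SE is ≈0.2)
are asserted on the mean over 10 fixed-seed replicates — the band tests
bias, the separate coverage tests handle variance. Ties in Cox are
Efron's approximation; binomial two-sided p-values include outcomes with
mass ≤ mass(k) up to 1e-12 relative tolerance; the logistic
separation guard triggers at |coefficient| > 10.

## Known limitations

The shipped architectures are synthetic stand-ins; analyses of the real
chains require the real segment tables and CDS through the same file
interfaces. The rate table is a two-parameter summary of
neighbour-dependent mutation, not a transcribed published matrix.
The splice screen ships no trained human splice-site parameters; it
trains on synthetic sites or loads external tables. Phenotype free-text
handling is keyword-stamping only — no LOVD-style heterogeneity. No
kinship adjustment, control matching, ancestry stratification or
multiple-testing correction beyond the reported per-test p-values.
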