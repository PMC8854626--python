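# col4gly

Genotype–phenotype analysis of glycine substitutions in collagen IV
α-chains (COL4A3/COL4A4/COL4A5), the variant class behind most missense
Alport syndrome. The package is built for geneticists and methodologists
who want the full analysis chain — from variant notation to survival,
case-control and population-genetic statistics — as reusable, tested
code that runs end-to-end on synthetic cohorts with known ground truth.

## The science

A collagen IV α-chain is a long Gly-Xaa-Yaa triplet repeat interrupted
by 21–26 short non-collagenous (NC) segments and flanked by NC termini.
Gly is the only residue that fits the core of the triple helix, so a
missense change at a Gly position destabilises the protomer — but not
uniformly. The pipeline derives, for every Gly missense variant, the
three molecular features that stratify severity:

* **molecular location** — exons 1–20 vs exon 21 to the carboxyl terminus;
* **NC boundary adjacency** — whether the Gly is the first or last of its
  *local collagenous region* (one uninterrupted triplet stretch), i.e.
  sits against an interruption or terminus;
* **destabilising class** of the replacing residue — mild (Ala/Ser/Cys)
  vs high (Arg/Val/Glu/Asp/Trp); these eight residues are exactly the
  missense space reachable from the four Gly codons by one nucleotide
  change.

Variants within 3 bases of a splice junction are screened with a
maximum-entropy splice model (log₂-odds of the 9-mer donor / 23-mer
acceptor window under a distribution matching low-order marginals of
true sites vs background); a mutant score more than 15% below wild type
excludes the variant as a presumed splicing change.

Downstream, three statistical stages consume the feature vectors:

1. **Survival** — families collapse to one observation each (mean age at
   kidney failure across affected males, range midpoints, censoring at
   last report); Kaplan–Meier with Greenwood log-transformed intervals,
   log-rank tests and a Cox proportional-hazards model (Efron ties),
   `h(t|x) = h₀(t)·exp(βᵀx)`.
2. **Haematuria** — logistic regression
   `logit P(haematuria) = β₀ + β₁·carboxyl-block + β₂·boundary + β₃·high-destab`
   on unrelated heterozygous carriers, with McFadden's pseudo-R²
   (`1 − ℓ_model/ℓ_null`), recurrent-variant sensitivity re-fits and a
   local-region subgroup (boundary carriers removed, amino/carboxyl-end
   indicators added).
3. **Population** — the expected share of Gly missense SNVs hitting
   boundary residues under a neighbour-dependent substitution-rate model
   (transitions ≫ transversions, CpG transitions boosted), compared with
   the observed share by the exact binomial test; carrier prevalence
   from hemizygote/heterozygote/homozygote counts with X-linked allele
   accounting (`alleles = hem + het + 2·hom`, homozygous females one
   carrier).

Because the source cohorts (a locus-specific family registry, a national
case-control genome programme, a population frequency database) are not
redistributable, `col4gly.synthetic` generates stand-ins whose
parameters are the study-scale conditions (157/80 families, 304
carriers, 23 collagenous regions with boundary Gly ≈ 1/10 of all Gly),
and every stage is validated against independent oracles on them. The
bundled chain architectures are synthetic and labelled as such.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_survival.py
python analysis/03_haematuria.py
python analysis/04_population.py
```

prints (abridged):

```
[kidney] 157 families, median age 19.5 y; boundary HR 0.71 (p=0.168),
         high-destab HR 1.96 (p=0.001)
[hearing] 80 families, ... boundary HR 0.44 (p=0.023), high-destab HR 2.43 (p=0.006)
[n=304] 304 individuals (34 with haematuria); full model not fitted:
        diverging coefficient suggests (quasi-)separation
[n=3000] 3000 individuals (463 with haematuria); boundary estimate -0.98
         (p=0.000), high-destab estimate 0.97 (p=0.000); pseudo-R2 0.038
expected boundary share 0.121 (splice-window sensitivity 0.125);
observed 0.333, exact binomial p = 1.71e-04
top-5 boundary variants: 732 carriers in 141456 people = 0.52% (1 in 193)
```

Reading this: the Cox fits recover the generating hazard ratios
(boundary protective, highly destabilising substitutions harmful); at
the study-scale cohort of 304 the boundary stratum carries so few events
that a replicate can be unfittable — the same sparsity that makes
boundary confidence intervals wide in real cohorts — while at n=3,000
the logistic stage recovers the generating coefficients (−1.25 and
+0.94). The population stage shows boundary variants over-represented
relative to their mutational opportunity, the signature of a
less-selected, milder variant class.

The same stages are scriptable via the `col4gly` CLI
(`simulate`, `annotate`, `splice`, `survival`, `haematuria`,
`population`, `run`).

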