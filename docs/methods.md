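# Methods

## The model

Somatic evolution leaves an asymmetric record: mutations that raise tumor-cell
fitness are enriched in a patient cohort (drivers), mutations that lower it are
purged before the tumor is sampled. A gene whose intact function the tumor
needs therefore shows *fewer* protein-altering mutations than a neutral gene of
the same size — negative selection is visible only as a deficit against a
size-matched background.

For a cohort of `N` patients and a gene `g` with coding length `L_g` (longest
transcript, in bases), the pipeline computes:

1. **Mutated fraction** `f_g = n_g / N`, where `n_g` is the number of patients
   with at least one protein-altering mutation in `g` (a patient counts once
   per gene, however many qualifying mutations it carries). Protein-altering
   means nonsynonymous, truncating, or canonical splice-site; the concrete MAF
   classification set is configurable (see below).
2. **Coverage correction** `c_g = f_g / m_g`, where `m_g` is the cohort median
   of the gene's per-sample covered fraction — the share of its coding bases
   with tumor depth ≥ 14 and matched-normal depth ≥ 8 (25 bp flanks included
   when depth arrays carry them). Without this step, a poorly sequenced gene
   would masquerade as conserved. `c_g` is deliberately not capped at 1.
3. **Gene filters.** Genes with median coverage < 0.5, expression < 2.0 log2
   counts, or an annotation-error flag are excluded before fitting (reasons
   are reported per gene; values exactly at a boundary are kept, matching the
   strict `<` in the rules). Low-expression genes are removed because a gene
   the tumor does not express cannot be under mutational selection for its
   protein function.
4. **Size regression.** Both axes are square-root transformed and a line
   `sqrt(c_g) ~ a + b·sqrt(L_g)` is fitted across all kept genes of the
   cohort. Under a neutral per-base hit process with small per-gene
   probability, `E[c_g] ≈ rate·L_g`, so `sqrt(c)` is nearly proportional to
   `sqrt(L)` — the transform simultaneously linearizes the size relation and
   stabilizes the binomial variance of the observed fraction
   (`Var sqrt(f) ≈ 1/4N`, independent of `p`), which is what makes a single
   residual scale meaningful across gene sizes.
5. **Standardized residual.** `SR_g = (sqrt(c_g) − fitted_g) / s`, with `s`
   the regression residual standard error `sqrt(RSS/(n−2))`. Genes with
   `SR ≤ −1` are labelled conserved, `SR ≥ +1` over-mutated, in between
   background; `|SR| ≥ 1.65` and `|SR| ≥ 2.0` mark the suggestive and
   significant tiers (two-sided normal reference, p ≈ 0.1 and 0.05). A
   two-sided normal p-value is reported per gene for reference; no
   multiple-testing correction is applied, matching the tiered-threshold
   usage of the statistic.

Cohorts are defined by driver stratification before any scoring: a patient
carrying a recurrent activating mutation in exactly one of the rule genes
(KRAS G12/G13/Q61/A146; BRAF V600/N581/G464/G466/G469/G596/D594; EGFR
L858/S768/L861/G719/T790 or an indel in exons 18–21) joins that gene's cohort;
matches in more than one rule gene exclude the patient; no match is WT. The
regression is fitted per cohort, independently, on that cohort's kept genes.

## Design choices where the procedure was genuinely open

- **Estimator.** Default is OLS; `--estimator huber` fits a Huber M-estimator
  (tuning constant 1.345, MAD scale) so that grossly over-mutated drivers do
  not drag the background line upward. OLS is the default because its
  residual scale has a closed form that an independent oracle can reproduce
  exactly, and on cohorts of ~2,000 genes a handful of drivers moves the OLS
  line negligibly.
- **Residual definition.** `SR` divides by the global residual standard error
  by default; a `studentized` option additionally divides each residual by
  `sqrt(1 − leverage)`. The default keeps the statistic scale-equivariant and
  trivially auditable; leverages matter only for extreme gene sizes.
- **Zero-mutation genes** stay in the fit (`sqrt(0) = 0` is well-defined);
  dropping them would bias the line upward and hide exactly the genes the
  method exists to find.
- **Sample selection.** When a patient has several tumor samples, the
  primary-tumor sample (barcode type code "01") with the lexicographically
  smallest barcode is kept. Any deterministic rule works; this one is stable
  across input orderings.
- **Hotspot semantics.** Rules name reference residues (e.g. "G12"), so any
  non-synonymous substitution at the site matches and synonymous changes
  (p.G12G) do not; three-letter HGVSp is normalized to one-letter form first.
  Frameshifts at a hotspot codon do not match the substitution rule (they are
  not activating); indels match only through an explicit exon-range rule.
- **Frequently mutated** genes use the *raw* fraction with a strict `> 0.10`
  cutoff.
- **Expression summarization.** Expression enters only as one log2 value per
  gene; when a per-sample matrix is supplied it is collapsed with a
  configurable aggregator (default median).

## What the synthetic generator emulates

`synthetic_data` produces the full input bundle (MAF, coverage TSV,
expression TSV, annotation TSV, plus truth tables) from one seed:

- Gene lengths are log-normal (median 1.5 kb, σ = 0.6), spanning roughly
  0.4–6 kb like human coding genes.
- Each patient mutates gene `g` with probability
  `1 − (1 − rate·mult_g)^{L_g}`; the default per-base rate is calibrated so a
  median-length neutral gene is mutated in 3% of patients, the background
  scale of exome-sequenced lung adenocarcinoma. Multiplier < 1 plants
  conservation, > 1 positive selection; planted genes are placed in the
  longest length-quartile so the neutral expectation they must fall away from
  is well above the noise floor.
- One uniform draw per (patient, gene) is compared with that probability, so
  under a fixed seed raising a multiplier can only add events (monotone
  coupling), and a fixed seed is byte-identical across runs.
- Coverage fractions are `1 − Beta(2, 40)` per gene and sample (mean ≈ 0.95);
  planted low-coverage genes draw from Uniform(0.10, 0.45) so their median is
  below the 0.5 filter in every replicate. Expression is Normal(7, 2) per
  gene with planted low-expression genes in (0.5, 1.9).
- Driver planting writes genuine hotspot HGVSp strings (KRAS p.G12D class,
  BRAF p.V600E class, EGFR p.L858R class and p.E746_A750del exon-19
  deletions) into chosen patients; multi-driver patients receive two rule
  genes and must be excluded by stratification. Silent decoy mutations
  (Poisson, ~1 per patient) exercise the protein-altering filter.

The generator is deliberately simpler than real tumors: no trinucleotide
signature structure, no hypermutators, no subclonality, no correlation
between expression and mutation rate, and coverage independent of sequence
context. Tests passing on it demonstrate that the statistics recover planted
selection under the model's own assumptions — not that those assumptions hold
in any particular TCGA cohort.

## Problem sizes and numerics

Simulation-based tests use 200 patients × 2,000 genes for null calibration
(20 replicates) and 400 × 2,000 for recovery (planted multiplier-0 genes and
multiplier-5 drivers); these sizes put ~3 mutated patients on a median gene,
enough for the sqrt-scale normal approximation to hold to the advertised
tolerances while each replicate runs in about a second. The regression core
is checked against an explicit normal-equation oracle at 1e−10. A residual
scale below 1e−12 (exactly collinear input) is treated as degenerate and
raises rather than producing infinite SRs. Fitting requires ≥ 3 genes and
non-constant sizes.

## Known limitations

- SR's normal reference is approximate; for very short genes or tiny cohorts
  the discreteness of `f` makes extreme negative SRs unreachable (a 400 bp
  gene cannot fall far below a line that predicts `sqrt(c) ≈ 0.1`). Planting
  conservation on long genes in tests reflects this: the method has power
  against conservation only where the expected burden is large.
- Coverage correction assumes missingness is independent of mutation status
  given the gene.
- One value of expression per gene per cohort; no per-patient expression
  modelling.
- No multiple-testing control: the tiers are screening thresholds, not
  family-wise error guarantees.
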