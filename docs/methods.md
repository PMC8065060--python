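# Methods

## Model and conventions

`dqmotif` analyses case–control association between type 1 diabetes and
HLA-DQ amino-acid motifs: the ordered residues at a fixed panel of structural
positions (default αa1, α44, α157, α196 on the alpha chain and β9, β30, β57,
β70, β135 on the beta chain). The panel itself is an *input* — it comes from
upstream residue-selection work (hierarchically organized haplotype
analysis), not from this package — and is configurable via `ResiduePanel`.

**Position labels are opaque.** Structural numbering of MHC II chains
involves alignment conventions that cannot be recomputed from raw sequences
alone (the alpha chain has an extra N-terminal residue labelled "a1" ahead of
positions 1..232; the beta chain runs 1..237). The registry therefore reads
position labels from the fixture header verbatim and never renumbers,
avoiding silent off-by-one drift. Allele names are matched at two-field
resolution (`DQA1*05:01`); higher-resolution suffixes map to their two-field
parent unless the fixture distinguishes them.

**The shipped fixture is curated, partly synthetic.** The motif-panel columns
of `data/dq_registry.tsv` are curated from published motif↔allele
correspondences (DQ2.5 = `DCAA-YSARD`, DQ8.1 = `DQAA-YYARD`/`DQDA-YYARD`,
DQ6.2 = `DRAA-FYDGD`, the β57 A/D dimorphism between DQB1\*03:02 and
DQB1\*06:02, the α157S chain behind `DCSA-YYDRD`, etc.). The additional
polymorphic columns (α22, α52, α75, β13, β26, β45, β66) are synthetic filler
whose only purpose is to exercise the polymorphic-position scan and the
residue-level conditional scan; they do not reproduce IMGT sequences. Parsing
raw IMGT alignments is deliberately out of scope.

## Odds-ratio conventions

Two conventions coexist, always labelled:

- `or_virtual` — the *virtual reference* convention. Rather than electing a
  reference haplotype, one imagines a haplotype with identical frequency in
  cases and controls (OR 1); every unit's OR is then the ratio of its case
  and control frequencies. The Wald SE of the log ratio under multinomial
  copy sampling is `sqrt(1/a − 1/N_case + 1/c − 1/N_control)`. Because case
  and control frequencies each sum to one, the control-frequency-weighted
  mean of the virtual ORs is forced to 1 — a constraint worth remembering
  when configuring the simulator (below).
- `or_2x2` — the familiar cross-product (or conditional-MLE) odds ratio of a
  2×2 table, used by the one-vs-rest genotype tests.

The genotype table's "virtual genotype" offset logistic is implemented in
closed form: an intercept-free binomial model with constant offset
`logit(N_case/(N_case+N_control))` has ML coefficient exactly equal to the
log frequency-ratio OR, with SE `sqrt(1/a + 1/c)`; a statsmodels GLM with
the same offset serves as the cross-check in the tests. Separation (a zero
cell) falls back to Fisher's exact test with a directional OR sentinel
(0 or ∞) instead of a diverging estimate; group-exclusive motifs are
classified using the exact p. Two-sided exact p-values sum hypergeometric
probabilities no larger than the observed table's.

**Subject-clustered variance.** A subject contributes two correlated motif
copies, so copy-level multinomial SEs understate uncertainty. For CI-based
checks, `virtual_or_clustered` estimates `Var(p̂)` per group from the
between-subject variance of per-subject copy counts. In a 2,000-rep
calibration of the simulate→analyse round trip this SE tracks the empirical
SD to better than 1% and the nominal 95% CI covers the generative truth
~94.7% of the time (log-OR Wald intervals are mildly below nominal).

## Conditional scans

Trans-motif and residue associations are assessed after adjusting for the
cis motifs, in two steps: fit `logit Pr(Y=1) = adjust(X, β)` without the
test terms, then test each term Z holding the adjustment fixed. The test is
the efficient score at γ = 0: `U = Z'(y − p̂)` with variance
`V = Z'WZ − Z'WX (X'WX)⁻¹ X'WZ`. The projection term matters: a plain Wald
test from the offset fit treats the adjustment as known and is severely
conservative whenever Z is correlated with X (in calibration runs it
rejected at rate ~0 instead of 0.05; the score test rejects at 0.05 ± 0.01).
Multi-column terms (one count column per non-baseline amino acid at a
residue) use the quadratic form `U'V⁻¹U ~ χ²`. Terms whose residual on the
adjustment design is numerically zero are reported as `confounded`
(coef 0, p NA) — with a one-haplotype-per-motif pool every residue is a
linear function of the motif counts, so this is the expected outcome, and
the marginal p is still reported for the contrast. Terms with fewer than
five copies are skipped.

No multiple-testing correction is applied anywhere by default; this mirrors
the deliberate analytic stance of the study design this package follows
(exploration within a region already known to be associated). A
Benjamini–Hochberg utility (`bh_adjust`) exists, off by default.

## Phasing

Unphased two-locus genotypes are phased by EM over haplotype frequencies:
initialisation from allele-frequency products, at most 500 iterations,
absolute log-likelihood tolerance 1e-8. Posteriors for the two phasings of a
double heterozygote are proportional to products of estimated haplotype
frequencies; subjects below the posterior threshold (default 0.97, chosen as
the plausible floor in a high-LD region like DR-DQ) are flagged. The
pipeline records whether input was pre-phased or EM-phased.

## Rare-unit handling

Motif-level (allelic) analysis *excludes* motifs with fewer than five copies
and reports effective totals `2N − excluded`; genotype-level analysis *pools*
genotypes with fewer than five observations into a single retained `rare`
category. The two behaviours differ deliberately, mirroring the allelic and
genotypic table conventions. Motif classification: `rare` takes precedence;
otherwise p < 0.05 with OR > 1 is `risk`, p < 0.05 with OR < 1 `resistant`,
else `neutral` (α configurable).

## Clustering

Unique motifs are compared by Levenshtein distance (engine: edlib's global
alignment; separators stripped first) and agglomerated with scipy's `ward`
linkage on the precomputed distances, which is the `ward.D2` convention
(verified against a hand-written Lance–Williams recurrence). Sequence labels
are sorted lexicographically before clustering so results are invariant to
input row order. The cut level k is a user parameter — no selection rule is
imposed. Newick export renders an ultrametric tree (branch length =
merge-height difference), and round-trips through standard parsers.

## Synthetic cohorts

`SynthConfig` defaults define the study conditions: 636 controls, 962
patients; a 17-haplotype (DQA1, DQB1, DRB1) pool whose frequencies are
synthetic but shaped like the published control motif spectrum; per-motif
log odds ratios equal to the log of the published motif ORs (DQ2.5 2.10,
DQ8.1 3.34/3.71, DQ6.2 0.03, ...); baseline prevalence logit −5.5 (~0.4%,
childhood T1D in Sweden); antibody baselines and motif-conditional effects
following the published GADA/IA-2A/ZnT8A patterns; and a small rare-motif
injection channel (rate 0.004) drawing unusual allele pairings.

Because the virtual-reference convention forces `Σ f·OR = 1` over the control
pool, the frequency map was balanced once so that the configured ORs are
mutually consistent (`Σ f·OR ≈ 0.99`); otherwise genuinely neutral motifs
would realise ORs systematically away from 1. Disease is drawn per subject
from `logit p = base + β(motif₁) + β(motif₂)`; cases and controls are
rejection-sampled to the requested quotas, so each group is an i.i.d. sample
from its conditional distribution. Antibodies are drawn for cases only;
controls carry missing calls, and missing is treated as missing, never as
negative.

`expected_virtual_ors` computes the *exact* population case/control motif
frequencies (and hence virtual ORs) by enumeration over all genotype pairs —
the closed-form truth that sampled cohorts estimate, used as the oracle in
parameter-recovery tests. `simulate_ld_panel` attaches a DRB1 allele to a
chosen DQ haplotype with tunable D′ for the joint-haplotype analyses.

**What the generator does not emulate:** genotyping error, allele imputation
uncertainty, population stratification or immigration structure, age/sex
covariates, temporal dynamics of autoantibody appearance, and structural
permissibility of trans dimers (all dimers are permitted by default; the
permissibility table is a user input). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to these real-data complications.

## Problem sizes in the shipped checks

The test suite and acceptance script use: exhaustive Fisher-vs-enumeration
agreement on all 2×2 tables with n ≤ 32 plus a seeded 3,000-table sample up
to n = 60; EM phasing at n = 2,000 under high LD; conditional-scan type-I
calibration over 1,000 replicates of n = 400; simulate→analyse CI coverage
over 500 cohorts of n = 2,000; 1,000 random string pairs against the DP
edit-distance oracle. These sizes were chosen to make each check
statistically decisive while keeping a full run fast on a single CPU.

## Known limitations

- The score-test z is reported in place of the haplotype-score statistic of
  specialised haplotype-regression software; equivalence with that software
  is not claimed.
- Attributable-fraction confidence intervals are not computed analytically
  (use bootstrap over subjects if needed).
- The EM phaser handles two loci (DQA1–DQB1); DRB1 is expected phased with
  DQ (as produced by the simulator), not phased de novo across three loci.
- Levenshtein distance on equal-length motif strings effectively reduces to
  Hamming-like substitution counts; insertions/deletions only matter for
  unequal-length chains, which the default fixture does not contain.
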