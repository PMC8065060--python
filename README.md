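# dqmotif

A case–control association pipeline for HLA-DQ amino-acid motifs, built around
the genetics of type 1 diabetes (T1D).

HLA-DQ is a class II major-histocompatibility heterodimer of an alpha chain
(encoded by *DQA1*) and a beta chain (*DQB1*) that presents peptides to CD4+
T cells. Most of the HLA contribution to T1D risk maps to this molecule, and
it can be summarised by a small panel of critical residues: four on the alpha
chain (αa1, α44, α157, α196) and five on the beta chain (β9, β30, β57, β70,
β135). The ordered amino acids at these nine positions form a **motif**,
rendered `AAAA-BBBBB` (alpha residues, hyphen, beta residues) — e.g.
`DCAA-YSARD` is the classic risk haplotype DQ2.5 (DQA1\*05:01–DQB1\*02:01)
and `DRAA-FYDGD` the protective DQ6.2 (DQA1\*01:02–DQB1\*06:02).

`dqmotif` takes subject-level DQA1/DQB1 genotypes (phased, or unphased with
EM phasing) and computes:

- **cis motifs** per haplotype and **trans heterodimers** (alpha from one
  chromosome, beta from the other; up to four distinct DQ molecules per
  doubly heterozygous subject), with a configurable permissibility table for
  structurally prohibited trans dimers;
- **allelic (motif) association** under the *virtual reference* convention:
  an imaginary haplotype with equal frequency in cases and controls has
  OR = 1, so any motif's odds ratio is simply the ratio of its case and
  control frequencies, `OR_m = p̂_case(m) / p̂_control(m)`, with Wald z on
  the log scale. Motifs with fewer than five observed copies are excluded;
- **genotype association** one-vs-rest with the virtual-genotype offset
  convention (rare genotypes pooled into a retained `rare` category), and the
  genotype-group pairing analysis of each risk motif with neutral motifs,
  itself, other risk motifs and resistant motifs;
- **conditional scans**: each trans motif or polymorphic residue tested after
  adjusting for the full cis-motif design, via the efficient score test
  `U = Z'(y − p̂)`, `V = Z'WZ − Z'WX(X'WX)⁻¹X'WZ` (marginal p reported
  alongside);
- **DR-DQ joint haplotype** analysis and per-motif **islet autoantibody**
  associations (IAA, GADA, IA-2A, ZnT8R/W/QA) among patients;
- **Shannon entropy** `H = −Σ f_j log f_j` of the motif pool per group, and
  **attributable fractions** per pooled genotype group,
  `AF = f(OR − 1) / (1 + f·|OR − 1|)`, with neutral homozygotes as the
  logistic-regression reference.

Because the underlying clinical cohort is not public, the package ships a
first-class synthetic-data module (`dqmotif.simulate`) that emulates the study
design: 636 controls and 962 patients, Hardy–Weinberg haplotypes from a
control pool shaped like the published motif spectrum, disease status from a
logistic model additive in per-motif log odds ratios, and motif-conditional
antibody positivity among patients. Every analysis stage is exercised against
this generator with known truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort; each step writes its tables under `results/`.

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_associations.py
python analysis/05_diversity_and_af.py
```

prints (abridged):

```
cohort: 636 controls, 962 patients (17 haplotypes in the pool, ...)
rare motif exclusion: 3 motifs, 4 control and 4 case copies excluded;
  effective totals 1268 control, 1920 case copies
motif classes: {'neutral': 4, 'resistant': 7, 'risk': 4}
strongest risk motif: DQAA-YYARD (OR 3.24, p 3.86e-26)
motif entropy: 2.35 nats among controls vs 1.94 among patients
  resistant/resistant    OR   0.03  AF  -12.8% (protection)
  neutral/risk           OR   2.90  AF  +22.6% (risk)
  risk/risk              OR   7.91  AF  +20.7% (risk)
```

Reading this: the generator injected OR 3.34 on the DQ8.1 motif
`DQAA-YYARD`, and the virtual-reference analysis recovers OR 3.24 at this
sample size. Rare-motif exclusion keeps the copy bookkeeping explicit
(2 × 636 − 4 = 1268 control copies retained). The patient motif pool is less
diverse than the control pool because cases concentrate on the few risk
motifs, and homozygous carriers of risk motifs account for about a fifth of
the population disease odds under this configuration.

The same pipeline is available as a CLI (`dqmotif simulate / registry /
cluster / motifs / assoc / summarize / run`) and as a library
(`dqmotif.run_pipeline`).

## Allele fixture

`src/dqmotif/data/dq_registry.tsv` maps common DQA1/DQB1 alleles to their
residues at the motif panel plus a few extra polymorphic positions. The panel
columns are curated from published motif↔allele correspondences; the extra
columns are synthetic filler for exercising residue scans (see the file
header and `docs/methods.md`).

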