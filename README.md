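# modscreen

Quantitative analysis pipeline for a *Drosophila melanogaster* genetic-modifier
screen of the gain-of-function sodium-channel allele *para^Shu*. The screen
asks which chromosomal deficiencies (and ultimately which gene — the sigma-class
glutathione S-transferase *GstS1*) dominantly suppress the allele's phenotypes:
defective reactive climbing, spontaneous tremors, heat-induced seizures,
bang-sensitive paralysis, down-turned wings and an indented thorax, reduced
male viability and fertility, and transcriptome changes.

The package is aimed at behavioral geneticists and biostatisticians who need
the screen's scoring statistics and tests as reusable, tested code: every
statistic is implemented from first principles, every assay has a synthetic
generator with known ground truth, and the published summary tables ship as
typed data so the screen's categorical analysis reproduces end to end.

## What it computes

**Climbing index** (Benzer countercurrent assay). After five climb trials the
flies in tubes 0–5 are counted and

    CI = Σ(Nᵢ · i) / (5 · ΣNᵢ),  i = 0..5.

Under the binomial model (each fly gets 5 independent Bernoulli(p) climb
opportunities) CI is the MLE of the per-trial climb probability and
E[CI] = p (`countercurrent`).

**Center occupancy** (video-tracked tremor severity). The fraction of
analyzed frames (last 5 min of a 10-min, 30 fps recording) a fly spends
strictly inside a concentric disc of radius 0.743 R in a circular arena:
wall-following flies score near 0, tremoring flies high (`locomotion`).

**Seizure and recovery analysis.** Per-5-s-bin seizure incidence over 2 min,
summarized across replicate groups (mean ± SEM) and compared between
genotypes by mixed two-way repeated-measures ANOVA with Holm-Sidak per-bin
comparisons; bang-sensitivity recovery times with right-censoring, compared
by the Mann-Whitney U test (`seizure_recovery`).

**Penetrance tables.** Affected/scored counts per trait, Fisher's exact test
against the control row, and significance against the Bonferroni threshold
α/m (0.05/11 in the published screen). Printed percentages are inverted back
to integer counts with a round-trip validity flag (`phenotype_tables`,
`datasets`).

**Differential expression (simplified).** Median-of-ratios size factors, a
per-gene negative-binomial Wald test (method-of-moments dispersion, no
shrinkage), BH adjustment, DE-set extraction and hypergeometric GO
over-representation (`de_counts`).

All tests — exact Fisher by integer hypergeometric enumeration, rank tests
with midranks and tie corrections, the mixed ANOVA sums-of-squares — live in
`core_stats` and are cross-checked in the test suite against independent
oracles (rational enumeration, scipy, statsmodels, pingouin, pydeseq2).

## Worked example

The numbered scripts under `analysis/` run each stage and write tables to
`results/`. Reproducing the published viability table and the GST-deficiency
screen needs no simulation at all:

```sh
python analysis/01_published_tables.py
```

prints, among other rows,

```
Viability and fertility of para^Shu males by GstS1^M26 dose:
    genotype  total_male  pct_mutant_class  fertility_tested  pct_fertile
         shu          73               8.2                43          2.3
shu;GstS1-/+         121              31.4                45         37.8
shu;GstS1-/-         145              53.1                44         38.6
...
  Df(3L)BSC157 thorax            70.0 5.156961e-03        False
  Df(2R)BSC433  wings            12.5 3.578419e-15         True
  Df(2R)BSC433 thorax            35.7 1.049730e-08         True

5 of 22 comparisons significant after Bonferroni.
```

i.e. *para^Shu* males are nearly absent (8.2% of male progeny) unless one or
two copies of the *GstS1* null are present (31.4%, 53.1%); in the deficiency
screen only the *GstS1*-removing deficiency suppresses both morphological
traits (p < 10⁻⁸ for each, far below the 0.05/11 = 0.004545 threshold),
while e.g. the *GstO1–O4* thorax comparison (p = 0.0052) just misses it.

The simulation-backed stages run the same way:

```sh
python analysis/02_climbing.py --seed 0        # Kruskal-Wallis + Dunn on CIs
python analysis/03_locomotion_tremor.py        # occupancy separation
python analysis/04_seizure_recovery.py         # RM-ANOVA + Mann-Whitney
python analysis/05_differential_expression.py  # NB test + BH + GO
```

For shell-based use the same stages are exposed as a CLI
(`modscreen simulate|climbing|locomotion|seizure|bangsense|tables|de`); see
`modscreen --help`.

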