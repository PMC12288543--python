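# plastcov

Depth and evenness of sequencing coverage in quadripartite plastid genomes.

Plastid (chloroplast) genomes archived in public databases were assembled
from read sets of very different quality, and the archived records rarely say
how trustworthy an assembly is.  Two coverage properties are informative:
**sequencing depth**, summarized here as *windows with reduced sequencing
depth* (WRSD — 250 bp windows whose mean depth falls more than one standard
deviation below the plastome-wide window average, counted per structural
partition and per coding status, normalized per kb), and **sequencing
evenness**, summarized as the plastome-wide E-score

```
C  = round(mean per-base depth)          D2 = {d : d ≤ C}
E  = 1 − (|D2| − Σ(D2)/C) / |D|          E ∈ [0, 1]
```

— the complement of the fraction of reads that would need redistribution
from above-average to below-average coverage sections to equalize coverage.

`plastcov` is a library plus a set of numbered analysis drivers for asking,
on a cohort of plastomes with per-base depth profiles: does depth vary with
the quadripartite structure (LSC / IRb / SSC / IRa) and the coding/non-coding
subdivision?  Is evenness associated with assembly quality (ambiguous
nucleotides, IR mismatches) or with the sequencing platform?  Are those
associations confounded by partition length or read length, biased by
phylogenetic signal, or driven by assembler choice?  It is aimed at
plastome/organelle genomics researchers doing assembly quality control.

## What is in the package

| module | contents |
|---|---|
| `plastcov.core` | circular-coordinate data model: `PlastomeRecord`, `PartitionMap`, `CoverageProfile` |
| `plastcov.genome_io` | GenBank / FASTA+GFF3 / BED input, samtools-depth & bedGraph tables, metadata harmonization, IR boundary polishing, provenance-stamped TSVs |
| `plastcov.coverage` | window tiling, WRSD classification, E-score, Tukey far-out fences |
| `plastcov.quality` | ambiguity count, IR synteny & mismatch count (banded edit distance), Tukey-ladder standardization |
| `plastcov.stats` | Kruskal–Wallis + η², Wilcoxon (normal approx., ties, continuity) + Cohen's d, pairwise tests with BH adjustment, Spearman, Levene, effect/significance labels, min-5 group rule |
| `plastcov.models` | OLS with treatment coding; CART trees with cost-complexity pruning and variable importance |
| `plastcov.physig` | Moran's I, Blomberg's K and K*, permutation tests, correlograms with bootstrap CIs, randomized / enforced-BM control traits |
| `plastcov.simulate` | synthetic cohorts with injected ground truth; Yule trees with BM or white-noise traits |
| `plastcov.pipeline` | the analysis recipes the drivers under `analysis/` call |

The model details and all numerical conventions are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a 60-genome cohort at canonical plastome scale and run the
univariate battery (`analysis/01_simulate_cohort.py` then
`analysis/04_univariate_tests.py`, or directly):

```python
from plastcov.simulate import SimConfig, simulate_dataset
from plastcov.pipeline import RunConfig, run_stats

per_sample, windows, truths = simulate_dataset(60, SimConfig(), seed=20_260_918)
out = run_stats(per_sample, windows, RunConfig(seed=20_260_918))
print(out["omnibus"].to_string(index=False))
```

which prints (abridged):

```
              variable   n  statistic      p  effect effect_label significance
        WRSD/partition 240     1.5100 0.6800 -0.0063         none           ns
WRSD coding/non-coding 120  1780.0000 0.9185  0.0468         none           ns
 E-score ~ q_ambiguous  60     0.2062 0.1139  0.2062        small           ns
      E-score/platform  60    15.6019 0.0081  0.1963        large           **
      E-score/software  60     1.8186 0.6109 -0.0211         none           ns
```

Reading it: the generator routes platform effects through coverage-dip rates
but gives assembly software no effect — and the tests recover exactly that
dichotomy (platform Kruskal–Wallis p = 0.008 with η² = 0.196; software
p = 0.61 with a negative η²).  WRSD counts do not differ across partitions
here because the generator places dips uniformly.  The phylogenetic-signal
driver (`analysis/06_phylo_signal.py`) shows the companion control: the
E-score trait is significant for Moran's I and Blomberg's K/K* only under
the enforced-Brownian-motion distribution (p = 0.001), not under the
empirical or randomized ones — evenness carries no phylogenetic bias in this
cohort, so platform associations can be read at face value.

The drivers `analysis/01…07` run these stages in order (cohort, coverage
dispersion, assembly quality, univariate tests, regression models,
phylogenetic signal, assembler comparison) and write their tables under
`results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch with the given seed: it simulates the
default cohort, computes coverage and evenness metrics with outlier
screening, runs the univariate battery, fits the linear and tree models with
and without covariates, and runs the three-distribution phylogenetic-signal
tests, writing summary tables next to the JSON output.
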