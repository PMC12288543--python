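"""Univariate battery: Kruskal-Wallis across partitions and platforms,
pairwise Wilcoxon with BH adjustment, the coding/non-coding comparison, and
Spearman correlations of evenness with assembly quality.

Writes results/univariate_omnibus.tsv and results/pairwise_partition.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import DEFAULT_SEED, RESULTS, build_cohort  # noqa: E402

from plastcov.genome_io import write_results_table  # noqa: E402
from plastcov.pipeline import RunConfig, run_stats  # noqa: E402


def main(seed: int = DEFAULT_SEED) -> None:
    per_sample, windows, _ = build_cohort(seed)
    out = run_stats(per_sample, windows, RunConfig(seed=seed))
    RESULTS.mkdir(exist_ok=True)
    write_results_table(out["omnibus"], RESULTS / "univariate_omnibus.tsv",
                        seed=seed)
    write_results_table(out["pairwise_partition"],
                        RESULTS / "pairwise_partition.tsv", seed=seed)
    print(out["omnibus"].to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}"))
    if out["pairwise_platform"] is not None:
        write_results_table(out["pairwise_platform"],
                            RESULTS / "pairwise_platform.tsv", seed=seed)
        n_sig = (out["pairwise_platform"]["p_adj"] < 0.05).sum()
        print(f"\npairwise platform comparisons significant after BH: "
              f"{n_sig}/{len(out['pairwise_platform'])}")
    print(f"wrote univariate tables to {RESULTS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
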