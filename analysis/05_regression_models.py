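"""Multivariate models: linear regression and CART trees for sequencing
depth (normalized WRSD counts) and evenness (E-score), each with and without
the covariates partition length and average read length.

Writes results/explained_variation.tsv and results/tree_importance.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import DEFAULT_SEED, RESULTS, build_cohort  # noqa: E402

from plastcov.genome_io import write_results_table  # noqa: E402
from plastcov.pipeline import (  # noqa: E402
    RunConfig,
    depth_model_table,
    evenness_model_table,
    explained_variation_table,
    run_models,
)


def main(seed: int = DEFAULT_SEED) -> None:
    per_sample, windows, _ = build_cohort(seed)

    dt = depth_model_table(windows, per_sample)
    depth_res = run_models(dt, "wrsd_norm", ["partition", "coding_status"],
                           ["partition_length", "avg_read_length"], seed=seed)
    et = evenness_model_table(per_sample, RunConfig(seed=seed))
    even_res = run_models(et, "e_score", ["platform", "q_ambiguous", "q_irmm"],
                          ["genome_length", "avg_read_length"], seed=seed)

    rows, imp_rows = [], []
    for outcome, results in [("depth", depth_res), ("evenness", even_res)]:
        tab = explained_variation_table(results)
        tab.insert(0, "outcome", outcome)
        rows.append(tab)
        for name, r in results.items():
            if r.kind == "tree":
                for var, score in r.importance.items():
                    imp_rows.append({"outcome": outcome, "model": name,
                                     "variable": var, "importance": score})
    expl = pd.concat(rows, ignore_index=True)
    imp = pd.DataFrame(imp_rows)
    RESULTS.mkdir(exist_ok=True)
    write_results_table(expl, RESULTS / "explained_variation.tsv", seed=seed)
    write_results_table(imp, RESULTS / "tree_importance.tsv", seed=seed)
    print(expl.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print("\ntop tree importances (with covariates):")
    top = (imp[imp.model == "tree_with_covariates"]
           .sort_values(["outcome", "importance"], ascending=[True, False])
           .groupby("outcome").head(2))
    print(top.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"wrote model tables to {RESULTS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
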