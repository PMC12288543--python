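"""Cohort dispersion of WRSD counts and E-scores (the depth/evenness
variability summary), with far-out outlier screening.

Writes results/dispersion.tsv with n, Na, outlier counts, min-max, quartiles,
median, mean and sd per variable.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import DEFAULT_SEED, RESULTS, build_cohort  # noqa: E402

from plastcov.genome_io import write_results_table  # noqa: E402
from plastcov.pipeline import run_coverage  # noqa: E402


def main(seed: int = DEFAULT_SEED) -> None:
    per_sample, windows, _ = build_cohort(seed)
    out = run_coverage(per_sample)
    disp = out["dispersion"]
    RESULTS.mkdir(exist_ok=True)
    write_results_table(disp, RESULTS / "dispersion.tsv", seed=seed)
    e_row = disp.set_index("variable").loc["e_score"]
    print(disp.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nE-score: mean {e_row['mean']:.2f}, "
          f"IQR {e_row['q1']:.2f}-{e_row['q3']:.2f}, "
          f"{int(e_row['outliers'])} lower-fence outliers")
    print(f"wrote {RESULTS / 'dispersion.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
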