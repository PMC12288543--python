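"""Assembly-quality metrics and their ladder standardization.

Writes results/quality.tsv: per-sample ambiguity and IR-mismatch counts with
[0,1] quality scores (1 = high quality) and the chosen power exponents.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import DEFAULT_SEED, RESULTS, build_cohort  # noqa: E402

from plastcov.genome_io import write_results_table  # noqa: E402
from plastcov.quality import tukey_ladder_standardize  # noqa: E402


def main(seed: int = DEFAULT_SEED) -> None:
    per_sample, _, _ = build_cohort(seed)
    amb = per_sample["n_ambiguous"].to_numpy(dtype=float)
    irm = pd.to_numeric(per_sample["ir_mismatches"], errors="coerce"
                        ).to_numpy(dtype=float)
    q_amb, lam_amb = tukey_ladder_standardize(amb)
    q_ir, lam_ir = tukey_ladder_standardize(irm)
    tab = per_sample[["sample_id", "n_ambiguous", "ir_mismatches"]].copy()
    tab["q_ambiguous"] = q_amb
    tab["q_irmm"] = q_ir
    tab["lambda_ambiguous"] = lam_amb
    tab["lambda_irmm"] = lam_ir
    RESULTS.mkdir(exist_ok=True)
    write_results_table(tab, RESULTS / "quality.tsv", seed=seed)
    print(f"ambiguous nucleotides: range {int(np.nanmin(amb))}-"
          f"{int(np.nanmax(amb))}, median {np.nanmedian(amb):.0f}; "
          f"ladder lambda = {lam_amb:g}")
    print(f"IR mismatches: range {int(np.nanmin(irm))}-{int(np.nanmax(irm))}, "
          f"median {np.nanmedian(irm):.0f}; ladder lambda = {lam_ir:g}")
    print(f"wrote {RESULTS / 'quality.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
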