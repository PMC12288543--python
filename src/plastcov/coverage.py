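"""Windowed sequencing-depth statistics and the coverage-evenness E-score.

Depth is summarized in fixed-size windows (default 250 bp) tiled independently
within each of the four structural partitions.  A window whose mean depth lies
more than one standard deviation below the plastome-wide window average is a
"window with reduced sequencing depth" (WRSD); WRSD counts are reported per
partition and per coding status, normalized per 1000 bp of cumulative length.

Evenness is the Oexle E-score: with ``D`` the per-base depths, ``C`` the
per-base mean rounded to the nearest integer (half-to-even) and
``D2 = {d in D : d <= C}``,

    E = 1 - (|D2| - sum(D2)/C) / |D|

i.e. one minus the fraction of reads that would need redistribution from
above-average to below-average sections to equalize coverage.  E ranges from
0 (maximally uneven) to 1 (perfectly even).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PARTITION_NAMES, CoverageProfile, PlastomeRecord

WINDOW_COLUMNS = ["window_id", "partition", "start", "end", "length",
                  "mean_depth", "coding", "wrsd"]


@dataclass
class WindowTable:
    """Per-window depth table plus the plastome-wide window mean/sd summary."""

    sample_id: str
    windows: pd.DataFrame  # columns WINDOW_COLUMNS
    mean_depth_all_windows: float
    sd_depth_all_windows: float

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class WRSDSummary:
    sample_id: str
    raw_counts: dict[str, int]          # keys LSC, IRb, SSC, IRa, coding, noncoding
    lengths: dict[str, int]             # cumulative lengths of the same categories
    normalized: dict[str, float]        # raw / length * 1000

    @property
    def total(self) -> int:
        return sum(self.raw_counts[p] for p in PARTITION_NAMES)


@dataclass
class EvennessResult:
    sample_id: str
    e_score: float
    mean_coverage_int: int
    outlier: bool = False


@dataclass
class Fences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    k: float


def tile_windows(profile: CoverageProfile, record: PlastomeRecord,
                 window_size: int = 250, statistic: str = "mean") -> WindowTable:
    """Tile fixed-size windows within each partition and summarize depth.

    Windows start at each partition's 5' boundary; a trailing partial window
    (>= 1 bp) is retained and weighted equally.  A window is ``coding`` iff
    strictly more than half of its bases overlap the union of gene intervals
    (introns included, strand-agnostic).  The summary mean and sd are computed
    across all windows with the sample (n-1) standard deviation.
    """
    if len(profile) != len(record):
        raise ValueError(
            f"profile length {len(profile)} != genome length {len(record)}")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown window statistic {statistic!r}")

    depths = np.asarray(profile.depths, dtype=float)
    gene_mask = record.gene_mask()
    circle = len(record)

    rows = []
    wid = 0
    for name in PARTITION_NAMES:
        iv = record.partition_map[name]
        pos = iv.positions(circle)  # 5'->3' order, handles origin wrap
        if len(pos) == 0:
            raise ValueError(f"zero-length partition {name}")
        for off in range(0, len(pos), window_size):
            wpos = pos[off:off + window_size]
            idx = wpos - 1
            wdepth = depths[idx]
            stat = float(np.mean(wdepth)) if statistic == "mean" else float(np.median(wdepth))
            coding = bool(gene_mask[idx].sum() * 2 > len(wpos))  # strict > 50%
            rows.append((wid, name, int(wpos[0]), int(wpos[-1]), len(wpos),
                         stat, coding, False))
            wid += 1

    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    mean_all = float(df["mean_depth"].mean())
    sd_all = float(df["mean_depth"].std(ddof=1)) if len(df) > 1 else 0.0
    return WindowTable(profile.sample_id, df, mean_all, sd_all)


def classify_wrsd(table: WindowTable) -> WindowTable:
    """Flag windows with mean depth strictly below (mean - sd) of all windows.

    Strict inequality keeps the degenerate constant-coverage case (sd = 0)
    free of flags.
    """
    threshold = table.mean_depth_all_windows - table.sd_depth_all_windows
    table.windows["wrsd"] = table.windows["mean_depth"] < threshold
    return table


def summarize_wrsd(table: WindowTable, record: PlastomeRecord) -> WRSDSummary:
    """Count WRSD windows by partition and coding status, normalized per kb."""
    df = table.windows
    circle = len(record)
    gene_mask = record.gene_mask()

    raw: dict[str, int] = {}
    lengths: dict[str, int] = {}
    for name in PARTITION_NAMES:
        raw[name] = int(df.loc[df["partition"] == name, "wrsd"].sum())
        lengths[name] = record.partition_map[name].length(circle)
    raw["coding"] = int(df.loc[df["coding"], "wrsd"].sum())
    raw["noncoding"] = int(df.loc[~df["coding"], "wrsd"].sum())
    lengths["coding"] = int(gene_mask.sum())
    lengths["noncoding"] = circle - lengths["coding"]

    normalized = {k: (raw[k] / lengths[k] * 1000.0) if lengths[k] > 0 else float("nan")
                  for k in raw}
    return WRSDSummary(table.sample_id, raw, lengths, normalized)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def e_score(profile: CoverageProfile,
            reference_coverage: int | None = None) -> EvennessResult:
    """Plastome-wide E-score from per-base depths (see module docstring).

    ``reference_coverage`` overrides the rounded mean C, allowing profiles to
    be compared at a common reference coverage (the score is otherwise not
    strictly comparable across profiles whose integer C differs).
    """
    d = np.asarray(profile.depths, dtype=float)
    c = (_round_half_even(float(d.mean())) if reference_coverage is None
         else int(reference_coverage))
    if c < 1:
        raise ValueError(
            f"coverage too low for E-score (rounded mean depth {c} < 1)")
    d2 = d[d <= c]
    e = 1.0 - (len(d2) - d2.sum() / c) / len(d)
    e = float(np.clip(round(e, 3), 0.0, 1.0))
    return EvennessResult(profile.sample_id, e, c)


def tukey_fences(values, k: float = 3.0, side: str = "both") -> tuple[Fences, np.ndarray]:
    """Tukey fences at quartile +/- k*IQR with an outlier mask.

    Quartiles use linear interpolation (numpy's default, R type 7).  With the
    default ``k = 3`` these are Tukey's "far out" fences.  ``side='lower'``
    masks only values below the lower fence (used for E-score outliers);
    ``side='both'`` masks values outside [lower, upper].
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if side not in ("both", "lower"):
        raise ValueError(f"side must be 'both' or 'lower', got {side!r}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    fences = Fences(float(q1), float(q3), float(iqr),
                    float(q1 - k * iqr), float(q3 + k * iqr), k)
    if side == "lower":
        mask = v < fences.lower
    else:
        mask = (v < fences.lower) | (v > fences.upper)
    return fences, mask
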