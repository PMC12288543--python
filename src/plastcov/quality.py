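"""Assembly-quality metrics for plastid genomes.

Two sequence-derived metrics: the number of ambiguous (non-ACGT IUPAC)
nucleotides, and the number of nucleotide mismatches between the two inverted
repeats, which are identical by biology and should be identical in a correct
assembly.  Both are standardized to a [0, 1] quality score (1 = high quality)
via Tukey's ladder of powers followed by min-max scaling and orientation flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import IUPAC_CODES, UNAMBIGUOUS, PlastomeRecord, reverse_complement

#: Tukey's ladder of candidate power exponents; 0 denotes log.
LADDER = (-2.0, -1.0, -0.5, 0.0, 1.0 / 3.0, 0.5, 1.0, 2.0)


@dataclass
class QualityMetrics:
    sample_id: str
    n_ambiguous: int
    ir_synteny_ok: bool | None
    ir_mismatches: int | None         # None when synteny fails / IRs unusable
    q_ambiguous: float | None = None  # filled by cohort-level standardization
    q_irmm: float | None = None
    lambda_ambiguous: float | None = None
    lambda_irmm: float | None = None


@dataclass
class SyntenyReport:
    ok: bool
    violating_genes: list[str]
    reason: str = ""


def count_ambiguous(sequence: str) -> int:
    """Number of IUPAC-ambiguity characters (anything outside A/C/G/T)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - IUPAC_CODES
    if bad:
        pos = next(i for i, ch in enumerate(seq, 1) if ch in bad)
        raise ValueError(f"non-IUPAC character {sequence[pos-1]!r} at position {pos}")
    return sum(1 for ch in seq if ch not in UNAMBIGUOUS)


def _genes_in_ir(record: PlastomeRecord, ir_name: str) -> list[tuple[str, int]]:
    """Genes overlapping an IR, as (name, 5'-most position within the IR)."""
    circle = len(record)
    iv = record.partition_map[ir_name]
    pos_order = {int(p): i for i, p in enumerate(iv.positions(circle))}
    hits = []
    for g in record.genes:
        offsets = [pos_order[p] for giv in g.intervals
                   for p in map(int, giv.positions(circle)) if p in pos_order]
        if offsets:
            hits.append((g.name, min(offsets)))
    hits.sort(key=lambda t: t[1])
    return hits


def ir_synteny_check(record: PlastomeRecord) -> tuple[bool, SyntenyReport]:
    """Verify gene content and mirrored gene order across the two IRs.

    True iff the multiset of gene names overlapping IRa equals that of IRb and
    the order along IRa is the reverse of the order along IRb (the IRs being
    reverse complements of each other).
    """
    genes_a = _genes_in_ir(record, "IRa")
    genes_b = _genes_in_ir(record, "IRb")
    if not genes_a and not genes_b:
        return False, SyntenyReport(False, [], "synteny-indeterminate: no genes in either IR")
    names_a = [n for n, _ in genes_a]
    names_b = [n for n, _ in genes_b]
    from collections import Counter
    ca, cb = Counter(names_a), Counter(names_b)
    if ca != cb:
        diff = sorted((ca - cb).keys() | (cb - ca).keys())
        return False, SyntenyReport(False, diff, "gene content differs between IRs")
    if names_a != names_b[::-1]:
        bad = [a for a, b in zip(names_a, names_b[::-1]) if a != b]
        return False, SyntenyReport(False, sorted(set(bad)), "gene order not mirrored")
    return True, SyntenyReport(True, [])


def ir_mismatches(record: PlastomeRecord, *, require_synteny: bool = True) -> int | None:
    """Nucleotide mismatches between IRa and the reverse complement of IRb.

    Equal lengths: Hamming distance.  Unequal lengths: unit-cost global edit
    distance (substitutions and indels each cost 1).  Returns None when the
    synteny check fails (the count would not be meaningful).
    """
    if require_synteny:
        ok, _ = ir_synteny_check(record)
        if not ok:
            return None
    a = record.extract(record.partition_map["IRa"]).upper()
    b = reverse_complement(record.extract(record.partition_map["IRb"]).upper())
    if len(a) == len(b):
        return int(sum(1 for x, y in zip(a, b) if x != y))
    return edit_distance(a, b)


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance, banded with iterative band doubling.

    The band starts just above ``|len(a) - len(b)|`` and doubles until the
    computed distance fits inside it, so near-identical IR copies cost
    O(n * d) rather than O(n^2).
    """
    if len(a) < len(b):
        a, b = b, a
    n, m = len(a), len(b)
    if m == 0:
        return n
    delta = n - m
    band = max(delta, 1)
    while True:
        d = _banded_levenshtein(a, b, band)
        if d is not None and d <= band:
            return d
        band *= 2
        if band > n + m:  # unconditional upper bound
            return _banded_levenshtein(a, b, n + m)


def _banded_levenshtein(a: str, b: str, band: int) -> int | None:
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    big = n + m + 1
    prev = np.full(m + 1, big, dtype=np.int64)
    width = band
    k = min(width, m)
    prev[: k + 1] = np.arange(k + 1)
    for i in range(1, n + 1):
        lo = max(0, i - width)
        hi = min(m, i + width)
        cur = np.full(m + 1, big, dtype=np.int64)
        if lo == 0:
            cur[0] = i
            lo = 1
        sub = prev[lo - 1:hi] + (aa[i - 1] != bb[lo - 1:hi])
        dele = prev[lo:hi + 1] + 1
        best = np.minimum(sub, dele)
        # insertion needs a left-to-right scan; do it with a loop-free trick:
        # cur[j] = min(best[j], cur[j-1] + 1) -- prefix-minimum of best[j] - j
        idx = np.arange(lo, hi + 1)
        run = np.minimum.accumulate(best - idx)
        left = cur[lo - 1] - (lo - 1)
        cur[lo:hi + 1] = idx + np.minimum(run, left + 0)
        cur[lo:hi + 1] = np.minimum(cur[lo:hi + 1], best)
        prev = cur
    d = int(prev[m])
    return d if d < big else None


def tukey_ladder_standardize(values) -> tuple[np.ndarray, float]:
    """Standardize a non-negative metric to [0, 1] quality scores.

    Values are shifted by +1 (both metrics are zero-inflated), transformed by
    the ladder power lambda maximizing the Shapiro-Wilk W of the transformed
    values, min-max scaled, and orientation-flipped so that 1 means high
    quality (small raw metric).  NaNs propagate.  Degenerate constant input:
    all zeros -> all 1.0 (nothing wrong anywhere); other constants -> 0.5 with
    a warning.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    x = v[finite]
    if len(x) < 4:
        raise ValueError("need at least 4 finite values")
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    out = np.full_like(v, np.nan)
    if np.ptp(x) == 0:
        fillv = 1.0 if x[0] == 0 else 0.5
        if x[0] != 0:
            warnings.warn("constant nonzero metric; quality scores set to 0.5")
        out[finite] = fillv
        return out, 1.0

    best_lam, best_w = 1.0, -np.inf
    for lam in LADDER:
        t = _ladder_transform(x, lam)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = float(sps.shapiro(t).statistic)
        except ValueError:
            continue
        if np.isfinite(w) and w > best_w:
            best_w, best_lam = w, lam
    t = _ladder_transform(x, best_lam)
    scaled = (t - t.min()) / (t.max() - t.min())
    out[finite] = 1.0 - scaled
    return out, best_lam


def _ladder_transform(x: np.ndarray, lam: float) -> np.ndarray:
    # +1 shift handles the zeros that dominate both metrics
    if lam == 0.0:
        return np.log(x + 1.0)
    return ((x + 1.0) ** lam - 1.0) / lam


def standardize_cohort(metrics: list[QualityMetrics]) -> list[QualityMetrics]:
    """Fill q_ambiguous / q_irmm across a cohort (NA propagated pairwise)."""
    amb = np.array([m.n_ambiguous for m in metrics], dtype=float)
    irm = np.array([np.nan if m.ir_mismatches is None else m.ir_mismatches
                    for m in metrics], dtype=float)
    q_amb, lam_amb = tukey_ladder_standardize(amb)
    q_ir, lam_ir = tukey_ladder_standardize(irm)
    for i, m in enumerate(metrics):
        m.q_ambiguous = float(q_amb[i]) if np.isfinite(q_amb[i]) else None
        m.q_irmm = float(q_ir[i]) if np.isfinite(q_ir[i]) else None
        m.lambda_ambiguous = lam_amb
        m.lambda_irmm = lam_ir
    return metrics


def compute_quality(record: PlastomeRecord) -> QualityMetrics:
    """Both raw metrics for one genome (standardization is cohort-level)."""
    n_amb = count_ambiguous(record.sequence)
    ok, _ = ir_synteny_check(record)
    mm = ir_mismatches(record, require_synteny=False) if ok else None
    return QualityMetrics(record.sample_id, n_amb, ok, mm)
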