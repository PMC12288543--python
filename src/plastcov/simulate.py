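"""Synthetic plastome cohorts with injected ground truth.

The generator emulates the data structure the analysis assumes: circular
quadripartite genomes whose inverted repeats are exact reverse complements by
construction (optionally perturbed), gene/intergenic structure mirrored into
both IRs, per-base depth with negative-binomial dispersion, a smooth GC-bias
multiplier and Poisson-placed low-coverage dips, platform-level effects on
evenness acting through the dip rate, and Yule trees carrying Brownian-motion
or white-noise traits.  Every injected perturbation is recorded in a
:class:`SyntheticTruth` sidecar so metric modules can be tested for exact
recovery.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .core import (
    CoverageProfile,
    GeneFeature,
    Interval,
    PartitionMap,
    PlastomeRecord,
    reverse_complement,
)
from .coverage import classify_wrsd, e_score, summarize_wrsd, tile_windows
from .physig import TraitVector, simulate_bm_trait
from .quality import compute_quality

#: canonical partition lengths of a ~154 kb plastome
DEFAULT_PARTITIONS = {"LSC": 85_000, "IRb": 25_500, "SSC": 18_000, "IRa": 25_500}


@dataclass
class SimConfig:
    """Stated world of the generator; defaults emulate an archived seed-plant
    plastome sequenced at moderate short-read depth."""

    partition_lengths: dict = field(default_factory=lambda: dict(DEFAULT_PARTITIONS))
    gc_content: float = 0.37          # typical plastome GC
    n_sc_genes: int = 70              # single-copy genes (LSC + SSC)
    n_ir_genes: int = 8               # genes mirrored into both IRs
    gene_length_mean: float = 900.0   # lognormal-ish gene lengths, bp
    mean_depth: float = 100.0         # reads capped at ~100x in practice
    dispersion: float = 30.0          # negative-binomial size; inf -> Poisson
    gc_bias_strength: float = 0.5     # 0 disables the GC multiplier
    dip_rate: float = 0.1             # expected dips per kb
    dip_depth_factor: float = 0.2     # multiplicative depth inside a dip
    dip_length: int = 250             # bp per dip window
    # sample-level heterogeneity: per-sample dip rates are Gamma around the
    # platform rate (shape below) and per-sample dispersion is lognormal
    # around `dispersion`; archived cohorts mix libraries and protocols, so
    # within-platform evenness spreads far beyond counting noise
    dip_rate_shape: float = 2.0
    dispersion_sigma: float = 0.5
    n_ambiguous_inject: int = 0
    ir_mismatch_subs: int = 0
    ir_mismatch_indels: int = 0
    # cohort-level zero-inflated quality defects (archived plastomes are
    # mostly clean; medians of both metrics are 0, tails are long)
    cohort_ambiguity_prob: float = 0.2
    cohort_ambiguity_mean: float = 30.0
    cohort_irmm_prob: float = 0.25
    cohort_irmm_mean: float = 8.0
    # across-sample variation in partition lengths (fractional sd); plastome
    # partition lengths differ across taxa, so length covariates are not
    # collinear with the partition factor
    partition_length_cv: float = 0.05
    platform_effects: dict = field(default_factory=lambda: {
        # platform -> mean dip rate per kb; platforms differ in evenness,
        # not depth.  Calibrated so the default cohort reproduces the
        # archived-cohort anchors (E-score ~0.90 on average, platform means
        # spanning ~0.88-0.92 with within-platform spread of similar size).
        "HiSeq 2000": 0.35, "HiSeq 2500": 0.05, "MiSeq": 0.15,
        "HiSeq 4000": 0.25, "NextSeq 500": 0.3, "GA II": 0.2,
    })
    tree_n_tips: int = 100
    trait_model: str = "bm"           # 'bm' | 'white'

    def validated(self) -> "SimConfig":
        if any(v < 0 for v in (self.dip_rate, self.gc_bias_strength,
                               self.n_ambiguous_inject, self.ir_mismatch_subs,
                               self.ir_mismatch_indels)):
            raise ValueError("rates and injection counts must be >= 0")
        return self


@dataclass
class SyntheticTruth:
    sample_id: str
    n_ambiguous: int = 0
    ir_mismatches: int = 0
    dip_windows: list = field(default_factory=list)   # 1-based (start, end)
    platform: str | None = None
    dip_rate: float | None = None
    trait_model: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _place_genes(rng: np.random.Generator, region_len: int, n_genes: int,
                 mean_len: float) -> list[tuple[int, int]]:
    """Non-overlapping (start, end) offsets (1-based within the region).

    Gene lengths are lognormal; an unlucky draw that exceeds the region is
    redrawn a few times before the demand is declared infeasible.
    """
    for _ in range(20):
        lengths = np.clip(rng.lognormal(np.log(mean_len), 0.5, n_genes),
                          60, None).astype(int)
        total = lengths.sum()
        slack = region_len - total
        if slack >= n_genes + 1:
            break
    else:
        raise ValueError(
            f"gene demand ({total} bp) exceeds region capacity ({region_len} bp)")
    gaps = rng.multinomial(slack - n_genes - 1, np.ones(n_genes + 1) / (n_genes + 1))
    out, pos = [], 1
    for i, ln in enumerate(lengths):
        pos += gaps[i] + 1
        out.append((pos, pos + ln - 1))
        pos += ln
    return out


def simulate_plastome(config: SimConfig, seed: int,
                      sample_id: str = "synth") -> tuple[PlastomeRecord, SyntheticTruth]:
    """One quadripartite genome with synteny-true mirrored IR genes and the
    requested ambiguity / IR perturbations injected."""
    config = config.validated()
    rng = np.random.default_rng(seed)
    pl = config.partition_lengths
    lsc = _random_seq(rng, pl["LSC"], config.gc_content)
    irb = _random_seq(rng, pl["IRb"], config.gc_content)
    ssc = _random_seq(rng, pl["SSC"], config.gc_content)

    truth = SyntheticTruth(sample_id)

    # IR perturbations are applied to IRb after mirroring into IRa, so the
    # injected counts are exactly what assembly_quality should recover.
    ira = np.array(list(reverse_complement("".join(irb))))
    if config.ir_mismatch_subs:
        pos = rng.choice(len(irb), size=config.ir_mismatch_subs, replace=False)
        for p in pos:
            alt = [b for b in "ACGT" if b != irb[p]]
            irb[p] = alt[rng.integers(3)]
        truth.ir_mismatches += int(config.ir_mismatch_subs)
    if config.ir_mismatch_indels:
        # one indel type per genome: mixed ins+del can cancel in length,
        # in which case the mismatch metric would be a Hamming distance
        irb_list = list(irb)
        insert = bool(rng.random() < 0.5)
        for _ in range(config.ir_mismatch_indels):
            p = int(rng.integers(10, len(irb_list) - 10))
            if insert:
                irb_list.insert(p, str(_BASES[rng.integers(4)]))
            else:
                del irb_list[p]
        irb = np.array(irb_list)
        truth.ir_mismatches += int(config.ir_mismatch_indels)

    # genes: split single-copy genes between LSC and SSC by length share
    n_lsc = int(round(config.n_sc_genes * pl["LSC"] / (pl["LSC"] + pl["SSC"])))
    n_ssc = config.n_sc_genes - n_lsc
    genes: list[GeneFeature] = []
    len_lsc, len_irb, len_ssc, len_ira = len(lsc), len(irb), len(ssc), len(ira)
    off_irb = len_lsc
    off_ssc = off_irb + len_irb
    off_ira = off_ssc + len_ssc
    for (s, e) in _place_genes(rng, len_lsc, n_lsc, config.gene_length_mean):
        genes.append(GeneFeature(f"lsc{s}", "+" if rng.random() < 0.5 else "-",
                                 (Interval(s, e),)))
    for (s, e) in _place_genes(rng, len_ssc, n_ssc, config.gene_length_mean):
        genes.append(GeneFeature(f"ssc{s}", "+" if rng.random() < 0.5 else "-",
                                 (Interval(off_ssc + s, off_ssc + e),)))
    ir_gene_len = min(config.gene_length_mean, len_irb / (2 * max(config.n_ir_genes, 1)))
    for i, (s, e) in enumerate(_place_genes(rng, min(len_irb, len_ira),
                                            config.n_ir_genes, ir_gene_len)):
        genes.append(GeneFeature(f"ir{i}", "+", (Interval(off_irb + s, off_irb + e),)))
        # mirrored copy in IRa: offsets reflected through the repeat
        ms, me = len_ira - e + 1, len_ira - s + 1
        genes.append(GeneFeature(f"ir{i}", "-", (Interval(off_ira + ms, off_ira + me),)))

    seq = np.concatenate([lsc, irb, ssc, ira])
    _block_junction_pairing(seq, off_irb, off_ssc, off_ira, rng)
    if config.n_ambiguous_inject:
        # inject into single-copy regions only, so IR mismatch truth is exact
        sc_pos = np.concatenate([np.arange(0, len_lsc),
                                 np.arange(off_ssc, off_ssc + len_ssc)])
        pos = rng.choice(sc_pos, size=config.n_ambiguous_inject, replace=False)
        seq[pos] = "N"
        truth.n_ambiguous = int(config.n_ambiguous_inject)

    pmap = PartitionMap(
        LSC=Interval(1, len_lsc),
        IRb=Interval(len_lsc + 1, off_ssc),
        SSC=Interval(off_ssc + 1, off_ira),
        IRa=Interval(off_ira + 1, len(seq)),
    )
    record = PlastomeRecord(sample_id, "".join(seq), pmap, genes)
    return record, truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _block_junction_pairing(seq: np.ndarray, off_irb: int, off_ssc: int,
                            off_ira: int, rng: np.random.Generator) -> None:
    """Mutate the single-copy bases flanking each IR junction so they never
    chance-pair under the repeat register: the annotated IRs are then exactly
    the maximal exact repeat, making boundary annotations an injected truth.
    """
    # outer junction: last LSC base vs first LSC base (circular partner)
    pairs = [(off_irb - 1, 0), (off_ssc, off_ira - 1)]
    for i, j in pairs:
        if i == j:
            continue
        while seq[i] == _COMP[str(seq[j])]:
            seq[i] = _BASES[rng.integers(4)]


def simulate_coverage(record: PlastomeRecord, config: SimConfig, seed: int,
                      truth: SyntheticTruth | None = None,
                      dip_rate: float | None = None
                      ) -> tuple[CoverageProfile, SyntheticTruth]:
    """Negative-binomial per-base depth with GC bias and low-coverage dips."""
    config = config.validated()
    if config.mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(record)
    truth = truth or SyntheticTruth(record.sample_id)
    rate = config.dip_rate if dip_rate is None else dip_rate
    truth.dip_rate = rate

    mu = np.full(L, float(config.mean_depth))
    if config.gc_bias_strength > 0:
        gc_local = _local_gc(record.sequence, window=200)
        mu *= np.exp(-config.gc_bias_strength * ((gc_local - 0.4) / 0.2) ** 2)

    n_dips = rng.poisson(rate * L / 1000.0)
    dips = []
    for _ in range(n_dips):
        s = int(rng.integers(1, max(L - config.dip_length, 1) + 1))
        e = min(s + config.dip_length - 1, L)
        mu[s - 1:e] *= config.dip_depth_factor
        dips.append((s, e))
    truth.dip_windows = dips

    if np.isfinite(config.dispersion) and config.dispersion < 1e6:
        r = config.dispersion
        depths = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9)))
    else:
        depths = rng.poisson(mu)
    return CoverageProfile(record.sample_id, depths.astype(np.int64)), truth


def _local_gc(sequence: str, window: int = 200) -> np.ndarray:
    isgc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    isgc = ((isgc == ord("G")) | (isgc == ord("C")) |
            (isgc == ord("g")) | (isgc == ord("c"))).astype(float)
    kernel = np.ones(window) / window
    # circular convolution: the genome is a circle
    padded = np.concatenate([isgc[-window:], isgc, isgc[:window]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[window:-window]


def simulate_dataset(n_samples: int, config: SimConfig, seed: int,
                     software_labels: tuple[str, ...] = ("Velvet", "CLC",
                                                         "SOAPdenovo", "YASRA"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame, list[SyntheticTruth]]:
    """A cohort: per-sample metric table, per-window WRSD table, truths.

    Platforms are assigned round-robin from ``config.platform_effects`` and
    act on evenness through their dip rate; software labels are assigned
    independently and carry no effect (the null the analysis should confirm).
    """
    config = config.validated()
    if len(config.platform_effects) < 2:
        raise ValueError("need >= 2 platform labels")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_samples)
    platforms = sorted(config.platform_effects)
    rng = np.random.default_rng(seed)

    rows, wrows, truths = [], [], []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        s1, s2 = child[i].spawn(2)
        seed1 = int(s1.generate_state(1)[0] % (2**31 - 1))
        seed2 = int(s2.generate_state(1)[0] % (2**31 - 1))
        jit = {
            name: max(500, int(round(length * rng.normal(
                1.0, config.partition_length_cv))))
            for name, length in config.partition_lengths.items()
        }
        jit["IRa"] = jit["IRb"]  # the IRs are identical in length by biology
        scfg = replace(
            config,
            partition_lengths=jit,
            n_ambiguous_inject=(int(rng.poisson(config.cohort_ambiguity_mean))
                                if rng.random() < config.cohort_ambiguity_prob
                                else 0),
            ir_mismatch_subs=(int(rng.poisson(config.cohort_irmm_mean))
                              if rng.random() < config.cohort_irmm_prob else 0),
        )
        record, truth = simulate_plastome(scfg, seed1, sample_id=sid)
        platform = platforms[i % len(platforms)]
        sample_rate = rng.gamma(config.dip_rate_shape,
                                config.platform_effects[platform]
                                / config.dip_rate_shape)
        sample_disp = float(np.exp(rng.normal(np.log(config.dispersion),
                                              config.dispersion_sigma))) \
            if np.isfinite(config.dispersion) else config.dispersion
        profile, truth = simulate_coverage(
            record, replace(scfg, dispersion=sample_disp), seed2, truth,
            dip_rate=float(sample_rate))
        truth.platform = platform
        truths.append(truth)

        table = classify_wrsd(tile_windows(profile, record))
        summary = summarize_wrsd(table, record)
        ev = e_score(profile)
        qual = compute_quality(record)
        software = software_labels[int(rng.integers(len(software_labels)))]
        row = {
            "sample_id": sid, "platform": platform, "software": software,
            "avg_read_length": float(rng.choice([100, 125, 150, 250, 300])),
            "e_score": ev.e_score,
            "n_ambiguous": qual.n_ambiguous,
            "ir_mismatches": qual.ir_mismatches,
            "coding_length": summary.lengths["coding"],
            "noncoding_length": summary.lengths["noncoding"],
        }
        for part in ("LSC", "IRb", "SSC", "IRa"):
            row[f"wrsd_{part}"] = summary.normalized[part]
            row[f"len_{part}"] = summary.lengths[part]
        row["wrsd_coding"] = summary.normalized["coding"]
        row["wrsd_noncoding"] = summary.normalized["noncoding"]
        rows.append(row)

        w = table.windows.copy()
        w.insert(0, "sample_id", sid)
        wrows.append(w)

    per_sample = pd.DataFrame(rows)
    windows = pd.concat(wrows, ignore_index=True)
    return per_sample, windows, truths


def simulate_tree_and_traits(n_tips: int, model: str = "bm", seed: int = 0,
                             ) -> tuple[dendropy.Tree, TraitVector]:
    """Yule (pure-birth) tree rescaled to depth 1 plus one trait.

    ``model='bm'``: Brownian motion from root 0 with sigma^2 = 1;
    ``model='white'``: i.i.d. standard-normal noise (no signal).
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    tree = yule_tree(n_tips, seed)
    if model == "bm":
        trait = simulate_bm_trait(tree, seed=seed + 1)
        trait.kind = "enforced_bm"
    elif model == "white":
        rng = np.random.default_rng(seed + 1)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        trait = TraitVector(pd.Series(rng.standard_normal(len(labels)),
                                      index=labels), kind="empirical")
    else:
        raise ValueError(f"unknown trait model {model!r}")
    return tree, trait


def yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree (unit birth rate) rescaled to unit root-to-tip depth.

    Simulated forward in time: starting from the root split (2 lineages),
    waiting times are exponential with rate k (k = current lineage count)
    and a uniformly chosen lineage splits; after the (n-1)-th split a final
    exponential(n) epoch with no split is appended, so no terminal branch
    has zero length.  The tree is ultrametric by construction.
    """
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    active: list[dendropy.Node] = []
    start: dict[int, float] = {}
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
        start[id(child)] = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - start[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
            start[id(child)] = t
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, node in enumerate(active):
        node.edge.length = t_end - start[id(node)]
        node.taxon = tns.new_taxon(label=f"T{i + 1}")
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= t_end
    return tree
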