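"""End-to-end analysis recipes over a dataset of plastomes + depth profiles.

The recipes mirror the analysis stages: coverage metrics and cohort
dispersion, the univariate test battery, multivariate models with and
without covariates, phylogenetic-signal contextualization, and the
assembler-comparison experiment.  Each stage is a plain function over
DataFrames so the numbered scripts under ``analysis/`` stay thin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import MISSING, CoverageProfile, PlastomeRecord
from .coverage import e_score, tukey_fences
from .genome_io import (
    read_depth_table,
    read_plastome,
    write_depth_table,
    write_plastome,
    write_results_table,
)
from .models import ModelResult, ModelSpec, fit_linear, fit_tree
from .physig import (
    CorrelogramResult,
    TraitVector,
    blomberg_K,
    correlogram,
    randomize_trait,
    simulate_bm_trait,
)
from .quality import tukey_ladder_standardize
from .stats import (
    enforce_min_group_size,
    groups_by_label,
    kruskal_wallis,
    label_effect,
    label_significance,
    levene_test,
    pairwise_wilcoxon,
    spearman_corr,
    wilcoxon_two_sample,
)

WRSD_VARIABLES = ["wrsd_LSC", "wrsd_IRb", "wrsd_SSC", "wrsd_IRa",
                  "wrsd_coding", "wrsd_noncoding"]


@dataclass
class RunConfig:
    window_size: int = 250
    fence_k: float = 3.0
    min_group: int = 5
    seed: int = 0
    n_classes: int = 30
    n_boot: int = 100
    n_perm: int = 999
    min_assembly_length: int = 100_000


# ---------------------------------------------------------------------------
# dataset directory

def write_dataset(outdir, records: list[PlastomeRecord],
                  profiles: list[CoverageProfile], metadata: pd.DataFrame,
                  tree: dendropy.Tree | None = None,
                  traits: pd.DataFrame | None = None,
                  truths: list | None = None, seed=None) -> None:
    """Write a dataset directory: per-sample FASTA/GFF3/BED/depth TSV plus
    metadata.tsv, tree.nwk, traits.tsv and truth.json sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, prof in zip(records, profiles):
        stem = out / rec.sample_id
        write_plastome(rec, f"{stem}.fasta", f"{stem}.gff3", f"{stem}.partitions.bed")
        write_depth_table(prof, f"{stem}.depth.tsv")
    write_results_table(metadata, out / "metadata.tsv", seed=seed)
    if tree is not None:
        tree.write(path=str(out / "tree.nwk"), schema="newick")
    if traits is not None:
        write_results_table(traits, out / "traits.tsv", seed=seed)
    if truths is not None:
        (out / "truth.json").write_text(
            json.dumps([json.loads(t.to_json()) for t in truths], indent=1))


def load_sample(directory, sample_id: str) -> tuple[PlastomeRecord, CoverageProfile]:
    stem = Path(directory) / sample_id
    rec = read_plastome(f"{stem}.fasta", gff3_path=f"{stem}.gff3",
                        partitions_bed=f"{stem}.partitions.bed",
                        sample_id=sample_id)
    prof = read_depth_table(f"{stem}.depth.tsv", expected_length=len(rec),
                            fill_missing=True, sample_id=sample_id)
    return rec, prof


# ---------------------------------------------------------------------------
# coverage stage

def run_coverage(per_sample: pd.DataFrame, config: RunConfig | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Cohort dispersion table plus per-variable outlier masks.

    WRSD variables are screened with two-sided far-out fences; the E-score
    with the lower far-out fence only (evenness can only be pathologically
    low).  Masked samples are excluded from downstream tests but stay in the
    per-sample table.
    """
    config = config or RunConfig()
    df = per_sample.copy()
    rows = []
    masks = pd.DataFrame(False, index=df.index,
                         columns=WRSD_VARIABLES + ["e_score"])
    for var in WRSD_VARIABLES + ["e_score", "n_ambiguous", "ir_mismatches"]:
        if var not in df.columns:
            continue
        v = pd.to_numeric(df[var], errors="coerce")
        n_na = int(v.isna().sum())
        vv = v.dropna()
        n_out = 0
        if var in WRSD_VARIABLES and len(vv) >= 4:
            _, m = tukey_fences(vv.to_numpy(), k=config.fence_k, side="both")
            masks.loc[vv.index[m], var] = True
            n_out = int(m.sum())
            vv = vv[~m]
        elif var == "e_score" and len(vv) >= 4:
            _, m = tukey_fences(vv.to_numpy(), k=config.fence_k, side="lower")
            masks.loc[vv.index[m], var] = True
            n_out = int(m.sum())
        rows.append({
            "variable": var, "n": len(vv), "Na": n_na, "outliers": n_out,
            "min": vv.min(), "max": vv.max(),
            "q1": vv.quantile(0.25), "q3": vv.quantile(0.75),
            "median": vv.median(), "mean": vv.mean(), "sd": vv.std(ddof=1),
        })
    return {"dispersion": pd.DataFrame(rows), "outlier_mask": masks}


def flag_escore_outliers(per_sample: pd.DataFrame, config: RunConfig | None = None
                         ) -> pd.Series:
    config = config or RunConfig()
    _, mask = tukey_fences(per_sample["e_score"].to_numpy(),
                           k=config.fence_k, side="lower")
    return pd.Series(mask, index=per_sample.index)


# ---------------------------------------------------------------------------
# univariate stage

def run_stats(per_sample: pd.DataFrame, windows: pd.DataFrame | None = None,
              config: RunConfig | None = None) -> dict:
    """The univariate battery: Kruskal-Wallis with eta-squared, pairwise
    Wilcoxon with BH adjustment, the single coding/non-coding Wilcoxon,
    Spearman correlations of the E-score with both quality scores, and
    Levene homoscedasticity checks."""
    config = config or RunConfig()
    df = per_sample.copy()
    cov = run_coverage(df, config)
    masks = cov["outlier_mask"]

    out: dict = {"dispersion": cov["dispersion"]}

    # -- WRSD across the structural quadripartition
    part_groups = {}
    for part in ("LSC", "IRb", "SSC", "IRa"):
        var = f"wrsd_{part}"
        v = pd.to_numeric(df[var], errors="coerce")
        v = v[~masks[var] & v.notna()]
        part_groups[part] = v.to_numpy()
    kw_part = kruskal_wallis(*part_groups.values())
    pw_part = pairwise_wilcoxon(part_groups)

    # -- coding vs non-coding (single test, not BH-adjusted)
    vx = pd.to_numeric(df["wrsd_coding"], errors="coerce")
    vy = pd.to_numeric(df["wrsd_noncoding"], errors="coerce")
    vx = vx[~masks["wrsd_coding"] & vx.notna()]
    vy = vy[~masks["wrsd_noncoding"] & vy.notna()]
    w_coding = wilcoxon_two_sample(vx.to_numpy(), vy.to_numpy())

    # -- evenness: outlier-screened E-scores
    e_keep = ~masks["e_score"]
    es = pd.to_numeric(df["e_score"], errors="coerce")

    # Spearman vs ladder-standardized quality scores
    q_amb, _ = tukey_ladder_standardize(df["n_ambiguous"].to_numpy(dtype=float))
    irm = pd.to_numeric(df["ir_mismatches"], errors="coerce").to_numpy(dtype=float)
    q_ir, _ = tukey_ladder_standardize(irm)
    sp_amb = _safe_spearman(es[e_keep].to_numpy(), q_amb[e_keep.to_numpy()])
    sp_ir = _safe_spearman(es[e_keep].to_numpy(), q_ir[e_keep.to_numpy()])

    # -- E-score by platform and by software (min-5 rule)
    kw_platform = _kw_by_label(es, df["platform"], e_keep, config)
    kw_software = _kw_by_label(es, df["software"], e_keep, config)

    omni = []
    for name, res, n in [
        ("WRSD/partition", kw_part, sum(len(g) for g in part_groups.values())),
        ("WRSD coding/non-coding", w_coding, len(vx) + len(vy)),
        ("E-score ~ q_ambiguous", sp_amb, sp_amb.n[0]),
        ("E-score ~ q_irmm", sp_ir, sp_ir.n[0]),
    ]:
        omni.append({"variable": name, "n": n, "statistic": res.statistic,
                     "p": res.p, "effect": res.effect,
                     "effect_kind": res.effect_kind,
                     "effect_label": res.effect_label,
                     "significance": res.significance_label})
    for name, kw in [("E-score/platform", kw_platform),
                     ("E-score/software", kw_software)]:
        if kw is not None:
            omni.append({"variable": name, "n": sum(kw["result"].n),
                         "statistic": kw["result"].statistic,
                         "p": kw["result"].p, "effect": kw["result"].effect,
                         "effect_kind": "eta2",
                         "effect_label": kw["result"].effect_label,
                         "significance": kw["result"].significance_label})

    # -- homoscedasticity
    lev_rows = [{"variable": "WRSD/partition",
                 "p": levene_test(*part_groups.values()).p}]
    if kw_platform is not None:
        lev_rows.append({"variable": "E-score/platform",
                         "p": levene_test(*kw_platform["groups"].values()).p})
    out.update({
        "omnibus": pd.DataFrame(omni),
        "pairwise_partition": pw_part,
        "pairwise_platform": (kw_platform or {}).get("pairwise"),
        "levene": pd.DataFrame(lev_rows),
        "kw_partition": kw_part, "w_coding": w_coding,
        "sp_ambiguous": sp_amb, "sp_irmm": sp_ir,
        "kw_platform": (kw_platform or {}).get("result"),
        "kw_software": (kw_software or {}).get("result"),
    })
    return out


def _safe_spearman(x, y):
    """Spearman, degrading to an NaN result when a metric has no variation
    (e.g. a defect-free cohort)."""
    from .stats import TestResult
    try:
        return spearman_corr(x, y)
    except ValueError:
        return TestResult("spearman", (len(x),), float("nan"), float("nan"),
                          float("nan"), "rs")


def _kw_by_label(values: pd.Series, labels: pd.Series, keep: pd.Series,
                 config: RunConfig) -> dict | None:
    try:
        filt = enforce_min_group_size(labels, min_n=config.min_group)
    except ValueError:
        return None
    v = values[keep]
    groups = groups_by_label(v.to_numpy(), filt[keep].to_numpy())
    groups = {k: g for k, g in groups.items() if len(g) >= 2}
    if len(groups) < 3:
        return None
    res = kruskal_wallis(*groups.values())
    pw = pairwise_wilcoxon(groups)
    return {"result": res, "groups": groups, "pairwise": pw}


# ---------------------------------------------------------------------------
# multivariate stage

def depth_model_table(windows: pd.DataFrame, per_sample: pd.DataFrame
                      ) -> pd.DataFrame:
    """Sample x partition x coding-status cells: normalized WRSD count per
    cell, with the covariates partition length and average read length."""
    rows = []
    meta = per_sample.set_index("sample_id")
    for (sid, part, coding), grp in windows.groupby(
            ["sample_id", "partition", "coding"]):
        cell_len = max(int(grp["length"].sum()), 1)
        n_wrsd = int(grp["wrsd"].sum())
        rows.append({
            "sample_id": sid, "partition": part,
            "coding_status": "coding" if coding else "noncoding",
            "wrsd_norm": n_wrsd / cell_len * 1000.0,
            "partition_length": meta.loc[sid, f"len_{part}"],
            "avg_read_length": meta.loc[sid, "avg_read_length"],
        })
    df = pd.DataFrame(rows)
    df["partition"] = df["partition"].astype(object)
    return df


def evenness_model_table(per_sample: pd.DataFrame,
                         config: RunConfig | None = None) -> pd.DataFrame:
    """Per-sample table for the evenness models: E-score outcome, platform +
    quality-score predictors, genome length and read length covariates."""
    config = config or RunConfig()
    df = per_sample.copy()
    q_amb, _ = tukey_ladder_standardize(df["n_ambiguous"].to_numpy(dtype=float))
    irm = pd.to_numeric(df["ir_mismatches"], errors="coerce").to_numpy(dtype=float)
    q_ir, _ = tukey_ladder_standardize(irm)
    df["q_ambiguous"], df["q_irmm"] = q_amb, q_ir
    df["genome_length"] = sum(df[f"len_{p}"] for p in ("LSC", "IRb", "SSC", "IRa"))
    try:
        df["platform"] = enforce_min_group_size(df["platform"],
                                                min_n=config.min_group)
    except ValueError:
        pass
    df = df[~flag_escore_outliers(df, config).to_numpy()]
    return df


def run_models(table: pd.DataFrame, outcome: str, predictors: list[str],
               covariates: list[str], seed: int = 0) -> dict[str, ModelResult]:
    """Linear + tree fits, each with and without the covariates."""
    out = {}
    for tag, cov in [("without_covariates", []), ("with_covariates", covariates)]:
        spec = ModelSpec(outcome, predictors, cov, seed=seed)
        out[f"linear_{tag}"] = fit_linear(table, spec)
        out[f"tree_{tag}"] = fit_tree(table, spec)
    return out


def explained_variation_table(results: dict[str, ModelResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append({"model": name,
                     "explained_pct": 100.0 * (r.r2_adj if r.kind == "linear"
                                               else r.r2_train)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phylogenetic-signal stage

def run_physignal(tree: dendropy.Tree, traits: dict[str, TraitVector],
                  config: RunConfig | None = None,
                  with_correlograms: bool = True) -> dict:
    """For each trait, indices and correlograms under the empirical,
    randomized, and enforced-Brownian-motion distributions."""
    config = config or RunConfig()
    tip_set = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    rows, correlograms = [], {}
    for tname, trait in traits.items():
        orphans = sorted(set(trait.values.index) - tip_set)
        if orphans:
            raise ValueError(f"trait {tname!r} has tips not in tree: {orphans}")
        variants = {
            "empirical": trait,
            "randomized": randomize_trait(trait, seed=config.seed + 1),
            "enforced_bm": simulate_bm_trait(tree, seed=config.seed + 2,
                                             match=trait),
        }
        for dist, tv in variants.items():
            idx = blomberg_K(tv, tree, n_perm=config.n_perm, seed=config.seed)
            rows.append({"trait": tname, "distribution": dist, "n": idx.n,
                         "I": idx.I, "p_I": idx.p_I,
                         "K": idx.K, "p_K": idx.p_K,
                         "K_star": idx.K_star, "p_K_star": idx.p_K_star})
            if with_correlograms:
                correlograms[(tname, dist)] = correlogram(
                    tv, tree, n_classes=config.n_classes,
                    n_boot=config.n_boot, seed=config.seed)
    return {"indices": pd.DataFrame(rows), "correlograms": correlograms}


# ---------------------------------------------------------------------------
# assembler comparison

def run_assembler_comparison(assemblies: list[tuple[str, str, int, CoverageProfile]],
                             config: RunConfig | None = None) -> dict:
    """E-score matrix across (sample, assembler) pairs.

    ``assemblies``: (sample_id, assembler, assembly_length, depth profile).
    Assemblies shorter than the completeness threshold (default 100 kb) are
    excluded.  Reports the per-sample E-score range (within-sample spread
    over assemblers) and the between-sample range of mean E-scores.
    """
    config = config or RunConfig()
    rows, excluded = [], []
    for sid, asm, length, prof in assemblies:
        if length < config.min_assembly_length:
            excluded.append({"sample_id": sid, "assembler": asm,
                             "length": length, "reason": "below length threshold"})
            continue
        rows.append({"sample_id": sid, "assembler": asm,
                     "e_score": e_score(prof).e_score})
    df = pd.DataFrame(rows)
    if df.empty:
        return {"matrix": df, "excluded": pd.DataFrame(excluded),
                "within_sample_range": pd.Series(dtype=float),
                "between_sample_range": float("nan")}
    mat = df.pivot(index="sample_id", columns="assembler", values="e_score")
    within = (mat.max(axis=1) - mat.min(axis=1)).rename("within_range")
    means = mat.mean(axis=1)
    between = float(means.max() - means.min())
    return {"matrix": mat, "excluded": pd.DataFrame(excluded),
            "within_sample_range": within, "between_sample_range": between}
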