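"""I/O layer: GenBank / FASTA+GFF3 / BED genome input, depth tables,
metadata harmonization, provenance-stamped TSV output, and IR boundary
polishing.

Internal coordinates are 1-based inclusive (GenBank convention); BED and
bedGraph are converted at the boundary (0-based half-open).  Origin-wrapping
intervals are stored as a single interval with ``end < start``.
"""

from __future__ import annotations

import hashlib
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    MISSING,
    PARTITION_NAMES,
    CoverageProfile,
    GeneFeature,
    Interval,
    PartitionError,
    PartitionMap,
    PlastomeRecord,
    SampleMetadata,
    reverse_complement,
)

logger = logging.getLogger("plastcov")

_PARTITION_ALIASES = {
    "lsc": "LSC", "irb": "IRb", "ssc": "SSC", "ira": "IRa",
    "ir_b": "IRb", "ir_a": "IRa", "inverted repeat b": "IRb",
    "inverted repeat a": "IRa",
}


def _norm_partition_name(raw: str) -> str | None:
    return _PARTITION_ALIASES.get(raw.strip().lower())


# ---------------------------------------------------------------------------
# coordinate conversions

def bed_to_interval(start0: int, end_excl: int) -> Interval:
    """BED 0-based half-open -> internal 1-based inclusive."""
    return Interval(start0 + 1, end_excl)


def interval_to_bed(iv: Interval) -> tuple[int, int]:
    if iv.wraps:
        raise ValueError("wrapping interval cannot be a single BED row")
    return iv.start - 1, iv.end


# ---------------------------------------------------------------------------
# genome input

def read_plastome(path, gff3_path=None, partitions_bed=None,
                  sample_id: str | None = None) -> PlastomeRecord:
    """Read a plastome from a GenBank flat file, or FASTA + GFF3 (+ BED).

    GenBank route: partitions are taken from ``repeat_region``/``misc_feature``
    features whose qualifiers name LSC/IRb/SSC/IRa.  FASTA route: gene
    features from the GFF3, partitions from a 4-row BED companion file.
    """
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank", ".gbff"):
        return _read_genbank(path, sample_id)
    if gff3_path is None or partitions_bed is None:
        raise ValueError("FASTA input requires gff3_path and partitions_bed")
    return _read_fasta_gff3(path, gff3_path, partitions_bed, sample_id)


def _read_genbank(path: Path, sample_id: str | None) -> PlastomeRecord:
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    parts: dict[str, Interval] = {}
    genes: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type in ("repeat_region", "misc_feature"):
            text = " ".join(feat.qualifiers.get("note", [])
                            + feat.qualifiers.get("standard_name", []))
            for token in re.split(r"[;,/\s]+", text):
                name = _norm_partition_name(token)
                if name:
                    parts[name] = Interval(int(feat.location.start) + 1,
                                           int(feat.location.end))
                    break
        elif feat.type == "gene":
            gname = (feat.qualifiers.get("gene") or feat.qualifiers.get("locus_tag")
                     or ["?"])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            ivs = tuple(sorted((Interval(int(p.start) + 1, int(p.end))
                                for p in feat.location.parts),
                               key=lambda iv: iv.start))
            genes.append(GeneFeature(gname, strand, ivs))
    missing = [p for p in PARTITION_NAMES if p not in parts]
    if missing:
        raise PartitionError(f"partition-incomplete: {', '.join(missing)}")
    pmap = PartitionMap(**parts)
    return PlastomeRecord(sample_id or rec.id, seq, pmap, genes)


def _read_fasta_gff3(fasta: Path, gff3: Path, bed: Path,
                     sample_id: str | None) -> PlastomeRecord:
    rec = SeqIO.read(str(fasta), "fasta")
    seq = str(rec.seq).upper()
    pmap = read_partitions_bed(bed, len(seq))
    genes = read_gff3_genes(gff3)
    return PlastomeRecord(sample_id or rec.id, seq, pmap, genes)


def read_gff3_genes(path) -> list[GeneFeature]:
    """Gene features (type ``gene``) from a GFF3 file, one interval per gene."""
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("ID") or "?"
            genes.append(GeneFeature(name, f[6] if f[6] in "+-" else "+",
                                     (Interval(int(f[3]), int(f[4])),)))
    return genes


def read_partitions_bed(path, genome_length: int) -> PartitionMap:
    """Quadripartite map from a BED file (0-based half-open).

    A partition split into two rows that abut the origin (one ending at L,
    one starting at 0) is merged into a single wrapping interval.
    """
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = _norm_partition_name(f[3])
            if name is None:
                continue
            rows.setdefault(name, []).append((int(f[1]), int(f[2])))
    missing = [p for p in PARTITION_NAMES if p not in rows]
    if missing:
        raise PartitionError(f"partition-incomplete: {', '.join(missing)}")
    parts: dict[str, Interval] = {}
    for name, runs in rows.items():
        if len(runs) == 1:
            parts[name] = bed_to_interval(*runs[0])
        elif len(runs) == 2:
            runs = sorted(runs)
            if runs[0][0] == 0 and runs[1][1] == genome_length:
                parts[name] = Interval(runs[1][0] + 1, runs[0][1])  # wraps origin
            else:
                raise PartitionError(f"partition {name} has disjoint non-origin runs")
        else:
            raise PartitionError(f"partition {name} has {len(runs)} BED rows")
    return PartitionMap(**parts)


def write_plastome(record: PlastomeRecord, fasta_path, gff3_path, bed_path) -> None:
    """Write FASTA + GFF3 genes + BED partition map (wrap -> two BED rows)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{record.sample_id}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i:i + 70] + "\n")
    L = len(record)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.sample_id} 1 {L}\n")
        for g in record.genes:
            for iv in g.intervals:
                fh.write(f"{record.sample_id}\tplastcov\tgene\t{iv.start}\t{iv.end}"
                         f"\t.\t{g.strand}\t.\tID={g.name};Name={g.name}\n")
    with open(bed_path, "w") as fh:
        for name in PARTITION_NAMES:
            for s, e in record.partition_map[name].runs(L):
                fh.write(f"{record.sample_id}\t{s - 1}\t{e}\t{name}\n")


# ---------------------------------------------------------------------------
# depth tables

def read_depth_table(path, expected_length: int, fill_missing: bool = False,
                     sample_id: str | None = None) -> CoverageProfile:
    """Per-base depth from a samtools-depth TSV (contig, 1-based pos, depth)
    or a bedGraph (contig, 0-based start, end, depth)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        contigs = df[0].unique()
        if len(contigs) > 1:
            raise ValueError(f"multiple contigs in depth table: {list(contigs)}")
        pos = df[1].to_numpy(dtype=np.int64)
        depth = df[2].to_numpy(dtype=np.int64)
        if (pos > expected_length).any() or (pos < 1).any():
            raise ValueError("position outside [1, expected_length]")
        depths = np.zeros(expected_length, dtype=np.int64)
        depths[pos - 1] = depth
        covered = np.zeros(expected_length, dtype=bool)
        covered[pos - 1] = True
    elif df.shape[1] == 4:
        contigs = df[0].unique()
        if len(contigs) > 1:
            raise ValueError(f"multiple contigs in bedGraph: {list(contigs)}")
        depths = np.zeros(expected_length, dtype=np.int64)
        covered = np.zeros(expected_length, dtype=bool)
        for _, row in df.iterrows():
            s, e, v = int(row[1]), int(row[2]), int(row[3])
            if e > expected_length or s < 0:
                raise ValueError("interval outside [0, expected_length)")
            depths[s:e] = v
            covered[s:e] = True
    else:
        raise ValueError(f"unrecognized depth table with {df.shape[1]} columns")
    if not covered.all() and not fill_missing:
        first = int(np.argmax(~covered)) + 1
        raise ValueError(f"position {first} absent from depth table "
                         "(pass fill_missing=True to zero-fill)")
    sid = sample_id or str(df[0].iloc[0])
    return CoverageProfile(sid, depths)


def write_depth_table(profile: CoverageProfile, path, contig: str | None = None) -> None:
    contig = contig or profile.sample_id
    with open(path, "w") as fh:
        for i, d in enumerate(profile.depths, 1):
            fh.write(f"{contig}\t{i}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# IR boundary polishing

@dataclass
class IRPolishReport:
    """Signed per-boundary shifts (bp): positive = outward extension,
    negative = inward contraction; None shifts mean polishing was refused."""
    shifts: dict[str, int] | None
    polished: bool
    reason: str = ""


def correct_ir_boundaries(record: PlastomeRecord) -> tuple[PlastomeRecord, IRPolishReport]:
    """Polish annotated IR boundaries against the maximal exact repeat.

    The reverse-complement pairing between the IRs maps IRb position ``p`` to
    IRa position ``S - p`` (circularly) for a fixed register ``S``.  The two
    annotated junctions each propose a register (outer: IRb start + IRa end;
    inner: IRb end + IRa start); these agree when the annotation is
    consistent and differ when one boundary is truncated or extended.  The
    better-matching register over the annotated span is chosen, then each
    junction is contracted inward past mismatching terminal base pairs and
    extended outward while flanking bases continue to pair exactly; the
    partner boundary follows through the register, so asymmetric truncations
    are recovered and the corrected IRs have equal length.  LSC/SSC are
    re-derived as the complementary arcs.

    If the annotated IRs are wholly dissimilar under both registers
    (mismatch fraction > 0.5 and no exact-match extension of >= 3 bp possible
    at either junction) the record is returned untouched with an
    "IR-unpolishable" warning; the polisher never invents annotations where
    none exist.
    """
    L = len(record)
    seq = record.sequence.upper()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def base(p: int) -> str:  # 1-based circular
        return seq[(p - 1) % L]

    def circ(p: int) -> int:
        return (p - 1) % L + 1

    irb = record.partition_map["IRb"]
    ira = record.partition_map["IRa"]
    bs, be = irb.start, irb.start + irb.length(L) - 1   # be may exceed L (unwrap)
    as_, ae = ira.start, ira.start + ira.length(L) - 1

    def paired(p: int, S: int) -> bool:
        return comp.get(base(p)) == base(S - p)

    def register_score(S: int) -> float:
        span = np.linspace(bs, be, num=min(irb.length(L), 1000)).astype(int)
        hits = sum(paired(int(p), S) for p in span)
        return hits / len(span)

    candidates = {bs + ae, be + as_}
    scored = sorted(((register_score(S), S) for S in candidates), reverse=True)
    score, S = scored[0]

    if score < 0.5:
        # wholly dissimilar unless a real (>= 3 bp) exact extension exists
        def can_extend(p0: int, step: int) -> bool:
            return all(paired(p0 + step * k, S) for k in (1, 2, 3))

        if not can_extend(bs, -1) and not can_extend(be, +1):
            warnings.warn(f"IR-unpolishable for {record.sample_id}: "
                          f"mismatch fraction {1 - score:.2f}")
            return record, IRPolishReport(None, False, "IR-unpolishable")

    shifts = {"irb_start": 0, "irb_end": 0, "ira_start": 0, "ira_end": 0}
    max_steps = L // 2
    min_len = 4

    # outer junction: move bs (partner ae = S - bs follows)
    steps = 0
    while not paired(bs, S) and (be - bs + 1) > min_len and steps < max_steps:
        bs += 1
        steps += 1
    steps = 0
    while paired(bs - 1, S) and steps < max_steps:
        if not _gap_ok(bs - 1, S, be, L):
            break  # would close the single-copy gap
        bs -= 1
        steps += 1

    # inner junction: move be (partner as = S - be follows)
    steps = 0
    while not paired(be, S) and (be - bs + 1) > min_len and steps < max_steps:
        be -= 1
        steps += 1
    steps = 0
    while paired(be + 1, S) and steps < max_steps:
        if not _gap_ok2(be + 1, S, bs, L):
            break
        be += 1
        steps += 1

    new_bs, new_be = circ(bs), circ(be)
    new_as, new_ae = circ(S - be), circ(S - bs)
    shifts["irb_start"] = _circ_diff(irb.start, new_bs, L)
    shifts["irb_end"] = -_circ_diff(irb.start + irb.length(L) - 1, be, L)
    shifts["ira_start"] = _circ_diff(ira.start, S - be, L)
    shifts["ira_end"] = -_circ_diff(ira.start + ira.length(L) - 1, S - bs, L)

    new_irb = Interval(new_bs, new_be)
    new_ira = Interval(new_as, new_ae)
    new_map = _rebuild_partition_map(record.partition_map, new_irb, new_ira, L)
    polished = PlastomeRecord(record.sample_id, record.sequence, new_map,
                              record.genes)
    return polished, IRPolishReport(shifts, True)


def _gap_ok(p: int, S: int, be: int, L: int) -> bool:
    """After claiming IRb position p (outer extension), at least 1 bp must
    remain in the single-copy arc between IRa's end (S - p) and p."""
    gap = (p - (S - p)) % L
    return gap > 2 and (be - p + 1) < L // 2


def _gap_ok2(p: int, S: int, bs: int, L: int) -> bool:
    gap = ((S - p) - p) % L
    return gap > 2 and (p - bs + 1) < L // 2


def _circ_diff(old: int, new: int, L: int) -> int:
    """Outward-positive boundary shift old -> new on the circle (bounded by
    L/2 to resolve direction)."""
    d = (old - new) % L
    if d > L // 2:
        d -= L
    return d


def _rebuild_partition_map(old: PartitionMap, irb: Interval, ira: Interval,
                           L: int) -> PartitionMap:
    """Re-derive the single-copy arcs between the polished IRs, keeping the
    original LSC/SSC identities (by overlap with the old arcs, falling back to
    longer-arc-is-LSC)."""
    def nxt(p):
        return p % L + 1

    def prv(p):
        return (p - 2) % L + 1

    arc1 = Interval(nxt(ira.end), prv(irb.start))   # old-LSC side in canonical order
    arc2 = Interval(nxt(irb.end), prv(ira.start))
    mid1 = _arc_midpoint(arc1, L)
    if old.LSC.contains(mid1, L):
        lsc, ssc = arc1, arc2
    elif old.SSC.contains(mid1, L):
        lsc, ssc = arc2, arc1
    else:
        lsc, ssc = ((arc1, arc2) if arc1.length(L) >= arc2.length(L)
                    else (arc2, arc1))
    return PartitionMap(LSC=lsc, IRb=irb, SSC=ssc, IRa=ira)


def _arc_midpoint(iv: Interval, L: int) -> int:
    return int(iv.positions(L)[iv.length(L) // 2])


# ---------------------------------------------------------------------------
# metadata

def _load_synonyms() -> dict[str, str]:
    path = Path(__file__).parent / "data" / "label_synonyms.tsv"
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["raw"].str.lower(), df["harmonized"]))


def harmonize_label(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Case/whitespace/vendor-prefix normalization via the shipped synonym
    table; unknown labels pass through verbatim with a logged notice."""
    if synonyms is None:
        synonyms = _load_synonyms()
    label = re.sub(r"\s+", " ", str(raw).strip())
    if not label or label.lower() in ("na", "nan", "none", MISSING):
        return MISSING
    key = label.lower()
    key = re.sub(r"^illumina\s+", "", key)  # "The prefix 'Illumina' was omitted"
    if key in synonyms:
        return synonyms[key]
    logger.info("unrecognized metadata label passed through verbatim: %r", label)
    return label


def parse_metadata(tsv_path) -> list[SampleMetadata]:
    """Per-sample metadata TSV with header
    sample_id, platform, software, avg_read_length."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "platform", "software", "avg_read_length"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata TSV must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    syn = _load_synonyms()
    out = []
    for _, row in df.iterrows():
        arl_raw = row["avg_read_length"]
        if pd.isna(arl_raw) or str(arl_raw).strip() == "":
            arl = None
        else:
            arl = float(arl_raw)
            if arl <= 0:
                raise ValueError(f"avg_read_length must be positive, got {arl} "
                                 f"for sample {row['sample_id']}")
        out.append(SampleMetadata(
            sample_id=str(row["sample_id"]),
            platform=harmonize_label(row["platform"] if pd.notna(row["platform"]) else "", syn),
            software=harmonize_label(row["software"] if pd.notna(row["software"]) else "", syn),
            avg_read_length=arl,
        ))
    return out


# ---------------------------------------------------------------------------
# results tables with provenance

from . import __version__ as _version  # noqa: E402  (cycle-free: set in __init__)


def provenance_header(seed=None, config: dict | None = None) -> list[str]:
    cfg = repr(sorted((config or {}).items())).encode()
    h = hashlib.sha1(cfg).hexdigest()[:12]
    lines = [f"# plastcov {_version}", f"# config_hash {h}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_results_table(df: pd.DataFrame, path, seed=None,
                        config: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance comment lines; reals at 12 significant
    digits so a round trip reproduces them."""
    with open(path, "w") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
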