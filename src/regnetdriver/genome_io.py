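"""Coordinate model and readers/writers for the standard genomic formats.

All internal coordinates are 0-based half-open (BED convention). Inputs in
1-based conventions (VCF POS) are converted on read and reconverted on write,
so no other module ever handles more than one convention.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}
SV_TYPES = {"DEL", "DUP", "INS", "INV", "TRA"}


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("interval chromosome name is empty")
        if self.start < 0:
            raise InputError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise InputError(
                f"interval end {self.end} <= start {self.start} on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise InputError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any shared base under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between two intervals; 0 when they overlap or abut."""
        if self.chrom != other.chrom:
            raise InputError("distance between intervals on different chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with its span, strand-resolved TSS, and TF flag."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    is_tf: bool = False

    @property
    def tss(self) -> int:
        """Transcript start: interval.start on +, interval.end - 1 on -."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class ChromosomeMap:
    """Chromosome lengths with optional centromere positions defining p/q arms."""

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise InputError(f"chromosome {chrom} length {length} <= 0")
        for chrom, cen in self.centromeres.items():
            if chrom not in self.lengths:
                raise InputError(f"centromere for unknown chromosome {chrom}")
            if not 0 < cen < self.lengths[chrom]:
                raise InputError(
                    f"centromere {cen} not strictly inside chromosome {chrom}"
                )

    def arm(self, chrom: str, pos: int) -> tuple[int, int]:
        """Half-open span of the arm containing pos; whole chromosome if no
        centromere is recorded."""
        length = self.lengths[chrom]
        cen = self.centromeres.get(chrom)
        if cen is None:
            return 0, length
        return (0, cen) if pos < cen else (cen, length)


def normalize_chrom(name: str, add_prefix: bool = True) -> str:
    name = name.strip()
    if add_prefix and not name.startswith("chr"):
        return "chr" + name
    return name


# ---------------------------------------------------------------------------
# Interval index: vectorised overlap queries over a static interval set.
# Built on sorted starts + a running maximum of ends, so a query reduces to
# two searchsorted calls plus an end filter. Needed because the SV null model
# recomputes per-element overlaps inside the permutation loop.
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Static overlap index over one chromosome's intervals.

    Intervals are half-open. ``query(s, e)`` returns the indices (into the
    construction order) of all intervals overlapping [s, e).
    """

    def __init__(self, starts: Sequence[int], ends: Sequence[int]):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise InputError("starts/ends length mismatch")
        order = np.argsort(starts, kind="stable")
        self._starts = starts[order]
        self._ends = ends[order]
        self._order = order
        # widest interval bounds how far left of the query an overlapping
        # interval's start can lie
        self._max_len = int((ends - starts).max()) if starts.size else 0

    def query(self, start: int, end: int) -> np.ndarray:
        lo = np.searchsorted(self._starts, start - self._max_len, side="left")
        hi = np.searchsorted(self._starts, end, side="left")
        cand = slice(lo, hi)
        keep = self._ends[cand] > start
        return self._order[cand][keep]

    def query_many(
        self, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Bulk overlap query.

        Returns (query_idx, interval_idx) pairs for every overlap, suitable
        for one vectorised pass over thousands of shuffled SVs.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        lo = np.searchsorted(self._starts, starts - self._max_len, side="left")
        hi = np.searchsorted(self._starts, ends, side="left")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(starts.size), counts)
        # flatten the per-query candidate ranges
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        iidx = np.repeat(lo, counts) + offs
        keep = self._ends[iidx] > starts[qidx]
        return qidx[keep], self._order[iidx[keep]]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(
    path: str | os.PathLike,
    n_extra_cols: int = 0,
    chr_prefix: bool = True,
) -> list[tuple[GenomicInterval, tuple]]:
    """Read a BED file (3+ columns) into intervals plus auxiliary columns.

    Returns a list of (interval, extras) in file order; ``extras`` holds the
    first ``n_extra_cols`` columns after the third (name, score, ...). A
    6-column BED's strand is picked up when present.
    """
    out: list[tuple[GenomicInterval, tuple]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            try:
                iv = GenomicInterval(
                    normalize_chrom(fields[0], chr_prefix), start, end, strand
                )
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            extras = tuple(fields[3 : 3 + n_extra_cols])
            out.append((iv, extras))
    return out


def write_bed(
    path: str | os.PathLike,
    records: Iterable[tuple[GenomicInterval, tuple]],
) -> None:
    with open(path, "w") as fh:
        for iv, extras in records:
            cols = [iv.chrom, str(iv.start), str(iv.end), *map(str, extras)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models / TF lists
# ---------------------------------------------------------------------------


def read_gene_models(path: str | os.PathLike, tf_list: set[str] | None = None) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id, gene_name, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "gene_name", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"gene-model table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise InputError(f"duplicate gene_id values: {dups[:5]}")
    tf_list = tf_list or set()
    genes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(
            normalize_chrom(row.chrom), int(row.start), int(row.end), row.strand
        )
        genes.append(
            GeneModel(row.gene_id, row.gene_name, iv, is_tf=row.gene_id in tf_list)
        )
    return genes


def write_gene_models(path: str | os.PathLike, genes: Sequence[GeneModel]) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "gene_name": g.gene_name,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tf_list(path: str | os.PathLike) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Somatic variants
# ---------------------------------------------------------------------------


@dataclass
class VariantSet:
    """Per-sample somatic SNVs, 0-based positions, optional functional scores.

    ``df`` columns: sample, chrom, pos, ref, alt, and fs when scores are
    attached (NaN when a scorer must be applied downstream).
    """

    df: pd.DataFrame

    COLUMNS = ("sample", "chrom", "pos", "ref", "alt", "fs")

    def __post_init__(self) -> None:
        for col in ("sample", "chrom", "pos", "ref", "alt"):
            if col not in self.df.columns:
                raise InputError(f"variant table missing column {col}")
        if "fs" not in self.df.columns:
            self.df["fs"] = np.nan
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def has_scores(self) -> bool:
        return len(self.df) > 0 and self.df["fs"].notna().all()


def _finalize_variants(df: pd.DataFrame, source: str) -> VariantSet:
    if (df["sample"].isna() | (df["sample"].astype(str) == "")).any():
        raise InputError(f"{source}: variant record without a sample identifier")
    bad = ~df["ref"].str.fullmatch("[ACGT]+") | ~df["alt"].str.fullmatch("[ACGT]+")
    if bad.any():
        log.warning("%s: %d variants with non-ACGT alleles kept", source, int(bad.sum()))
    n0 = len(df)
    df = df.drop_duplicates(subset=["sample", "chrom", "pos", "alt"], keep="first")
    if len(df) < n0:
        log.info("%s: deduplicated %d repeated sample/pos/alt records", source, n0 - len(df))
    return VariantSet(df.reset_index(drop=True))


def read_variants(path: str | os.PathLike, chr_prefix: bool = True) -> VariantSet:
    """Read somatic SNVs from a TSV or a VCF (sample in the SAMPLE INFO key).

    VCF POS is 1-based and converted to the internal 0-based convention.
    """
    path = os.fspath(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_variants_vcf(path, chr_prefix)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: variant TSV missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(c, chr_prefix))
    df["pos"] = df["pos"].astype(np.int64)
    if "fs" in df.columns:
        df["fs"] = df["fs"].astype(float)
        if (df["fs"].dropna() < 0).any():
            raise InputError(f"{path}: negative functional-impact score")
    return _finalize_variants(df, path)


def _read_variants_vcf(path: str, chr_prefix: bool) -> VariantSet:
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            sample = rec.info.get("SAMPLE")
            if sample is None:
                raise InputError(f"{path}: VCF record at {rec.chrom}:{rec.pos} lacks SAMPLE INFO key")
            fs = rec.info.get("FS_SCORE")
            for alt in rec.alts or ():
                rows.append(
                    {
                        "sample": str(sample),
                        "chrom": normalize_chrom(rec.chrom, chr_prefix),
                        # pysam rec.start is already 0-based
                        "pos": rec.start,
                        "ref": rec.ref,
                        "alt": alt,
                        "fs": float(fs) if fs is not None else np.nan,
                    }
                )
    df = pd.DataFrame(rows, columns=list(VariantSet.COLUMNS))
    df["pos"] = df["pos"].astype(np.int64)
    return _finalize_variants(df, path)


def write_variants_tsv(path: str | os.PathLike, variants: VariantSet) -> None:
    variants.df.to_csv(path, sep="\t", index=False, columns=list(VariantSet.COLUMNS))


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------


@dataclass
class SVSet:
    """Per-sample SV events.

    ``df`` columns: sample, svtype, chrom1, start1, end1, chrom2, start2,
    end2, length. Intrachromosomal events carry length = span between
    breakpoints; translocations carry NaN.
    """

    df: pd.DataFrame

    COLUMNS = (
        "sample",
        "svtype",
        "chrom1",
        "start1",
        "end1",
        "chrom2",
        "start2",
        "end2",
        "length",
    )

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())


def read_sv_bedpe(path: str | os.PathLike, chr_prefix: bool = True) -> SVSet:
    """Read SVs from BEDPE-like TSV: chrom1,start1,end1,chrom2,start2,end2,sample,svtype."""
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "sample", "svtype"]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                         dtype={"chrom1": str, "chrom2": str, "sample": str, "svtype": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    if len(df) == 0:
        empty = pd.DataFrame(columns=list(SVSet.COLUMNS))
        return SVSet(empty)
    bad = set(df["svtype"]) - SV_TYPES
    if bad:
        raise InputError(
            f"{path}: unknown svtype(s) {sorted(bad)}; allowed: {sorted(SV_TYPES)}"
        )
    for c in ("chrom1", "chrom2"):
        df[c] = df[c].map(lambda v: normalize_chrom(v, chr_prefix))
    for c in ("start1", "end1", "start2", "end2"):
        df[c] = df[c].astype(np.int64)
    intra = df["chrom1"] == df["chrom2"]
    tra = df["svtype"] == "TRA"
    if ((~intra) & (~tra)).any():
        raise InputError(f"{path}: non-TRA event with breakpoints on two chromosomes")
    df["length"] = np.where(
        tra, np.nan, (df[["start2", "end2"]].min(axis=1) - df[["start1", "end1"]].min(axis=1)).abs()
    )
    return SVSet(df[list(SVSet.COLUMNS)])


def write_sv_bedpe(path: str | os.PathLike, svs: SVSet) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "sample", "svtype"]
    svs.df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def compute_beta(methylated: float, unmethylated: float) -> float:
    """Methylation fraction beta = M / (M + U)."""
    total = methylated + unmethylated
    if total <= 0:
        raise InputError("beta undefined: M + U <= 0")
    return methylated / total


def read_beta_matrix(path: str | os.PathLike, probe_locations: str | os.PathLike):
    """Read a probes x samples beta matrix plus a probe-location TSV.

    Probes without a location are dropped (count logged). Values must lie in
    [0, 1]; missing entries stay NaN and are excluded pairwise downstream.
    Returns a :class:`regnetdriver.methylation.MethylationAssay` without
    sample labels or probe classes (attach those separately).
    """
    from .methylation import MethylationAssay

    beta = pd.read_csv(path, sep="\t", index_col=0)
    vals = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise InputError(f"{path}: beta values outside [0, 1]")
    loc = pd.read_csv(probe_locations, sep="\t", dtype={"chrom": str})
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(loc.columns)
    if missing:
        raise InputError(f"{probe_locations}: missing columns {sorted(missing)}")
    loc = loc.set_index("probe_id")
    located = beta.index.intersection(loc.index)
    dropped = len(beta.index) - len(located)
    if dropped:
        log.info("%s: dropped %d probes lacking a location", path, dropped)
    beta = beta.loc[located]
    loc = loc.loc[located]
    locations = {
        p: GenomicInterval(normalize_chrom(str(r.chrom)), int(r.pos), int(r.pos) + 1)
        for p, r in loc.iterrows()
    }
    return MethylationAssay(beta=beta, locations=locations)


# ---------------------------------------------------------------------------
# Chromosome sizes / expression / labels
# ---------------------------------------------------------------------------


def read_chrom_sizes(
    path: str | os.PathLike, centromeres: str | os.PathLike | None = None
) -> ChromosomeMap:
    """2-column TSV (chrom, length); optional centromere BED (midpoint used)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            lengths[normalize_chrom(chrom)] = int(length)
    cen: dict[str, int] = {}
    if centromeres is not None:
        for iv, _ in read_bed(centromeres):
            cen[iv.chrom] = (iv.start + iv.end) // 2
    return ChromosomeMap(lengths, cen)


def write_chrom_sizes(path: str | os.PathLike, chrom_map: ChromosomeMap) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_map.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Generic TSV matrix: first column = row ids, header row = sample names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_labels(path: str | os.PathLike) -> pd.Series:
    """TSV with columns sample, label (tumor/normal)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "label"} <= set(df.columns):
        raise InputError(f"{path}: label table needs 'sample' and 'label' columns")
    bad = set(df["label"]) - {"tumor", "normal"}
    if bad:
        raise InputError(f"{path}: unknown labels {sorted(bad)}")
    return df.set_index("sample")["label"]
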