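"""Genome geometry: builds, centromere-aware bins and weighted-mean copy numbers.

Internal coordinates are 0-based half-open throughout. Copy-number values are
ploidy-normalised log2 ratios: the segment log2 ratio adjusted for sample
ploidy, so every gain or loss is relative to the sample's overall ploidy.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIN_COLUMNS = ["chrom", "start", "end", "arm", "bin_id"]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of a genome build with its centromere interval."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self):
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise ValueError(
                f"{self.name}: need 0 < cen_start < cen_end < length, got "
                f"({self.cen_start}, {self.cen_end}, {self.length})"
            )


@dataclass
class GenomeBuild:
    """Ordered collection of chromosomes with centromere annotations."""

    chromosomes: dict[str, Chromosome]

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome build must contain at least one chromosome")

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> Chromosome:
        return self.chromosomes[name]

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @classmethod
    def from_chromosomes(cls, chroms) -> "GenomeBuild":
        d: dict[str, Chromosome] = {}
        for c in chroms:
            if c.name in d:
                raise ValueError(f"duplicate chromosome name {c.name!r}")
            d[c.name] = c
        return cls(d)

    @classmethod
    def from_tsv(cls, path) -> "GenomeBuild":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        required = {"chromosome", "length", "cen_start", "cen_end"}
        if not required.issubset(df.columns):
            raise ValueError(f"genome build TSV needs columns {sorted(required)}")
        return cls.from_chromosomes(
            Chromosome(str(r.chromosome), int(r.length), int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(c.name, c.length, c.cen_start, c.cen_end) for c in self.chromosomes.values()],
            columns=["chromosome", "length", "cen_start", "cen_end"],
        ).to_csv(path, sep="\t", index=False)

    def arms(self) -> pd.DataFrame:
        """Arm intervals (p before, q after the centromere) as a table."""
        rows = []
        for c in self.chromosomes.values():
            rows.append((c.name, "p", 0, c.cen_start))
            rows.append((c.name, "q", c.cen_end, c.length))
        return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])


@dataclass
class SegmentedProfile:
    """One sample's segmented copy-number profile.

    `segments` has columns chrom, start, end, cn (0-based half-open; cn is the
    ploidy-normalised log2 ratio). Segments must not overlap within a
    chromosome.
    """

    sample_id: str
    segments: pd.DataFrame
    ploidy: float = 2.0

    def __post_init__(self):
        seg = self.segments
        missing = {"chrom", "start", "end", "cn"} - set(seg.columns)
        if missing:
            raise ValueError(f"segments missing columns {sorted(missing)}")
        if len(seg):
            if (seg["start"] >= seg["end"]).any():
                raise ValueError(f"{self.sample_id}: segment with start >= end")
            if not np.isfinite(seg["cn"]).all():
                raise ValueError(f"{self.sample_id}: non-finite segment copy number")
            for chrom, grp in seg.groupby("chrom", sort=False):
                g = grp.sort_values("start")
                if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                    raise ValueError(
                        f"overlapping segments in sample {self.sample_id!r} on {chrom}"
                    )
        self.segments = seg.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )


def _arm_of(start: int, end: int, chrom: Chromosome) -> str:
    if end <= chrom.cen_start:
        return "p"
    if start >= chrom.cen_end:
        return "q"
    return "cen"


def build_bins(build: GenomeBuild, bin_size: int, per_arm: bool = False) -> pd.DataFrame:
    """Centromere-aware genomic bins for every chromosome of a build.

    Default scheme tiles each chromosome from 0 in `bin_size` steps and inserts
    both centromere boundaries so no bin spans the two arms; the
    centromere-interior bin is retained (it is typically missing-valued
    downstream). With `per_arm=True` each arm is tiled from its own start
    instead.

    Returns a table with columns chrom, start, end, arm, bin_id, ordered by
    build order then position.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom in build.chromosomes.values():
        if per_arm:
            bounds = set()
            for a_start, a_end in ((0, chrom.cen_start), (chrom.cen_end, chrom.length)):
                bounds.update(range(a_start, a_end, bin_size))
                bounds.add(a_end)
            bounds.update((chrom.cen_start, chrom.cen_end))
        else:
            bounds = set(range(0, chrom.length, bin_size))
            bounds.update((chrom.length, chrom.cen_start, chrom.cen_end))
        ordered = sorted(bounds)
        for s, e in zip(ordered[:-1], ordered[1:]):
            rows.append((chrom.name, s, e, _arm_of(s, e, chrom)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
    df["bin_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return df


def gene_bins(genes: pd.DataFrame, build: GenomeBuild) -> pd.DataFrame:
    """Gene-centred bins: one bin per gene using its start/end as boundaries.

    `genes` needs columns chrom, start, end, name (BED order). Genes on
    chromosomes absent from the build raise; a gene overlapping the centromere
    is assigned to the arm holding the larger share of the gene.
    """
    rows = []
    for r in genes.itertuples():
        if r.chrom not in build:
            raise ValueError(f"gene {r.name!r} on unknown chromosome {r.chrom!r}")
        chrom = build[r.chrom]
        arm = _arm_of(r.start, r.end, chrom)
        if arm == "cen":
            p_part = max(0, min(r.end, chrom.cen_start) - r.start)
            q_part = max(0, r.end - max(r.start, chrom.cen_end))
            arm = "p" if p_part >= q_part else "q"
        rows.append((r.chrom, int(r.start), int(r.end), arm, str(r.name)))
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def read_gene_bed(path) -> pd.DataFrame:
    """Read a 4-column BED (chrom, start, end, name) of gene locations."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene BED needs at least 4 columns: chrom, start, end, name")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"]
    return df


def interval_copy_number(
    profile: SegmentedProfile, chrom: str, start: int, end: int
) -> tuple[float, float]:
    """Weighted-mean segment copy number over one interval.

    The weight of each segment is its overlap length with the interval;
    `covered_fraction` is total overlap divided by interval length. Returns
    (nan, 0.0) when nothing overlaps.
    """
    if start >= end:
        raise ValueError(f"malformed interval [{start}, {end})")
    seg = profile.segments
    seg = seg[seg["chrom"] == chrom]
    if not len(seg):
        return float("nan"), 0.0
    ov = np.minimum(seg["end"].to_numpy(), end) - np.maximum(seg["start"].to_numpy(), start)
    w = np.clip(ov, 0, None).astype(float)
    total = w.sum()
    if total == 0:
        return float("nan"), 0.0
    cn = float((w * seg["cn"].to_numpy()).sum() / total)
    return cn, float(total / (end - start))


@dataclass
class BinCopyMatrix:
    """Samples x bins weighted-mean copy numbers with coverage fractions.

    `cn` holds NaN exactly where `covered` is zero.
    """

    cn: pd.DataFrame
    covered: pd.DataFrame
    bins: pd.DataFrame = field(repr=False, default=None)

    @property
    def samples(self) -> list[str]:
        return list(self.cn.index)


def bin_copy_matrix(profiles, bins: pd.DataFrame, build: GenomeBuild | None = None) -> BinCopyMatrix:
    """Weighted-mean copy number of every (sample, bin) pair.

    Segments on chromosomes absent from the bin set (or the build, if given)
    are skipped with a logged count. Rows follow profile order, columns the
    bin-table order.
    """
    profiles = list(profiles)
    if not profiles or not len(bins):
        raise ValueError("need at least one profile and one bin")
    bin_chroms = set(bins["chrom"])
    known = bin_chroms if build is None else set(build.names)
    n_samples, n_bins = len(profiles), len(bins)
    cn = np.full((n_samples, n_bins), np.nan)
    cov = np.zeros((n_samples, n_bins))
    by_chrom = {c: g for c, g in bins.groupby("chrom", sort=False)}
    skipped = 0
    for i, prof in enumerate(profiles):
        for chrom, seg in prof.segments.groupby("chrom", sort=False):
            if chrom not in known:
                skipped += len(seg)
                continue
            if chrom not in by_chrom:
                continue
            b = by_chrom[chrom]
            s = seg["start"].to_numpy()[:, None]
            e = seg["end"].to_numpy()[:, None]
            v = seg["cn"].to_numpy()[:, None]
            bs = b["start"].to_numpy()[None, :]
            be = b["end"].to_numpy()[None, :]
            w = np.clip(np.minimum(e, be) - np.maximum(s, bs), 0, None).astype(float)
            tot = w.sum(axis=0)
            idx = b.index.to_numpy()
            pos = bins.index.get_indexer(idx)
            with np.errstate(invalid="ignore"):
                vals = (w * v).sum(axis=0) / tot
            cn[i, pos] = np.where(tot > 0, vals, np.nan)
            cov[i, pos] = tot / (be[0] - bs[0])
    if skipped:
        logger.warning("skipped %d segments on chromosomes absent from the bin set", skipped)
    sample_ids = [p.sample_id for p in profiles]
    cols = bins["bin_id"].tolist()
    return BinCopyMatrix(
        cn=pd.DataFrame(cn, index=sample_ids, columns=cols),
        covered=pd.DataFrame(cov, index=sample_ids, columns=cols),
        bins=bins.reset_index(drop=True),
    )


_SEG_ALIASES = {
    "sample": ("sample", "sample_id", "id"),
    "chrom": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start", "start_position"),
    "end": ("end", "loc.end", "end_position"),
    "cn": ("seg_cn", "value", "seg.mean", "segment_mean", "cn", "log2"),
}


def read_segments(source, dialect: str = "1-based-inclusive") -> list[SegmentedProfile]:
    """Read SEG-like tab-separated text into per-sample profiles.

    The default dialect treats coordinates as 1-based inclusive (the common SEG
    convention) and converts to internal 0-based half-open; pass
    ``dialect="0-based-half-open"`` for data already in internal convention.
    Exact duplicate rows are dropped with a warning; overlapping segments
    within a sample raise, naming the sample.
    """
    if dialect not in ("1-based-inclusive", "0-based-half-open"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str)
    cols = {}
    lowered = {c.lower(): c for c in df.columns}
    for canon, aliases in _SEG_ALIASES.items():
        for a in aliases:
            if a in lowered:
                cols[canon] = lowered[a]
                break
        else:
            raise ValueError(f"SEG input lacks a column for {canon!r} (tried {aliases})")
    df = df[[cols[k] for k in ("sample", "chrom", "start", "end", "cn")]].copy()
    df.columns = ["sample", "chrom", "start", "end", "cn"]
    for col in ("start", "end", "cn"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"non-numeric {col!r} value at line {line}")
        df[col] = converted
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning("dropped %d duplicate SEG rows", n_before - len(df))
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if dialect == "1-based-inclusive":
        df["start"] = df["start"] - 1
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        profiles.append(
            SegmentedProfile(sample_id=str(sample), segments=grp[["chrom", "start", "end", "cn"]])
        )
    return profiles


def write_segments(profiles, path, dialect: str = "1-based-inclusive") -> None:
    """Write profiles as SEG-like TSV (columns sample, chromosome, start, end, seg_cn)."""
    rows = []
    off = 1 if dialect == "1-based-inclusive" else 0
    for p in profiles:
        for r in p.segments.itertuples():
            rows.append((p.sample_id, r.chrom, r.start + off, r.end, r.cn))
    pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "seg_cn"]).to_csv(
        path, sep="\t", index=False
    )


def normalize_ploidy(profile: SegmentedProfile) -> SegmentedProfile:
    """Apply cn - log2(ploidy/2) when raw (non-ploidy-normalised) ratios were supplied."""
    seg = profile.segments.copy()
    seg["cn"] = seg["cn"] - np.log2(profile.ploidy / 2.0)
    return SegmentedProfile(profile.sample_id, seg, ploidy=2.0)
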