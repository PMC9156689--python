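"""Genomic annotation: feature loci, varied-segment definitions, cis/trans partitioning.

In a B-A translocation dosage series only a defined chromosomal segment is
varied.  Features (miRNA clusters or genes) whose locus overlaps that segment
are *cis*; everything else in the genome is *trans*.  Internal coordinates are
1-based inclusive (GFF convention); BED input is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "FeatureLocus",
    "SegmentDef",
    "GenotypeDesign",
    "read_loci",
    "read_segments",
    "read_genotype_designs",
    "write_loci_bed",
    "partition_cis_trans",
    "segment_length",
    "cis_count_size_correlation",
]

_FEATURE_CLASSES = {"mirna_cluster", "gene"}
_SEGMENT_KINDS = {"distal", "interstitial"}


@dataclass(frozen=True)
class FeatureLocus:
    """A genomic feature interval, 1-based inclusive."""

    feature_id: str
    chrom: str
    start: int
    end: int
    feature_class: str = "mirna_cluster"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.feature_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.feature_id}: end < start ({self.end} < {self.start})")
        if self.feature_class not in _FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")


@dataclass(frozen=True)
class SegmentDef:
    """The dosage-varied chromosomal segment of one translocation line.

    ``distal`` segments run from a breakpoint to the telomere (they exclude
    the centromere); ``interstitial`` segments may span it.
    """

    line_id: str
    chrom: str
    interval_start: int
    interval_end: int
    kind: str = "distal"

    def __post_init__(self) -> None:
        if self.interval_start >= self.interval_end:
            raise ValueError(
                f"{self.line_id}: interval_start must be < interval_end "
                f"({self.interval_start} >= {self.interval_end})"
            )
        if self.kind not in _SEGMENT_KINDS:
            raise ValueError(f"{self.line_id}: unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class GenotypeDesign:
    """Per-genotype karyotype: background ploidy, segment dosages, B-chromosome count.

    A segment not listed in ``segment_dosages`` is at background ploidy;
    genotypes with an empty map are euploid.
    """

    genotype_id: str
    background_ploidy: int
    segment_dosages: Mapping[str, int] = field(default_factory=dict)
    b_count: int = 0

    def __post_init__(self) -> None:
        if self.background_ploidy not in (1, 2, 3, 4):
            raise ValueError(f"{self.genotype_id}: background ploidy must be 1-4")
        if self.b_count < 0:
            raise ValueError(f"{self.genotype_id}: negative B count")
        for line, d in self.segment_dosages.items():
            if d < 0:
                raise ValueError(f"{self.genotype_id}: negative dosage for {line}")

    def dosage_of(self, line_id: str) -> int:
        """Copy number of a segment in this genotype (background ploidy if unvaried)."""
        return self.segment_dosages.get(line_id, self.background_ploidy)

    @property
    def is_euploid(self) -> bool:
        return not self.segment_dosages


def read_loci(path: str | Path, dialect: str | None = None) -> list[FeatureLocus]:
    """Read feature loci from BED (0-based half-open) or GFF3 (1-based inclusive).

    The dialect is inferred from the file suffix (.bed / .gff / .gff3) unless
    given explicitly.  Coordinates are normalised to the internal 1-based
    inclusive convention.  Duplicate feature ids are an error.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            dialect = "bed"
        elif suffix in (".gff", ".gff3"):
            dialect = "gff3"
        else:
            raise ValueError(f"cannot infer dialect from suffix {suffix!r}; pass dialect=")
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'bed' or 'gff3')")

    loci: list[FeatureLocus] = []
    seen: set[str] = set()
    malformed: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"\s+", line) if dialect == "bed" else line.split("\t")
            try:
                if dialect == "bed":
                    chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    fclass = fields[4] if len(fields) > 4 and fields[4] in _FEATURE_CLASSES else "mirna_cluster"
                    locus = FeatureLocus(name, chrom, start0 + 1, end0, fclass)
                else:
                    chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("ID") or attrs.get("Name")
                    if name is None:
                        raise ValueError("missing ID attribute")
                    ftype = fields[2]
                    fclass = "gene" if ftype == "gene" else "mirna_cluster"
                    locus = FeatureLocus(name, chrom, start, end, fclass)
            except (IndexError, ValueError) as exc:
                malformed.append(lineno)
                continue
            if locus.feature_id in seen:
                raise ValueError(f"duplicate feature_id {locus.feature_id!r} at line {lineno}")
            seen.add(locus.feature_id)
            loci.append(locus)
    if malformed:
        import warnings

        warnings.warn(f"{path.name}: skipped {len(malformed)} malformed rows: lines {malformed[:10]}")
    return loci


def write_loci_bed(loci: Iterable[FeatureLocus], path: str | Path) -> None:
    """Write loci as 5-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{loc.feature_id}\t{loc.feature_class}\n")


def read_segments(path: str | Path) -> list[SegmentDef]:
    """Read varied-segment definitions from a TSV with header
    line_id, chrom, interval_start, interval_end, kind."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "chrom": str})
    required = {"line_id", "chrom", "interval_start", "interval_end", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment file missing columns: {sorted(missing)}")
    dup = df["line_id"][df["line_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate line_id(s): {sorted(dup.unique())}")
    return [
        SegmentDef(r.line_id, r.chrom, int(r.interval_start), int(r.interval_end), r.kind)
        for r in df.itertuples()
    ]


def read_genotype_designs(path: str | Path) -> dict[str, GenotypeDesign]:
    """Read genotype designs from a TSV with header
    genotype_id, background_ploidy, b_count, segment_dosages.

    ``segment_dosages`` is '.' for euploids or 'line=dose' pairs joined by ','.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    designs: dict[str, GenotypeDesign] = {}
    for r in df.itertuples():
        if r.genotype_id in designs:
            raise ValueError(f"duplicate genotype_id {r.genotype_id!r}")
        dosages: dict[str, int] = {}
        if r.segment_dosages not in (".", "", None) and not pd.isna(r.segment_dosages):
            for pair in str(r.segment_dosages).split(","):
                line, dose = pair.split("=")
                dosages[line] = int(dose)
        designs[r.genotype_id] = GenotypeDesign(
            r.genotype_id, int(r.background_ploidy), dosages, int(r.b_count)
        )
    return designs


def write_genotype_designs(designs: Mapping[str, GenotypeDesign], path: str | Path) -> None:
    rows = []
    for g in designs.values():
        dos = ",".join(f"{k}={v}" for k, v in sorted(g.segment_dosages.items())) or "."
        rows.append((g.genotype_id, g.background_ploidy, g.b_count, dos))
    pd.DataFrame(rows, columns=["genotype_id", "background_ploidy", "b_count", "segment_dosages"]).to_csv(
        path, sep="\t", index=False
    )


def _overlaps(locus: FeatureLocus, seg: SegmentDef) -> bool:
    # any-overlap rule: >=1 bp shared, same chromosome
    return (
        locus.chrom == seg.chrom
        and locus.start <= seg.interval_end
        and locus.end >= seg.interval_start
    )


def partition_cis_trans(loci: Sequence[FeatureLocus], seg: SegmentDef) -> pd.DataFrame:
    """Label every locus cis or trans relative to one line's varied segment.

    A locus is *cis* iff it overlaps the segment interval by at least 1 bp on
    the same chromosome (breakpoint-straddling loci are cis, since part of
    their sequence has varied copy number); otherwise *trans*.  The partition
    is exhaustive and exclusive.
    """
    if not loci:
        raise ValueError("loci must be non-empty")
    rows = [
        (loc.feature_id, seg.line_id, "cis" if _overlaps(loc, seg) else "trans")
        for loc in loci
    ]
    return pd.DataFrame(rows, columns=["feature_id", "line_id", "label"])


def segment_length(seg: SegmentDef) -> int:
    """Segment length in bp (inclusive interval)."""
    return seg.interval_end - seg.interval_start + 1


def cis_count_size_correlation(
    cis_counts: Mapping[str, int], segments: Sequence[SegmentDef]
) -> tuple[float, float, int]:
    """Pearson correlation between per-line cis-feature counts and segment sizes.

    Returns (R, two-sided P, n lines).  Requires >= 3 lines.
    """
    segs = {s.line_id: s for s in segments}
    lines = [l for l in cis_counts if l in segs]
    if len(lines) < 3:
        raise ValueError(f"correlation undefined with {len(lines)} lines (need >= 3)")
    counts = [cis_counts[l] for l in lines]
    sizes = [segment_length(segs[l]) for l in lines]
    r, p = stats.pearsonr(counts, sizes)
    return float(r), float(p), len(lines)
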