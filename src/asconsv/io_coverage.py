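"""Alignment and coverage I/O for strand-specific RNA-seq.

Converts properly paired alignments into transcribed-strand fragments,
accumulates per-base per-strand read depth, and round-trips the depth
tracks through per-strand bedGraph files.

Coordinate conventions: everything in memory is 0-based half-open.
GFF3 on disk is 1-based inclusive; BED/bedGraph on disk is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
import pysam
from gffutils import feature as gff_feature

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: How the library protocol encodes the transcribed strand of a template.
#: "dutp": dUTP second-strand marking — the transcribed strand is the strand
#: mate 2 aligns to (mate 1 is antisense to the transcript). "reverse" is an
#: alias of the same convention; "forward" takes mate 1's strand instead.
STRAND_DIALECTS = ("dutp", "reverse", "forward")


class ReadFragment(NamedTuple):
    """One sequenced cDNA fragment (a properly paired template)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # transcribed strand, '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StrandedCoverage:
    """Per-base read depth on each strand of each chromosome.

    ``depth[chrom][strand]`` is an integer array of length
    ``chrom_sizes[chrom]``; ``total_mapped_bases`` is the sum of all depth
    values over both strands (equivalently, the summed length of the
    fragments the track was built from).
    """

    chrom_sizes: dict[str, int]
    depth: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    total_mapped_bases: int = 0

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if chrom not in self.depth:
                self.depth[chrom] = {
                    s: np.zeros(size, dtype=np.int64) for s in STRANDS
                }

    def track(self, chrom: str, strand: str) -> np.ndarray:
        return self.depth[chrom][strand]

    def validate(self) -> None:
        total = 0
        for chrom, size in self.chrom_sizes.items():
            for s in STRANDS:
                arr = self.depth[chrom][s]
                if len(arr) != size:
                    raise ValueError(
                        f"depth array length {len(arr)} != chromosome "
                        f"size {size} for {chrom}{s}"
                    )
                if (arr < 0).any():
                    raise ValueError(f"negative depth on {chrom}{s}")
                total += int(arr.sum())
        if total != self.total_mapped_bases:
            raise ValueError(
                f"total_mapped_bases {self.total_mapped_bases} != summed "
                f"depth {total}"
            )

    def merged_with(self, other: "StrandedCoverage") -> "StrandedCoverage":
        """Base-wise sum of two tracks over the same chromosomes."""
        if self.chrom_sizes != other.chrom_sizes:
            raise ValueError("cannot merge coverage over different genomes")
        out = StrandedCoverage(dict(self.chrom_sizes))
        for chrom in self.chrom_sizes:
            for s in STRANDS:
                out.depth[chrom][s] = self.depth[chrom][s] + other.depth[chrom][s]
        out.total_mapped_bases = self.total_mapped_bases + other.total_mapped_bases
        return out


@dataclass
class GenomeAnnotation:
    """ORF (and optional intron) annotation in internal coordinates.

    ``orfs``: DataFrame with columns id, chrom, strand, start, end, status
    (status in {"verified", "uncharacterized", "other"}).
    ``introns``: DataFrame with columns orf_id, chrom, start, end (may be
    empty).
    """

    orfs: pd.DataFrame
    introns: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["orf_id", "chrom", "start", "end"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.orfs):
            if self.orfs["id"].duplicated().any():
                dups = self.orfs.loc[self.orfs["id"].duplicated(), "id"].tolist()
                raise ValueError(f"duplicate ORF ids: {dups}")
            bad = self.orfs[self.orfs["start"] >= self.orfs["end"]]
            if len(bad):
                raise ValueError(f"invalid ORF intervals: {bad['id'].tolist()}")


def _fragment_strand(mate1_is_reverse: bool, dialect: str) -> str:
    """Transcribed strand of a template from mate 1's orientation (FR pairs)."""
    if dialect not in STRAND_DIALECTS:
        raise ValueError(
            f"unknown strand dialect {dialect!r}; expected one of {STRAND_DIALECTS}"
        )
    mate2_plus = mate1_is_reverse  # FR layout: mates on opposite strands
    if dialect in ("dutp", "reverse"):
        return "+" if mate2_plus else "-"
    return "-" if mate2_plus else "+"


def _passes_uniqueness(read: "pysam.AlignedSegment", policy: str, min_mapq: int) -> bool:
    if policy == "all":
        return True
    if policy != "unique":
        raise ValueError(f"unknown uniqueness policy {policy!r}")
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= min_mapq


def load_alignments(
    path: str | Path,
    strand_dialect: str = "dutp",
    uniqueness: str = "unique",
    min_mapq: int = 10,
) -> list[ReadFragment]:
    """Read paired-end alignments into transcribed-strand fragments.

    One fragment is produced per properly paired template, spanning the
    leftmost to rightmost aligned base of the pair. Templates failing the
    uniqueness policy (NH tag != 1 when present, else MAPQ < ``min_mapq``)
    are excluded; unpaired or non-primary records are skipped and counted.
    """
    if strand_dialect not in STRAND_DIALECTS:
        raise ValueError(
            f"unknown strand dialect {strand_dialect!r}; "
            f"expected one of {STRAND_DIALECTS}"
        )
    fragments: list[ReadFragment] = []
    n_unpaired = 0
    n_filtered = 0
    with pysam.AlignmentFile(str(path), require_index=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                n_unpaired += 1
                continue
            # process each template once, from its first-in-pair record
            if not read.is_read1:
                continue
            if not _passes_uniqueness(read, uniqueness, min_mapq):
                n_filtered += 1
                continue
            tlen = abs(read.template_length)
            if tlen == 0:
                n_unpaired += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            strand = _fragment_strand(read.is_reverse, strand_dialect)
            fragments.append(
                ReadFragment(read.reference_name, start, start + tlen, strand)
            )
    if n_unpaired:
        logger.info("skipped %d unpaired/improper records", n_unpaired)
    if n_filtered:
        logger.info("excluded %d non-unique templates", n_filtered)
    return fragments


def build_coverage(
    fragments: Iterable[ReadFragment], chrom_sizes: Mapping[str, int]
) -> StrandedCoverage:
    """Accumulate fragment intervals into per-strand per-base depth.

    Depth at base b on strand s is the number of strand-s fragments whose
    interval contains b; ``total_mapped_bases`` is the summed fragment
    length. A fragment outside its chromosome's bounds is fatal.
    """
    cov = StrandedCoverage(dict(chrom_sizes))
    # difference arrays, cumulative-summed once per track
    diffs: dict[tuple[str, str], np.ndarray] = {}
    total = 0
    for frag in fragments:
        if frag.chrom not in chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome: {frag}")
        size = chrom_sizes[frag.chrom]
        if frag.start < 0 or frag.end > size or frag.start >= frag.end:
            raise ValueError(f"fragment outside chromosome bounds: {frag}")
        key = (frag.chrom, frag.strand)
        if key not in diffs:
            diffs[key] = np.zeros(size + 1, dtype=np.int64)
        diffs[key][frag.start] += 1
        diffs[key][frag.end] -= 1
        total += frag.length
    for (chrom, strand), diff in diffs.items():
        cov.depth[chrom][strand] = np.cumsum(diff[:-1])
    cov.total_mapped_bases = total
    return cov


# ---------------------------------------------------------------------------
# bedGraph round-trip


def _track_from_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict:
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom not in tracks:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: interval out of bounds")
            if covered[chrom][start:end].any():
                raise ValueError(
                    f"{path}:{lineno}: overlapping intervals (ambiguous depth)"
                )
            covered[chrom][start:end] = True
            tracks[chrom][start:end] = int(float(value))
    return tracks


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    total_mapped_bases: int | None = None,
) -> StrandedCoverage:
    """Build StrandedCoverage from one bedGraph per strand.

    Bases not covered by any interval get depth 0. If ``total_mapped_bases``
    is not given it is taken as the sum of all depth values (exact when the
    tracks were produced by :func:`build_coverage`).
    """
    cov = StrandedCoverage(dict(chrom_sizes))
    for strand, path in (("+", plus_path), ("-", minus_path)):
        for chrom, arr in _track_from_bedgraph(path, chrom_sizes).items():
            cov.depth[chrom][strand] = arr
    if total_mapped_bases is None:
        total_mapped_bases = int(
            sum(
                cov.depth[c][s].sum()
                for c in chrom_sizes
                for s in STRANDS
            )
        )
    cov.total_mapped_bases = total_mapped_bases
    return cov


def write_bedgraph_pair(
    cov: StrandedCoverage, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Write one bedGraph file per strand (zero runs omitted)."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom in sorted(cov.chrom_sizes):
                arr = cov.depth[chrom][strand]
                if not len(arr):
                    continue
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = int(arr[s])
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# GFF3 annotation

_STATUS_MAP = {"verified": "verified", "uncharacterized": "uncharacterized"}

#: Feature types read as ORF records, checked in order.
ORF_FEATURE_TYPES = ("gene", "ORF", "CDS")


def load_annotation(
    gff_path: str | Path,
    status_attribute: str = "orf_classification",
    orf_types: tuple[str, ...] = ORF_FEATURE_TYPES,
) -> GenomeAnnotation:
    """Load ORFs (and introns) from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open. ORF status is read from ``status_attribute``
    (case-insensitively mapped to verified/uncharacterized); anything
    unrecognized or absent becomes status "other". Features of type
    "intron" are collected as intron records keyed by their Parent (or
    orf_id) attribute.
    """
    orf_rows = []
    intron_rows = []
    with open(gff_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            try:
                feat = gff_feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ValueError(f"{gff_path}:{lineno}: malformed GFF line: {exc}")
            if feat.start is None or feat.end is None or not feat.seqid:
                raise ValueError(f"{gff_path}:{lineno}: malformed GFF line")
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if feat.featuretype == "intron":
                parent = (
                    feat.attributes.get("Parent")
                    or feat.attributes.get("orf_id")
                    or [""]
                )[0]
                intron_rows.append((parent, feat.seqid, start, end))
            elif feat.featuretype in orf_types:
                ident = (feat.attributes.get("ID") or feat.attributes.get("Name"))
                if not ident:
                    raise ValueError(f"{gff_path}:{lineno}: ORF record without ID")
                raw_status = (feat.attributes.get(status_attribute) or [""])[0]
                status = _STATUS_MAP.get(raw_status.lower(), "other")
                orf_rows.append(
                    (ident[0], feat.seqid, feat.strand, start, end, status)
                )
    if not orf_rows:
        logger.warning("no ORF records found in %s", gff_path)
    orfs = pd.DataFrame(
        orf_rows, columns=["id", "chrom", "strand", "start", "end", "status"]
    )
    introns = pd.DataFrame(intron_rows, columns=["orf_id", "chrom", "start", "end"])
    return GenomeAnnotation(orfs=orfs, introns=introns)


def write_annotation_gff(ann: GenomeAnnotation, path: str | Path, source: str = "asconsv") -> None:
    """Write ORFs (and introns) back out as GFF3 (1-based inclusive)."""
    status_attr = {"verified": "Verified", "uncharacterized": "Uncharacterized"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.orfs.itertuples():
            status = status_attr.get(row.status, "other")
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.id};orf_classification={status}\n"
            )
        for row in ann.introns.itertuples():
            fh.write(
                f"{row.chrom}\t{source}\tintron\t{row.start + 1}\t{row.end}\t.\t"
                f".\t.\tParent={row.orf_id}\n"
            )
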