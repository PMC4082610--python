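"""BPKM quantification, ORF classification, sense-antisense pairing.

BPKM (bases per kilobase of gene model per million mapped bases) of a unit
is B / ((L/1000) * (T/1e6)) where B is the summed same-strand depth over
the unit, L the unit length and T the sample's total mapped bases.

A unit overlapping (>= 1 base, same orientation) a verified or
uncharacterized ORF is an ORF transcript (ORF-T); a unit with no such
overlap is an ncRNA; a unit whose only same-orientation ORF overlaps have
status "other" (dubious ORFs etc.) is classed "other". An ORF-T and an
ncRNA on opposite strands overlapping by >= 1 base form a sense-antisense
pair, the ncRNA being the antisense transcript.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import TranscriptUnit
from .io_coverage import GenomeAnnotation, StrandedCoverage

CONDITIONS = ("ML", "ES", "HS")

PAIR_COLUMNS = [
    "orf_t_id", "antisense_id", "chrom", "overlap_start", "overlap_end",
    "overlap_len", "sense_len", "primary",
]


def bpkm(cov: StrandedCoverage, unit: TranscriptUnit) -> float:
    """Expression of one unit in the sample the coverage came from."""
    if cov.total_mapped_bases <= 0:
        raise ValueError("total_mapped_bases must be positive")
    if unit.length <= 0:
        raise ValueError(f"zero-length unit {unit.id}")
    track = cov.track(unit.chrom, unit.strand)
    if unit.start < 0 or unit.end > len(track):
        raise ValueError(f"unit {unit.id} outside coverage bounds")
    b = float(track[unit.start:unit.end].sum())
    return b / ((unit.length / 1e3) * (cov.total_mapped_bases / 1e6))


def expression_table(
    units: Sequence[TranscriptUnit],
    coverages: Mapping[str, StrandedCoverage],
) -> pd.DataFrame:
    """BPKM of every unit in every sample (units x samples DataFrame)."""
    data = {
        sample: [bpkm(cov, u) for u in units]
        for sample, cov in coverages.items()
    }
    return pd.DataFrame(data, index=[u.id for u in units])


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def classify_units(
    units: Sequence[TranscriptUnit], annotation: GenomeAnnotation
) -> list[TranscriptUnit]:
    """Label each unit ORF-T / ncRNA / other against the ORF annotation.

    ORF-T units also record the id of the same-orientation ORF with the
    largest overlap.
    """
    orfs = annotation.orfs
    out = []
    for u in units:
        same = orfs[(orfs["chrom"] == u.chrom) & (orfs["strand"] == u.strand)]
        ov = np.minimum(same["end"], u.end) - np.maximum(same["start"], u.start)
        hits = same[ov > 0]
        coding = hits[hits["status"].isin(("verified", "uncharacterized"))]
        if len(coding):
            best = coding.loc[
                (
                    np.minimum(coding["end"], u.end)
                    - np.maximum(coding["start"], u.start)
                ).idxmax()
            ]
            out.append(replace(u, unit_class="ORF-T", orf_id=best["id"]))
        elif len(hits):
            out.append(replace(u, unit_class="other", orf_id=None))
        else:
            out.append(replace(u, unit_class="ncRNA", orf_id=None))
    return out


def pair_sense_antisense(units: Sequence[TranscriptUnit]) -> pd.DataFrame:
    """Couple every (ORF-T, ncRNA) duo on opposite strands overlapping >= 1 base.

    An ncRNA overlapping several ORF-Ts yields one pair per ORF-T; the
    maximal-overlap pair for each ncRNA is flagged primary (ties broken by
    ORF-T coordinate).
    """
    orf_ts = [u for u in units if u.unit_class == "ORF-T"]
    ncrnas = [u for u in units if u.unit_class == "ncRNA"]
    rows = []
    for nc in ncrnas:
        cands = []
        for s in orf_ts:
            if s.chrom != nc.chrom or s.strand == nc.strand:
                continue
            ov = _overlap(s.start, s.end, nc.start, nc.end)
            if ov >= 1:
                cands.append((s, ov))
        cands.sort(key=lambda t: (-t[1], t[0].start, t[0].id))
        for rank, (s, ov) in enumerate(cands):
            rows.append(
                (
                    s.id, nc.id, s.chrom,
                    max(s.start, nc.start), min(s.end, nc.end),
                    ov, s.length, rank == 0,
                )
            )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.sort_values(["chrom", "overlap_start", "orf_t_id"]).reset_index(
        drop=True
    )


def filter_expressed_all(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    samples: Sequence[str] | None = None,
    min_bpkm: float = 0.0,
) -> pd.DataFrame:
    """Keep pairs whose both members exceed ``min_bpkm`` in every sample.

    This is the "expressed in all conditions" working-set filter; it is
    idempotent. ``samples`` defaults to every column of ``table``.
    """
    if samples is None:
        samples = list(table.columns)
    missing = [s for s in samples if s not in table.columns]
    if missing:
        raise ValueError(f"missing sample columns: {missing}")
    if not len(pairs):
        return pairs.copy()
    sub = table.loc[:, list(samples)]
    expressed = (sub > min_bpkm).all(axis=1)

    def ok(uid: str) -> bool:
        return uid in expressed.index and bool(expressed.loc[uid])

    keep = pairs["orf_t_id"].map(ok) & pairs["antisense_id"].map(ok)
    return pairs[keep].reset_index(drop=True)


def intron_overlap_summary(
    pairs: pd.DataFrame,
    units: Sequence[TranscriptUnit],
    annotation: GenomeAnnotation,
    n_orfs_total: int | None = None,
) -> dict:
    """Relate sense-antisense pairing to intron-containing ORFs.

    Returns the number of intron-containing ORFs, how many of those form
    sense-antisense pairs, how many pairs have the antisense unit's
    strand-aware 5' start inside an intron of the paired ORF, and the
    genome-wide pairing frequency for comparison.
    """
    introns = annotation.introns
    if not len(introns):
        raise ValueError("no intron records in the annotation")
    units_by_id = {u.id: u for u in units}
    orf_by_unit = {
        u.id: u.orf_id for u in units if u.unit_class == "ORF-T" and u.orf_id
    }
    intron_orfs = set(introns["orf_id"])
    paired_orfs = {
        orf_by_unit[uid] for uid in pairs["orf_t_id"] if uid in orf_by_unit
    }
    paired_intron_orfs = intron_orfs & paired_orfs

    n_from_intron = 0
    for row in pairs.itertuples():
        orf = orf_by_unit.get(row.orf_t_id)
        if orf not in intron_orfs:
            continue
        anti = units_by_id[row.antisense_id]
        tss = anti.start if anti.strand == "+" else anti.end - 1
        sub = introns[introns["orf_id"] == orf]
        if ((sub["start"] <= tss) & (tss < sub["end"])).any():
            n_from_intron += 1

    if n_orfs_total is None:
        n_orfs_total = int(
            (annotation.orfs["status"].isin(("verified", "uncharacterized"))).sum()
        )
    all_paired = {v for v in orf_by_unit.values()} & {
        orf_by_unit[uid] for uid in pairs["orf_t_id"] if uid in orf_by_unit
    }
    return {
        "n_intron_orfs": len(intron_orfs),
        "n_intron_orfs_paired": len(paired_intron_orfs),
        "n_pairs_antisense_from_intron": n_from_intron,
        "genomewide_pair_frequency": (
            len(all_paired) / n_orfs_total if n_orfs_total else float("nan")
        ),
    }
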