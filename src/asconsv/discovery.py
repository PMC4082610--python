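"""Iterative transcript-unit calling from strand-specific read depth.

A transcript unit is called per chromosome per strand by a four-step
greedy procedure:

(i)   seed at the unmasked position of maximal depth, requiring depth >= a
      seed threshold (default 5);
(ii)  grow the interval one base at a time, alternating left/right; a
      direction stops once the mean depth of the current interval is at
      least ``edge_ratio`` (default 4) times the depth of the next unmasked
      position beyond that boundary (out-of-bounds or masked neighbours
      count as depth 0, so they always stop);
(iii) each stopped boundary is reassigned once to cover the full span of
      every same-strand fragment containing that boundary's stop position,
      clipped so the unit never enters previously called (masked) bases;
(iv)  the unit's bases are masked and the cycle repeats until no eligible
      seed remains.

Masking is strand-specific: a unit on '+' does not block calling on '-',
since sense/antisense overlap is precisely what the downstream analysis
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_coverage import STRANDS, ReadFragment, StrandedCoverage

UNIT_CLASSES = ("unassigned", "ORF-T", "ncRNA", "other")


@dataclass(frozen=True)
class TranscriptUnit:
    """A called transcript interval on one strand (0-based half-open)."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    peak_position: int
    mean_depth: float
    unit_class: str = "unassigned"
    orf_id: str | None = None  # best same-orientation ORF, set by classification

    @property
    def length(self) -> int:
        return self.end - self.start


class _FragmentIndex:
    """Same-strand fragments sorted by start, for boundary reassignment."""

    def __init__(self, fragments: Iterable[ReadFragment]):
        by_track: dict[tuple[str, str], list[ReadFragment]] = {}
        for f in fragments:
            by_track.setdefault((f.chrom, f.strand), []).append(f)
        self._starts: dict[tuple[str, str], np.ndarray] = {}
        self._ends: dict[tuple[str, str], np.ndarray] = {}
        self._maxlen: dict[tuple[str, str], int] = {}
        for key, frags in by_track.items():
            starts = np.array([f.start for f in frags])
            ends = np.array([f.end for f in frags])
            order = np.argsort(starts, kind="stable")
            self._starts[key] = starts[order]
            self._ends[key] = ends[order]
            self._maxlen[key] = int((ends - starts).max())

    def span_containing(
        self, chrom: str, strand: str, pos: int
    ) -> tuple[int, int] | None:
        """(min start, max end) over fragments containing base ``pos``."""
        key = (chrom, strand)
        if key not in self._starts:
            return None
        starts, ends = self._starts[key], self._ends[key]
        lo = np.searchsorted(starts, pos - self._maxlen[key], side="left")
        hi = np.searchsorted(starts, pos, side="right")
        sel = ends[lo:hi] > pos
        if not sel.any():
            return None
        return int(starts[lo:hi][sel].min()), int(ends[lo:hi][sel].max())


def _call_track(
    depth: np.ndarray,
    chrom: str,
    strand: str,
    frag_index: _FragmentIndex | None,
    min_seed_depth: int,
    edge_ratio: float,
) -> list[tuple[int, int, int, float]]:
    """Call (start, end, peak, mean_depth) tuples on one depth track."""
    n = len(depth)
    masked = np.zeros(n, dtype=bool)
    d = depth.astype(np.float64)
    out = []
    while True:
        avail = np.where(masked, -1.0, d)
        peak = int(np.argmax(avail))  # ties -> leftmost
        if avail[peak] < min_seed_depth:
            break
        start, end = peak, peak + 1
        total = d[peak]
        stopped = {"L": False, "R": False}

        def neighbour(side: str) -> float:
            if side == "L":
                p = start - 1
            else:
                p = end
            if p < 0 or p >= n or masked[p]:
                return 0.0
            return d[p]

        # alternate single-base steps, left first; recompute mean each step
        turn = "L"
        while not (stopped["L"] and stopped["R"]):
            side = turn
            turn = "R" if turn == "L" else "L"
            if stopped[side]:
                continue
            mean = total / (end - start)
            nb = neighbour(side)
            if mean >= edge_ratio * nb:
                stopped[side] = True
                continue
            if side == "L":
                start -= 1
                total += d[start]
            else:
                total += d[end]
                end += 1

        # (iii) one-pass boundary reassignment from fragment spans,
        # clipped to unmasked bases
        if frag_index is not None:
            left_span = frag_index.span_containing(chrom, strand, start)
            right_span = frag_index.span_containing(chrom, strand, end - 1)
            new_start, new_end = start, end
            if left_span is not None:
                new_start = min(new_start, left_span[0])
            if right_span is not None:
                new_end = max(new_end, right_span[1])
            while new_start < start and masked[new_start:start].any():
                new_start += 1
            while new_end > end and masked[end:new_end].any():
                new_end -= 1
            start, end = new_start, new_end

        masked[start:end] = True
        mean_depth = float(d[start:end].mean())
        out.append((start, end, peak, mean_depth))
    return out


def call_transcripts(
    cov: StrandedCoverage,
    fragments: Sequence[ReadFragment] | None = None,
    min_seed_depth: int = 5,
    edge_ratio: float = 4.0,
    min_length: int = 1,
    id_prefix: str = "TU",
) -> list[TranscriptUnit]:
    """Call transcript units on every strand of every chromosome.

    ``fragments`` drive the step-(iii) boundary reassignment; pass None to
    skip it (boundaries are then the step-(ii) intervals). Units shorter
    than ``min_length`` are masked but not reported. Returned units are
    sorted by (chrom, start, strand with '+' first) and numbered in that
    order.
    """
    if min_seed_depth <= 0 or edge_ratio <= 0 or min_length <= 0:
        raise ValueError("min_seed_depth, edge_ratio and min_length must be positive")
    frag_index = _FragmentIndex(fragments) if fragments else None
    units: list[TranscriptUnit] = []
    call_no = 0  # ids record call order (deeper units are called earlier)
    for chrom in sorted(cov.chrom_sizes):
        for strand in STRANDS:
            for start, end, peak, mean_depth in _call_track(
                cov.track(chrom, strand), chrom, strand, frag_index,
                min_seed_depth, edge_ratio,
            ):
                if end - start >= min_length:
                    call_no += 1
                    units.append(
                        TranscriptUnit(
                            id=f"{id_prefix}{call_no:05d}",
                            chrom=chrom, strand=strand, start=start, end=end,
                            peak_position=peak, mean_depth=mean_depth,
                        )
                    )
    units.sort(key=lambda u: (u.chrom, u.start, u.end, u.strand))
    return units


def assert_non_overlapping(units: Iterable[TranscriptUnit]) -> None:
    """Raise if two units on the same strand of the same chromosome overlap."""
    by_track: dict[tuple[str, str], list[TranscriptUnit]] = {}
    for u in units:
        by_track.setdefault((u.chrom, u.strand), []).append(u)
    for track_units in by_track.values():
        track_units.sort(key=lambda u: u.start)
        for a, b in zip(track_units, track_units[1:]):
            if b.start < a.end:
                raise AssertionError(f"overlapping units {a.id} and {b.id}")


# ---------------------------------------------------------------------------
# GFF3 round-trip for unit sets


def write_units(units: Iterable[TranscriptUnit], path: str | Path) -> None:
    """Write units as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in units:
            attrs = (
                f"ID={u.id};peak_position={u.peak_position};"
                f"mean_depth={u.mean_depth!r};unit_class={u.unit_class}"
            )
            if u.orf_id:
                attrs += f";orf_id={u.orf_id}"
            fh.write(
                f"{u.chrom}\tasconsv\ttranscript_unit\t{u.start + 1}\t{u.end}"
                f"\t.\t{u.strand}\t.\t{attrs}\n"
            )


def read_units(path: str | Path) -> list[TranscriptUnit]:
    units = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF line")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            units.append(
                TranscriptUnit(
                    id=attrs["ID"],
                    chrom=parts[0],
                    strand=parts[6],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    peak_position=int(attrs["peak_position"]),
                    mean_depth=float(attrs["mean_depth"]),
                    unit_class=attrs.get("unit_class", "unassigned"),
                    orf_id=attrs.get("orf_id"),
                )
            )
    return units
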