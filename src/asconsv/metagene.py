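"""Sense/antisense expression density over a canonical gene model.

Each gene is mapped onto a fixed 400-point profile: 100 upstream
single-base points, 200 equal gene-body intervals (per-interval mean of
per-base depth), and 100 downstream single-base points. Index 0 is always
the 5' (upstream) side; minus-strand genes are orientation-flipped.
Per-gene values are divided by a per-gene normalizer — by convention the
mean of the gene's sense and antisense BPKM — and profiles are averaged
element-wise across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_coverage import StrandedCoverage

N_BODY_BINS = 200
FLANK = 100
PROFILE_LEN = 2 * FLANK + N_BODY_BINS

_OPP = {"+": "-", "-": "+"}


@dataclass
class MetageneProfile:
    sense_density: np.ndarray  # length 400
    antisense_density: np.ndarray  # length 400
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.sense_density) != PROFILE_LEN or len(self.antisense_density) != PROFILE_LEN:
            raise ValueError(f"profile arrays must have length {PROFILE_LEN}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _flank_values(track: np.ndarray, start: int, end: int) -> np.ndarray:
    """Per-base depth over [start, end), zero-padded outside the chromosome."""
    out = np.zeros(end - start, dtype=float)
    lo, hi = max(start, 0), min(end, len(track))
    if lo < hi:
        out[lo - start:hi - start] = track[lo:hi]
    return out


def _body_bins(track: np.ndarray, start: int, end: int) -> np.ndarray:
    """Means of per-base depth over 200 equal intervals of [start, end)."""
    edges = start + np.floor(
        np.arange(N_BODY_BINS + 1) * (end - start) / N_BODY_BINS
    ).astype(int)
    body = track[start:end].astype(float)
    sums = np.add.reduceat(body, edges[:-1] - start)
    widths = np.diff(edges)
    return sums / widths


def gene_profile(
    cov: StrandedCoverage,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    norm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """400-point (sense, antisense) density arrays for one gene.

    ``norm`` is the per-gene normalizer (mean of the gene's sense and
    antisense BPKM); it must be positive. Genes shorter than 200 bases
    cannot be profiled.
    """
    if end - start < N_BODY_BINS:
        raise ValueError(
            f"gene body {end - start} bases is shorter than {N_BODY_BINS}"
        )
    if norm <= 0:
        raise ValueError("normalizer must be positive")
    profiles = []
    for which_strand in (strand, _OPP[strand]):
        track = cov.track(chrom, which_strand)
        up = _flank_values(track, start - FLANK, start)
        body = _body_bins(track, start, end)
        down = _flank_values(track, end, end + FLANK)
        prof = np.concatenate([up, body, down])
        if strand == "-":
            prof = prof[::-1]
        profiles.append(prof / norm)
    return profiles[0], profiles[1]


def mean_profile(
    profiles: Iterable[tuple[np.ndarray, np.ndarray]]
) -> MetageneProfile:
    """Element-wise mean of per-gene (sense, antisense) profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("mean_profile needs at least one gene profile")
    sense = np.mean([p[0] for p in profiles], axis=0)
    anti = np.mean([p[1] for p in profiles], axis=0)
    return MetageneProfile(sense, anti, n_genes=len(profiles))


def antisense_three_prime_bias(profile: MetageneProfile) -> float:
    """Ratio of mean antisense density in the 3' body half vs the 5' half.

    Body indices 100..299; 5' half is 100..199, 3' half 200..299. Values
    above 1 indicate the antisense signal concentrates toward gene 3' ends.
    """
    five = float(profile.antisense_density[FLANK:FLANK + N_BODY_BINS // 2].mean())
    three = float(
        profile.antisense_density[FLANK + N_BODY_BINS // 2:FLANK + N_BODY_BINS].mean()
    )
    if five == 0:
        return float("inf") if three > 0 else float("nan")
    return three / five


def profile_table(profile: MetageneProfile):
    """Long-form table (position class, index, sense, antisense)."""
    import pandas as pd

    classes = (["upstream"] * FLANK + ["body"] * N_BODY_BINS + ["downstream"] * FLANK)
    return pd.DataFrame(
        {
            "position_class": classes,
            "index": np.arange(PROFILE_LEN),
            "sense": profile.sense_density,
            "antisense": profile.antisense_density,
        }
    )
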