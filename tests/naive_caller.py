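"""Deliberately naive, literal re-implementation of the four-step caller.

Pure-Python lists and loops, written directly from the procedure's
description and kept independent of the package implementation. Used as
the equivalence oracle on small random tracks.
"""

from __future__ import annotations


def naive_call(
    depth: list[int],
    fragments: list[tuple[int, int]] | None = None,
    min_seed_depth: int = 5,
    edge_ratio: float = 4.0,
    min_length: int = 1,
) -> list[tuple[int, int]]:
    """Return (start, end) intervals, sorted by coordinate."""
    n = len(depth)
    masked = [False] * n
    fragments = fragments or []
    units: list[tuple[int, int]] = []

    while True:
        # (i) highest-depth unmasked position, leftmost on ties
        best_pos, best_depth = -1, -1
        for i in range(n):
            if not masked[i] and depth[i] > best_depth:
                best_pos, best_depth = i, depth[i]
        if best_depth < min_seed_depth:
            break

        # (ii) alternate single-base extensions, left first
        start, end = best_pos, best_pos + 1
        stopped = {"L": False, "R": False}

        def mean() -> float:
            return sum(depth[start:end]) / (end - start)

        def neighbour_depth(side: str) -> int:
            pos = start - 1 if side == "L" else end
            if pos < 0 or pos >= n or masked[pos]:
                return 0
            return depth[pos]

        while not (stopped["L"] and stopped["R"]):
            for side in ("L", "R"):
                if stopped[side]:
                    continue
                if mean() >= edge_ratio * neighbour_depth(side):
                    stopped[side] = True
                elif side == "L":
                    start -= 1
                else:
                    end += 1

        # (iii) reassign each boundary once to span fragments containing the
        # stop position, without entering already-masked bases
        left_candidates = [f0 for (f0, f1) in fragments if f0 <= start < f1]
        right_candidates = [f1 for (f0, f1) in fragments if f0 <= end - 1 < f1]
        new_start = min(left_candidates + [start])
        new_end = max(right_candidates + [end])
        while new_start < start and any(masked[new_start:start]):
            new_start += 1
        while new_end > end and any(masked[end:new_end]):
            new_end -= 1
        start, end = new_start, new_end

        # (iv) mask and record
        for i in range(start, end):
            masked[i] = True
        if end - start >= min_length:
            units.append((start, end))

    return sorted(units)
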