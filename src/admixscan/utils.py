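"""Shared numerics: seeded substreams, FDR correction, range expansion, intervals."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def rng_substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG derived from a master seed and a stream label.

    All randomness in the package flows from a single top-level seed through
    named substreams, so adding a stage never perturbs another stage's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def expand_ranges(lo, hi):
    """Flatten per-row index ranges [lo_i, hi_i) into paired (row, index) vectors.

    Used to vectorise "for each focal site, visit all neighbours in a window"
    loops without Python-level iteration.
    """
    lo = np.asarray(lo, dtype=np.int64)
    hi = np.asarray(hi, dtype=np.int64)
    counts = np.maximum(hi - lo, 0)
    rows = np.repeat(np.arange(lo.size), counts)
    if rows.size == 0:
        return rows, rows.copy()
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    flat = np.arange(counts.sum()) - np.repeat(starts, counts) + np.repeat(lo, counts)
    return rows, flat


def merge_intervals(intervals):
    """Merge possibly overlapping half-open [start, end) intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_total(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def interval_intersection(a, b):
    """Intersection of two half-open interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def interval_jaccard(a, b) -> float:
    """Jaccard index (bp overlap / bp union) between two interval sets."""
    inter = interval_total(interval_intersection(a, b))
    union = interval_total(a) + interval_total(b) - inter
    return inter / union if union > 0 else 0.0
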