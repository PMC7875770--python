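"""Genomic interval utilities (0-based, half-open throughout).

BED input is consumed natively; VCF positions are converted to 0-based on
read, so every in-memory coordinate in this package shares one convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

IntervalSet = dict[str, np.ndarray]  # chrom -> (n, 2) array of [start, end)


def read_bed(path) -> IntervalSet:
    """Read a BED3(+) file into merged per-chromosome interval arrays."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str}, comment="#",
    )
    out: IntervalSet = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = merge_intervals(sub[["start", "end"]].to_numpy())
    return out


def merge_intervals(iv: np.ndarray, warn_overlap: bool = False) -> np.ndarray:
    """Sort and merge overlapping/adjacent [start, end) intervals."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(iv, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [iv[0].tolist()]
    overlapped = False
    for start, end in iv[1:]:
        if start <= merged[-1][1]:
            if start < merged[-1][1]:
                overlapped = True
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    if overlapped and warn_overlap:
        warnings.warn("overlapping intervals were merged", stacklevel=2)
    return np.array(merged, dtype=np.int64)


def positions_in_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the merged intervals."""
    pos = np.asarray(pos)
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < iv[idx[ok], 1]
    return ok


def overlap_length(start: int, end: int, iv: np.ndarray) -> int:
    """Total overlap of [start, end) with the merged interval set."""
    if len(iv) == 0:
        return 0
    lo = np.maximum(iv[:, 0], start)
    hi = np.minimum(iv[:, 1], end)
    return int(np.maximum(hi - lo, 0).sum())
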