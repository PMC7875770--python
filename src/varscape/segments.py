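"""1-Mb segment variant density: contiguous and conservation-concatenated.

Biallelic SNVs are classified common (allele frequency >= 0.005) or rare
(< 0.005) and coding or noncoding, then counted per contiguous 1-Mb
chromosomal segment.  A short terminal segment of length L < 1e6 has its
counts scaled by 1e6 / L.  Because the coding proportion C of a segment
(and mapping accessibility A) correlate with its variant count, counts are
adjusted by ordinary least squares,

    count = b0 + b1*C + b2*A + count_adj,

and the residual count_adj (plus its Z-score across segments) is the
quantity compared between segments.  The concatenated analysis instead
strings together all bases of one conservation class (coding/noncoding x
CADD high/medium/low) in genome order and counts variants per 1-Mb of
concatenated sequence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals, overlap_length, \
    positions_in_intervals
from .variant_io import VariantTable

CATEGORIES = ["common_coding", "common_noncoding", "rare_coding",
              "rare_noncoding"]
CADD_TIERS = ["high", "medium", "low"]


def cadd_tier(score) -> np.ndarray:
    """Deleteriousness tier: high (CADD >= 20), medium (10 <= CADD < 20), low."""
    score = np.asarray(score, dtype=float)
    return np.select([score >= 20, score >= 10], ["high", "medium"], "low")


def contiguous_segment_counts(table: VariantTable,
                              coding_intervals: IntervalSet,
                              chrom_lengths: dict[str, int],
                              mask: IntervalSet | None = None,
                              window_size: int = 1_000_000,
                              af_common: float = 0.005,
                              drop_empty: bool = True) -> pd.DataFrame:
    """Per-segment category counts with coding/accessibility proportions.

    Returns one row per (non-empty) segment with raw and scaled counts for
    the four common/rare x coding/noncoding categories, the segment length,
    C (coding proportion) and A (accessibility-mask overlap proportion).
    """
    snv = table.biallelic_snvs()
    coding_intervals = {
        c: merge_intervals(iv, warn_overlap=True)
        for c, iv in coding_intervals.items()
    }
    rows = []
    for chrom, length in chrom_lengths.items():
        sel = (snv.variants["chrom"] == chrom).to_numpy()
        pos = snv.variants.loc[sel, "pos"].to_numpy()
        af = snv.variants.loc[sel, "af"].to_numpy()
        civ = coding_intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        miv = (mask or {}).get(chrom, np.empty((0, 2), dtype=np.int64))
        coding = positions_in_intervals(pos, civ)
        common = af >= af_common
        win = pos // window_size
        for start in range(0, int(length), window_size):
            end = min(start + window_size, int(length))
            seg_len = end - start
            here = win == start // window_size
            raw = {
                "common_coding": int((here & common & coding).sum()),
                "common_noncoding": int((here & common & ~coding).sum()),
                "rare_coding": int((here & ~common & coding).sum()),
                "rare_noncoding": int((here & ~common & ~coding).sum()),
            }
            total = sum(raw.values())
            if drop_empty and total == 0:
                continue
            scale = window_size / seg_len
            row = {"chrom": chrom, "start": start, "end": end,
                   "length": seg_len,
                   "C": overlap_length(start, end, civ) / seg_len,
                   "A": overlap_length(start, end, miv) / seg_len}
            for cat in CATEGORIES:
                row[cat] = raw[cat]
                row[f"{cat}_scaled"] = raw[cat] * scale
            rows.append(row)
    return pd.DataFrame(rows)


def adjust_counts(segments: pd.DataFrame,
                  categories: list[str] = CATEGORIES) -> pd.DataFrame:
    """OLS-adjust scaled counts for coding and accessibility proportions.

    Appends ``<cat>_adj`` (residual) and ``<cat>_z`` (residual Z-score over
    segments) per category.  If C and A are constant the design is rank
    deficient; the offending columns are dropped, leaving centred counts.
    """
    if len(segments) < 10:
        raise ValueError("need at least 10 segments for adjustment")
    out = segments.copy()
    covs = segments[["C", "A"]].to_numpy(dtype=float)
    use = [j for j in range(2) if np.ptp(covs[:, j]) > 0]
    if len(use) < 2:
        dropped = [name for j, name in enumerate(["C", "A"]) if j not in use]
        warnings.warn(
            f"constant covariate(s) {dropped} dropped from adjustment",
            stacklevel=2,
        )
    X = np.column_stack([np.ones(len(segments)), covs[:, use]])
    for cat in categories:
        y = segments[f"{cat}_scaled"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[f"{cat}_adj"] = resid
        sd = resid.std(ddof=0)
        out[f"{cat}_z"] = resid / sd if sd > 0 else 0.0
    return out


def concatenated_segment_counts(table: VariantTable,
                                base_classes: pd.DataFrame,
                                window_size: int = 1_000_000,
                                af_common: float = 0.005) -> pd.DataFrame:
    """Variant counts per 1-Mb of class-concatenated sequence.

    ``base_classes`` labels every analyzable base with intervals (chrom,
    start, end, coding: bool, tier: high/medium/low); bases not covered are
    outside the analysis and a variant falling there is an error.  For each
    of the six classes, its intervals are concatenated in the given genome
    order and cut into 1-Mb segments of concatenated coordinate; the final
    short segment is scaled by 1e6 / L.
    """
    snv = table.biallelic_snvs()
    af = snv.variants["af"].to_numpy()
    rows = []
    captured = np.zeros(len(snv.variants), dtype=bool)
    for (coding, tier), cls in base_classes.groupby(["coding", "tier"],
                                                    sort=False):
        offsets = np.concatenate([[0], np.cumsum(
            (cls["end"] - cls["start"]).to_numpy(dtype=np.int64))])
        total_len = int(offsets[-1])
        concat_pos = np.full(len(snv.variants), -1, dtype=np.int64)
        for chrom, sub in cls.reset_index(drop=True).groupby("chrom",
                                                             sort=False):
            sel = np.where((snv.variants["chrom"] == chrom).to_numpy())[0]
            if len(sel) == 0:
                continue
            pos = snv.variants["pos"].to_numpy()[sel]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            offs = offsets[sub.index.to_numpy()]
            order = np.argsort(starts, kind="stable")
            starts, ends, offs = starts[order], ends[order], offs[order]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[ok] < ends[idx[ok]]
            concat_pos[sel[ok]] = offs[idx[ok]] + (pos[ok] - starts[idx[ok]])
        hit = concat_pos >= 0
        for seg_start in range(0, total_len, window_size):
            seg_len = min(window_size, total_len - seg_start)
            here = hit & (concat_pos // window_size == seg_start // window_size)
            scale = window_size / seg_len
            rows.append({
                "coding": bool(coding), "tier": tier,
                "segment": seg_start // window_size, "length": seg_len,
                "common": int((here & (af >= af_common)).sum()),
                "rare": int((here & (af < af_common)).sum()),
                "common_scaled": float((here & (af >= af_common)).sum() * scale),
                "rare_scaled": float((here & (af < af_common)).sum() * scale),
            })
        captured |= hit
    if len(snv.variants) and not captured.all():
        i = int(np.where(~captured)[0][0])
        v = snv.variants.iloc[i]
        raise ValueError(
            f"variant {v['chrom']}:{v['pos']} falls at an unlabelled base"
        )
    return pd.DataFrame(rows)
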