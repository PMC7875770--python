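"""pLOF burden per gene and CDS-length-matched gene-set bootstrap.

For every gene we record L, the number of retained putative
loss-of-function (pLOF) variants per protein-coding base pair, and S, the
proportion of singletons among those variants.  A gene set's mean L and S
are compared against a null that resamples genes of matched CDS length:
genes are sorted by CDS length, divided into equal-size bins, and each
bootstrap replicate draws, with replacement and from each bin, as many
genes as the set contributes to that bin.  Empirical one-sided P values
count replicates whose mean falls strictly below / above the observed
mean; the fold change is observed over the bootstrap average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, positions_in_intervals

logger = logging.getLogger(__name__)


@dataclass
class DepletionResult:
    gene_set: str
    n_genes: int
    observed_L: float
    observed_S: float
    boot_mean_L: float
    boot_mean_S: float
    fold_change_L: float
    fold_change_S: float
    p_low_L: float
    p_high_L: float
    p_low_S: float
    p_high_S: float
    n_boot: int
    bin_size: int
    seed: int | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def gene_plof_stats(plof_variants: pd.DataFrame, genes: pd.DataFrame,
                    af_threshold: float = 0.005,
                    mask: IntervalSet | None = None) -> pd.DataFrame:
    """Per-gene L and S after allele-frequency and accessibility filters.

    ``plof_variants`` columns: gene_id, chrom, pos, af, is_singleton (the
    pLOF annotation itself is consumed as input).  Variants with
    af > ``af_threshold`` or inside ``mask`` are excluded.  ``genes``
    columns: gene_id, cds_length.  Genes with no retained pLOF variant get
    L = 0 and undefined (NaN) S.
    """
    if (genes["cds_length"] <= 0).any():
        bad = genes.loc[genes["cds_length"] <= 0, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad} has non-positive CDS length")
    v = plof_variants[plof_variants["af"] <= af_threshold]
    if mask is not None and len(v):
        drop = np.zeros(len(v), dtype=bool)
        for chrom, iv in mask.items():
            sel = (v["chrom"] == chrom).to_numpy()
            if sel.any():
                drop[sel] = positions_in_intervals(v.loc[sel, "pos"].to_numpy(), iv)
        v = v.loc[~drop]
    agg = v.groupby("gene_id").agg(
        n_plof=("gene_id", "size"),
        n_singleton=("is_singleton", "sum"),
    )
    out = genes[["gene_id", "cds_length"]].merge(
        agg, left_on="gene_id", right_index=True, how="left")
    out[["n_plof", "n_singleton"]] = out[["n_plof", "n_singleton"]].fillna(0)
    out["n_plof"] = out["n_plof"].astype(np.int64)
    out["L"] = out["n_plof"] / out["cds_length"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["S"] = np.where(out["n_plof"] > 0,
                            out["n_singleton"] / out["n_plof"], np.nan)
    return out.drop(columns=["n_singleton"])


def _assign_bins(genes: pd.DataFrame, bin_size: int) -> np.ndarray:
    """Equal-count bins by ascending CDS length (ties broken by gene id)."""
    order = np.lexsort((genes["gene_id"].to_numpy(),
                        genes["cds_length"].to_numpy()))
    bins = np.empty(len(genes), dtype=np.int64)
    bins[order] = np.arange(len(genes)) // bin_size
    return bins


def length_matched_bootstrap(genes: pd.DataFrame, gene_set, set_id: str = "set",
                             n_boot: int = 10_000, bin_size: int = 1000,
                             seed: int | None = None) -> DepletionResult:
    """CDS-length-matched bootstrap of a gene set's mean L and S.

    The final short bin (fewer than ``bin_size`` genes) is kept as its own
    bin.  Genes without pLOF variants contribute L = 0 but are excluded
    from the S averages (S undefined).  P values are strict-inequality
    proportions of ``n_boot`` replicates, floored at 1/n_boot.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    unknown = set(gene_set) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"gene set members missing from gene table: "
                         f"{sorted(unknown)[:5]}")
    g = genes.reset_index(drop=True)
    bins = _assign_bins(g, bin_size)
    in_set = g["gene_id"].isin(gene_set).to_numpy()
    L = g["L"].to_numpy(dtype=float)
    S = g["S"].to_numpy(dtype=float)

    n_excluded_s = int(np.isnan(S[in_set]).sum())
    if n_excluded_s:
        logger.info("%d set genes lack pLOF variants; excluded from S averages",
                    n_excluded_s)
    obs_L = float(L[in_set].mean())
    obs_S = float(np.nanmean(S[in_set])) if np.isfinite(S[in_set]).any() else np.nan

    rng = np.random.default_rng(seed)
    sum_L = np.zeros(n_boot)
    sum_S = np.zeros(n_boot)
    cnt_S = np.zeros(n_boot)
    n_set = int(in_set.sum())
    for b in np.unique(bins[in_set]):
        take = int((in_set & (bins == b)).sum())
        pool = np.where(bins == b)[0]
        draws = pool[rng.integers(0, len(pool), size=(n_boot, take))]
        sum_L += L[draws].sum(axis=1)
        s_draw = S[draws]
        finite = np.isfinite(s_draw)
        sum_S += np.where(finite, s_draw, 0.0).sum(axis=1)
        cnt_S += finite.sum(axis=1)
    mean_L = sum_L / n_set
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_S = np.where(cnt_S > 0, sum_S / cnt_S, np.nan)

    def p_pair(sampled, observed):
        if not np.isfinite(observed):
            return np.nan, np.nan
        low = float((sampled < observed).sum()) / n_boot
        high = float((sampled > observed).sum()) / n_boot
        return max(low, 1.0 / n_boot), max(high, 1.0 / n_boot)

    p_low_L, p_high_L = p_pair(mean_L, obs_L)
    p_low_S, p_high_S = p_pair(mean_S[np.isfinite(mean_S)], obs_S)
    boot_L = float(mean_L.mean())
    boot_S = float(np.nanmean(mean_S))
    return DepletionResult(
        gene_set=set_id, n_genes=n_set,
        observed_L=obs_L, observed_S=obs_S,
        boot_mean_L=boot_L, boot_mean_S=boot_S,
        fold_change_L=obs_L / boot_L if boot_L > 0 else np.nan,
        fold_change_S=obs_S / boot_S if boot_S and boot_S > 0 else np.nan,
        p_low_L=p_low_L, p_high_L=p_high_L,
        p_low_S=p_low_S, p_high_S=p_high_S,
        n_boot=n_boot, bin_size=bin_size, seed=seed,
    )


def singleton_proportion_by_annotation(variants: pd.DataFrame,
                                       categories: list[str] | None = None,
                                       stratify_cpg: bool = False
                                       ) -> pd.DataFrame:
    """Singleton proportion per annotation category (optionally CpG-split).

    ``variants`` columns: annotation, is_singleton, and cpg_flag when
    ``stratify_cpg``.  Categories with zero variants are emitted with NaN
    proportion and flagged ``empty=True``.  Aggregates and strata can
    disagree in direction when CpG composition differs between categories
    (Simpson's paradox), which is why the stratified view exists.
    """
    keys = ["annotation"] + (["cpg_flag"] if stratify_cpg else [])
    agg = variants.groupby(keys, dropna=False).agg(
        n_variants=("is_singleton", "size"),
        n_singletons=("is_singleton", "sum"),
    ).reset_index()
    if categories is not None:
        have = set(agg["annotation"])
        pad = [{"annotation": c, "n_variants": 0, "n_singletons": 0}
               for c in categories if c not in have]
        if pad:
            agg = pd.concat([agg, pd.DataFrame(pad)], ignore_index=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["proportion"] = np.where(agg["n_variants"] > 0,
                                     agg["n_singletons"] / agg["n_variants"],
                                     np.nan)
    agg["empty"] = agg["n_variants"] == 0
    return agg.sort_values(keys).reset_index(drop=True)
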