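"""Jaccard rare-variant sharing between and within study/population groups.

Two individuals' sharing is J = |A ∩ B| / |A ∪ B| over their carrier sets
of rare variants, where a variant is *rare* when its full-sample carrier
count (individuals with at least one alternate allele, het or hom) lies in
[2, 100].  The filter is applied over the full analysis sample before any
group split, so the variant universe is identical for every pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class CarrierMatrix:
    """Binary individuals x rare-variants carriage matrix."""

    matrix: np.ndarray            # (n_individuals, n_variants) bool
    samples: list[str]
    carrier_counts: np.ndarray    # full-sample counts of the retained variants

    def row(self, individual_id: str) -> np.ndarray:
        return self.matrix[self.samples.index(individual_id)]


def build_carrier_matrix(table: VariantTable, min_carriers: int = 2,
                         max_carriers: int = 100) -> CarrierMatrix:
    """Filter to rare SNVs by full-sample carrier count and binarize.

    Indels, multiallelic records and singletons (carrier count < 2) are
    removed; so are variants carried by more than ``max_carriers``
    individuals.
    """
    snv = (table.variants["var_class"] == "SNV").to_numpy()
    carriers = table.carriage > 0
    counts = carriers.sum(axis=1)
    keep = snv & (counts >= min_carriers) & (counts <= max_carriers)
    if not keep.any():
        raise ValueError("no variants survive the carrier-count filter")
    return CarrierMatrix(carriers[keep].T.copy(), list(table.samples),
                         counts[keep])


def jaccard_pair(a: np.ndarray, b: np.ndarray) -> float:
    """J = |A ∩ B| / |A ∪ B| over two boolean carrier rows (0 if both empty)."""
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        logger.info("empty carrier union; defining J = 0")
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def pairwise_jaccard(matrix: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard matrix (diagonal = 1 by convention)."""
    m = matrix.astype(np.float64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return jac


def group_sharing(cm: CarrierMatrix, metadata: pd.DataFrame,
                  min_group: int = 19,
                  subsample: tuple[int, int] | None = None) -> pd.DataFrame:
    """Mean J within and between study x population-group splits.

    ``metadata`` columns: individual_id, study, population_group.
    Individuals with a missing or "other" population group are dropped;
    groups smaller than ``min_group`` are excluded.  ``subsample=(n, seed)``
    first samples n individuals without replacement from each eligible
    group (the sample-size robustness check).  Averages exclude the
    diagonal; the within mean runs over all unordered pairs inside a group,
    the between mean over all cross pairs.
    """
    meta = metadata.copy()
    meta["population_group"] = meta["population_group"].astype("string")
    drop = meta["population_group"].isna() | (
        meta["population_group"].str.lower() == "other")
    meta = meta[~drop]
    meta = meta[meta["individual_id"].isin(cm.samples)]
    meta["group"] = meta["study"].astype(str) + "/" + meta["population_group"]

    sizes = meta.groupby("group")["individual_id"].count()
    eligible = sizes[sizes >= min_group].index
    meta = meta[meta["group"].isin(eligible)]
    if meta.empty:
        raise ValueError("no groups meet the minimum size")

    rng = None
    if subsample is not None:
        n_sub, seed = subsample
        rng = np.random.default_rng(seed)
        picks = []
        for _, sub in meta.groupby("group", sort=True):
            take = min(n_sub, len(sub))
            picks.append(sub.iloc[np.sort(rng.choice(len(sub), take,
                                                     replace=False))])
        meta = pd.concat(picks, ignore_index=True)

    index = {s: i for i, s in enumerate(cm.samples)}
    members = {
        g: np.array([index[i] for i in sub["individual_id"]])
        for g, sub in meta.groupby("group", sort=True)
    }
    jac = pairwise_jaccard(cm.matrix)
    groups = sorted(members)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i:]:
            ia, ib = members[ga], members[gb]
            block = jac[np.ix_(ia, ib)]
            if ga == gb:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            rows.append((ga, gb, float(vals.mean()) if len(vals) else np.nan,
                         len(vals)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_J",
                                       "n_pairs"])


def heterozygosity_and_singletons(table: VariantTable) -> pd.DataFrame:
    """Per-individual heterozygous-site and full-sample-singleton counts.

    Counts run over biallelic SNVs; a singleton here is a variant whose
    allele count over the whole table equals 1.
    """
    snv = table.biallelic_snvs()
    het = (snv.carriage == 1).sum(axis=0)
    singleton_rows = snv.variants["ac"].to_numpy() == 1
    sing = (snv.carriage[singleton_rows] == 1).sum(axis=0)
    return pd.DataFrame({
        "individual_id": snv.samples,
        "het_count": het.astype(np.int64),
        "singleton_count": sing.astype(np.int64),
    })
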