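"""Variant input: VCF reading, subsample allele counts, singleton extraction.

A *singleton* is an allele observed exactly once in the defining sample
subset, carried as a heterozygote by one individual.  Because allele counts
change with the subset, `read_variants` always recomputes them over the
samples actually requested; a variant that is rare in the full callset may
or may not be a singleton within a 1,000-individual subsample.

All positions are 0-based half-open internally; the VCF's 1-based POS is
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import IntervalSet, positions_in_intervals

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "var_class", "ac", "af"]


@dataclass
class VariantTable:
    """Variant sites plus per-individual carriage over a sample subset.

    variants : DataFrame with columns chrom, pos (0-based), ref, alt,
        var_class in {SNV, indel, multiallelic}, ac (subsample allele
        count), af (ac / 2n), plus any annotation columns.
    carriage : (n_variants, n_samples) int8 array; 0 = non-carrier,
        1 = heterozygote, 2 = homozygote for the alternate allele.
    samples : individual ids, column order of `carriage`.
    """

    variants: pd.DataFrame
    carriage: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.carriage.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"carriage shape {self.carriage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, individual_id: str) -> int:
        try:
            return self.samples.index(individual_id)
        except ValueError:
            raise KeyError(
                f"individual {individual_id!r} is not in the sample subset"
            ) from None

    def biallelic_snvs(self) -> "VariantTable":
        keep = (self.variants["var_class"] == "SNV").to_numpy()
        return self.subset(keep)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return replace(
            self,
            variants=self.variants.loc[mask].reset_index(drop=True),
            carriage=self.carriage[mask],
        )


def table_from_arrays(chrom, pos, ref, alt, carriage, samples,
                      var_class=None, **annotations) -> VariantTable:
    """Build a VariantTable from in-memory arrays (synthetic data, tests)."""
    carriage = np.asarray(carriage, dtype=np.int8)
    n = carriage.shape[0]
    if var_class is None:
        var_class = np.where(
            (np.char.str_len(np.asarray(ref, dtype=str)) == 1)
            & (np.char.str_len(np.asarray(alt, dtype=str)) == 1),
            "SNV", "indel",
        )
    ac = carriage.sum(axis=1).astype(np.int64)
    df = pd.DataFrame({
        "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (n,)).copy(),
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": ref, "alt": alt, "var_class": var_class,
        "ac": ac, "af": ac / (2 * carriage.shape[1]),
    })
    for key, values in annotations.items():
        df[key] = values
    return VariantTable(df, carriage, list(samples))


def read_variants(vcf_path, sample_subset=None, mask: IntervalSet | None = None,
                  annotation_fields: tuple[str, ...] = ()) -> VariantTable:
    """Read a VCF, recomputing allele counts within ``sample_subset``.

    Multiallelic records (more than one ALT) are retained but flagged
    ``var_class == "multiallelic"``; downstream analyses drop them.  Sites
    whose 0-based position falls inside ``mask`` are removed.  Missing
    genotypes count as non-carriers.

    Raises
    ------
    KeyError if a requested sample is absent from the VCF header.
    ValueError if the VCF is not coordinate-sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise KeyError(f"samples not in VCF header: {missing}")
        vcf = VCF(str(vcf_path), gts012=True, samples=list(sample_subset))
        samples = list(vcf.samples)
    else:
        samples = header_samples

    rows, carriage_rows = [], []
    last = {}
    seen_chroms: list[str] = []
    for v in vcf:
        chrom, pos0 = v.CHROM, v.POS - 1
        if chrom not in last:
            if chrom in seen_chroms:
                raise ValueError(f"unsorted VCF: chromosome {chrom} re-visited")
            seen_chroms.append(chrom)
            last[chrom] = -1
        if pos0 < last[chrom]:
            raise ValueError(
                f"unsorted VCF: {chrom}:{v.POS} after position {last[chrom] + 1}"
            )
        last[chrom] = pos0

        if len(v.ALT) > 1:
            var_class = "multiallelic"
        elif len(v.ALT) == 0:
            continue
        elif len(v.REF) == 1 and len(v.ALT[0]) == 1:
            var_class = "SNV"
        else:
            var_class = "indel"

        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing -> carriage copies
        gt = np.asarray(v.gt_types)
        carr = np.where(gt == 3, 0, gt).astype(np.int8)
        row = [chrom, pos0, v.REF, v.ALT[0] if v.ALT else ".", var_class]
        for f in annotation_fields:
            row.append(v.INFO.get(f))
        rows.append(row)
        carriage_rows.append(carr)

    columns = ["chrom", "pos", "ref", "alt", "var_class", *annotation_fields]
    df = pd.DataFrame(rows, columns=columns)
    carriage = (np.vstack(carriage_rows) if carriage_rows
                else np.empty((0, len(samples)), dtype=np.int8))
    if mask is not None and len(df):
        drop = np.zeros(len(df), dtype=bool)
        for chrom, iv in mask.items():
            sel = (df["chrom"] == chrom).to_numpy()
            if sel.any():
                drop[sel] = positions_in_intervals(df.loc[sel, "pos"].to_numpy(), iv)
        df = df.loc[~drop].reset_index(drop=True)
        carriage = carriage[~drop]
    ac = carriage.sum(axis=1).astype(np.int64)
    df.insert(5, "ac", ac)
    df.insert(6, "af", ac / (2 * len(samples)) if samples else np.nan)
    return VariantTable(df, carriage, samples)


@dataclass
class SingletonSet:
    """One individual's singleton SNVs with nearest-neighbour distances.

    ``distances[j]`` is the bp distance from singleton j to the nearest
    other singleton of the same individual on the same chromosome (NaN when
    the chromosome holds only that one singleton).
    """

    individual_id: str
    records: pd.DataFrame  # chrom, pos, ref, alt, [context]
    distances: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df.insert(0, "individual_id", self.individual_id)
        df["distance"] = self.distances if self.distances is not None else np.nan
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SingletonSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ids = df["individual_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"expected one individual per file, got {list(ids)}")
        dist = df.pop("distance").to_numpy(dtype=float)
        return cls(str(ids[0]), df.drop(columns=["individual_id"]), dist)


def extract_singletons(table: VariantTable, individual_id: str) -> SingletonSet:
    """SNVs with subsample allele count 1 carried by ``individual_id``.

    Indels and multiallelic records never qualify; a homozygous-alternate
    genotype in one individual has allele count 2 and is not a singleton.
    """
    col = table.sample_index(individual_id)
    keep = (
        (table.variants["var_class"] == "SNV").to_numpy()
        & (table.variants["ac"].to_numpy() == 1)
        & (table.carriage[:, col] == 1)
    )
    cols = ["chrom", "pos", "ref", "alt"]
    if "context" in table.variants.columns:
        cols.append("context")
    records = table.variants.loc[keep, cols].reset_index(drop=True)
    return SingletonSet(individual_id, records)


def nearest_neighbor_distances(singletons: SingletonSet) -> SingletonSet:
    """Fill per-singleton distances to the nearest same-chromosome singleton.

    The distance is min(gap to previous, gap to next) within the same
    individual; chromosome boundaries are never crossed.  Duplicate
    positions indicate malformed input (two singletons cannot share a site).
    """
    records = singletons.records
    dist = np.full(len(records), np.nan)
    for _, idx in records.groupby("chrom", sort=False).indices.items():
        pos = records["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        p = pos[order]
        if len(p) < 2:
            continue
        gaps = np.diff(p).astype(float)
        if (gaps == 0).any():
            at = p[:-1][gaps == 0][0]
            raise ValueError(
                f"duplicate singleton position {at} for "
                f"{singletons.individual_id}: input is malformed"
            )
        nn = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
        dist[idx[order]] = nn
    return SingletonSet(singletons.individual_id, records, dist)
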