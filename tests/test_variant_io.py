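"""Allele-count recomputation, singleton extraction, neighbour distances."""

import numpy as np
import pandas as pd
import pytest

from varscape import simulate, variant_io
from conftest import manual_table


class TestReadVariants:
    def test_counts_match_bruteforce_genotype_sum(self, vcf_path, geno_table):
        table, _ = geno_table
        read = variant_io.read_variants(vcf_path)
        # brute force: allele copies summed over the generating carriage
        expected = table.carriage.sum(axis=1)
        np.testing.assert_array_equal(read.variants["ac"].to_numpy(), expected)
        np.testing.assert_array_equal(read.carriage, table.carriage)

    def test_subsample_counts_recomputed(self, vcf_path, geno_table):
        table, _ = geno_table
        subset = table.samples[:5]
        read = variant_io.read_variants(vcf_path, sample_subset=subset)
        expected = table.carriage[:, :5].sum(axis=1)
        np.testing.assert_array_equal(read.variants["ac"].to_numpy(), expected)
        # all-reference sites are retained with count 0
        assert (read.variants["ac"] == 0).any()
        assert np.allclose(read.variants["af"],
                           read.variants["ac"] / (2 * 5))

    def test_missing_sample_is_named(self, vcf_path):
        with pytest.raises(KeyError, match="nope"):
            variant_io.read_variants(vcf_path, sample_subset=["nope"])

    def test_unsorted_vcf_rejected(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0",
            "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",
            "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",
        ]
        p = tmp_path / "unsorted.vcf"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="unsorted"):
            variant_io.read_variants(p)

    def test_mask_removes_sites(self, vcf_path):
        unmasked = variant_io.read_variants(vcf_path)
        lo, hi = 500, 5000
        masked = variant_io.read_variants(
            vcf_path, mask={"chr1": np.array([[lo, hi]])})
        pos = masked.variants["pos"].to_numpy()
        assert not ((pos >= lo) & (pos < hi)).any()
        inside = ((unmasked.variants["pos"] >= lo)
                  & (unmasked.variants["pos"] < hi)).sum()
        assert len(masked.variants) == len(unmasked.variants) - inside


class TestExtractSingletons:
    def test_matches_exhaustive_scan(self, rng):
        carr = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        table = manual_table(carr)
        for j, ind in enumerate(table.samples):
            got = variant_io.extract_singletons(table, ind)
            expect = [i for i in range(50)
                      if carr[i].sum() == 1 and carr[i, j] == 1]
            assert list(got.records["pos"]) == \
                [table.variants["pos"].iloc[i] for i in expect]

    def test_count_two_and_homalt_excluded(self):
        # variant 0: two hets (ac 2); variant 1: hom-alt in s0 (ac 2);
        # variant 2: single het in s0 (the only singleton)
        table = manual_table([[1, 1, 0], [2, 0, 0], [1, 0, 0]])
        got = variant_io.extract_singletons(table, "s0")
        assert len(got) == 1
        assert got.records["pos"].iloc[0] == table.variants["pos"].iloc[2]

    def test_indels_never_qualify(self):
        table = manual_table([[1, 0], [1, 0]], ref=["A", "AT"],
                             alt=["C", "A"])
        got = variant_io.extract_singletons(table, "s0")
        assert len(got) == 1 and got.records["ref"].iloc[0] == "A"

    def test_unknown_individual_errors(self, geno_table):
        with pytest.raises(KeyError):
            variant_io.extract_singletons(geno_table[0], "ghost")


class TestNearestNeighborDistances:
    def _set(self, chroms, positions):
        rec = pd.DataFrame({
            "chrom": chroms, "pos": positions,
            "ref": "A", "alt": "C",
        })
        return variant_io.SingletonSet("x", rec)

    def test_three_point_example(self):
        got = variant_io.nearest_neighbor_distances(
            self._set(["1"] * 3, [100, 200, 500]))
        np.testing.assert_array_equal(got.distances, [100, 100, 300])

    def test_lone_singleton_has_no_distance(self):
        got = variant_io.nearest_neighbor_distances(self._set(["1"], [42]))
        assert np.isnan(got.distances).all()

    def test_matches_all_pairs_oracle(self, rng):
        pos = np.sort(rng.choice(100000, size=50, replace=False))
        got = variant_io.nearest_neighbor_distances(self._set(["1"] * 50, pos))
        oracle = [min(abs(p - q) for q in pos if q != p) for p in pos]
        np.testing.assert_array_equal(got.distances, oracle)

    def test_distances_never_cross_chromosomes(self):
        got = variant_io.nearest_neighbor_distances(
            self._set(["1", "1", "2"], [100, 200, 201]))
        np.testing.assert_array_equal(got.distances[:2], [100, 100])
        assert np.isnan(got.distances[2])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            variant_io.nearest_neighbor_distances(
                self._set(["1", "1"], [7, 7]))

    def test_emitted_distance_count_invariant(self, rng):
        chroms = rng.choice(["1", "2", "3"], size=40)
        pos = rng.choice(10**6, size=40, replace=False)
        got = variant_io.nearest_neighbor_distances(self._set(chroms, pos))
        lone = sum((chroms == c).sum() == 1 for c in set(chroms))
        assert np.isfinite(got.distances).sum() == 40 - lone


def test_singleton_set_tsv_roundtrip(tmp_path, geno_table):
    table, _ = geno_table
    ss = variant_io.nearest_neighbor_distances(
        variant_io.extract_singletons(table, table.samples[0]))
    path = tmp_path / "s.tsv"
    ss.to_tsv(path)
    back = variant_io.SingletonSet.from_tsv(path)
    assert back.individual_id == ss.individual_id
    pd.testing.assert_frame_equal(
        back.records.astype({"pos": np.int64}), ss.records)
    np.testing.assert_allclose(back.distances, ss.distances)


def test_duplicated_individual_identical_singletons(vcf_path):
    read = variant_io.read_variants(vcf_path)
    a = variant_io.extract_singletons(read, read.samples[0])
    b = variant_io.extract_singletons(read, read.samples[0])
    pd.testing.assert_frame_equal(a.records, b.records)


def test_allele_counts_invariant_to_subset_order(vcf_path, geno_table):
    table, _ = geno_table
    fwd = variant_io.read_variants(vcf_path, sample_subset=table.samples[:6])
    rev = variant_io.read_variants(
        vcf_path, sample_subset=list(reversed(table.samples[:6])))
    np.testing.assert_array_equal(fwd.variants["ac"], rev.variants["ac"])


def test_duplicated_individual_copies_have_identical_singletons(tmp_path):
    table, _ = simulate.simulate_genotype_matrix(
        simulate.GenotypeConfig(n_sites=120, groups={"A": 5},
                                duplicate_individual=True), seed=13)
    path = tmp_path / "dup.vcf"
    simulate.write_vcf(table, path)
    read = variant_io.read_variants(path)
    a = variant_io.extract_singletons(read, read.samples[0])
    b = variant_io.extract_singletons(read, read.samples[-1])
    # both copies carry every shared variant twice, so neither has those
    # as singletons and their singleton sets coincide (and are empty here)
    pd.testing.assert_frame_equal(a.records, b.records)
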