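"""Segment variant-density counting, adjustment and CADD concatenation."""

import numpy as np
import pandas as pd
import pytest

from varscape import segments
from conftest import manual_table


def snv_table(pos, af_counts, n_samples=1000, chrom="chr1"):
    """Variant table with chosen allele counts (af = ac / 2n)."""
    carr = np.zeros((len(pos), n_samples), dtype=np.int8)
    for i, k in enumerate(af_counts):
        carr[i, :k] = 1
    return manual_table(carr, pos=np.asarray(pos), chrom=chrom)


class TestContiguousSegmentCounts:
    def test_end_segment_scaling(self):
        # chromosome of 1.5 Mb: second segment has L = 5e5
        pos = [1_000_000 + 10 * i for i in range(10)]
        table = snv_table(pos, [1] * 10)
        got = segments.contiguous_segment_counts(
            table, {}, {"chr1": 1_500_000})
        seg = got[got["start"] == 1_000_000].iloc[0]
        assert seg["rare_noncoding"] == 10
        assert seg["rare_noncoding_scaled"] == 20
        full = got[got["start"] == 0]
        assert full.empty  # no variants -> dropped

    def test_af_boundary_is_common(self):
        table = snv_table([5, 6], [10, 9], n_samples=1000)  # af 0.005, 0.0045
        got = segments.contiguous_segment_counts(
            table, {}, {"chr1": 1_000_000})
        assert got["common_noncoding"].iloc[0] == 1
        assert got["rare_noncoding"].iloc[0] == 1

    def test_matches_bruteforce_counting(self, rng):
        pos = np.sort(rng.choice(3_000_000, size=400, replace=False))
        acs = rng.integers(1, 40, size=400)
        table = snv_table(pos, acs, n_samples=1000)
        coding = {"chr1": np.array([[100_000, 400_000],
                                    [2_100_000, 2_200_000]])}
        got = segments.contiguous_segment_counts(
            table, coding, {"chr1": 3_000_000})
        af = acs / 2000
        for _, seg in got.iterrows():
            inwin = (pos >= seg["start"]) & (pos < seg["end"])
            incod = ((pos >= 100_000) & (pos < 400_000)) | \
                    ((pos >= 2_100_000) & (pos < 2_200_000))
            assert seg["rare_coding"] == (inwin & incod & (af < 0.005)).sum()
            assert seg["common_noncoding"] == \
                (inwin & ~incod & (af >= 0.005)).sum()

    def test_coding_and_mask_proportions(self):
        table = snv_table([10], [1])
        coding = {"chr1": np.array([[0, 250_000]])}
        mask = {"chr1": np.array([[500_000, 600_000]])}
        got = segments.contiguous_segment_counts(
            table, coding, {"chr1": 1_000_000}, mask=mask)
        assert got["C"].iloc[0] == pytest.approx(0.25)
        assert got["A"].iloc[0] == pytest.approx(0.1)

    def test_full_length_segment_unscaled(self, rng):
        pos = rng.choice(1_000_000, size=50, replace=False)
        table = snv_table(np.sort(pos), [1] * 50)
        got = segments.contiguous_segment_counts(
            table, {}, {"chr1": 1_000_000})
        assert (got["rare_noncoding_scaled"] == got["rare_noncoding"]).all()


class TestAdjustCounts:
    def _segments(self, counts, C, A):
        n = len(counts)
        df = pd.DataFrame({"chrom": "chr1", "start": np.arange(n),
                           "end": np.arange(n) + 1, "length": 1,
                           "C": C, "A": A})
        for cat in segments.CATEGORIES:
            df[cat] = counts
            df[f"{cat}_scaled"] = counts
        return df

    def test_degenerate_design_centers_counts(self, rng):
        counts = rng.integers(0, 100, size=30).astype(float)
        segs = self._segments(counts, 0.5, 0.2)
        with pytest.warns(UserWarning, match="constant"):
            got = segments.adjust_counts(segs)
        np.testing.assert_allclose(got["rare_coding_adj"],
                                   counts - counts.mean(), atol=1e-9)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(4)
        n = 1000
        C = rng.uniform(0, 0.1, n)
        A = rng.uniform(0.5, 1.0, n)
        counts = 5 + 100 * C + 20 * A + rng.normal(0, 1, n)
        got = segments.adjust_counts(self._segments(counts, C, A))
        adj = got["rare_coding_adj"].to_numpy()
        assert abs(np.corrcoef(adj, C)[0, 1]) < 0.05
        assert abs(np.corrcoef(adj, A)[0, 1]) < 0.05
        assert got["rare_coding_adj"].sum() == pytest.approx(0, abs=1e-6)
        z = got["rare_coding_z"].to_numpy()
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std() == pytest.approx(1, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        n = 200
        C = rng.uniform(0, 0.2, n)
        A = rng.uniform(0, 1, n)
        counts = rng.poisson(50, n).astype(float)
        got = segments.adjust_counts(self._segments(counts, C, A))
        X = np.column_stack([np.ones(n), C, A])
        beta = np.linalg.solve(X.T @ X, X.T @ counts)
        np.testing.assert_allclose(got["rare_coding_adj"],
                                   counts - X @ beta, atol=1e-9)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError, match="10"):
            segments.adjust_counts(self._segments(np.arange(5), 0.1, 0.1))


class TestCaddTiers:
    def test_boundaries(self):
        got = segments.cadd_tier([20.0, 19.99, 10.0, 9.99])
        assert got.tolist() == ["high", "medium", "medium", "low"]


class TestConcatenatedSegmentCounts:
    def test_toy_genome_matches_bruteforce(self, rng):
        # 10-kb genome, alternating 1-kb class blocks
        blocks = []
        tiers = ["high", "medium", "low"]
        for i in range(10):
            blocks.append(("chr1", i * 1000, (i + 1) * 1000,
                           i % 2 == 0, tiers[i % 3]))
        classes = pd.DataFrame(blocks, columns=["chrom", "start", "end",
                                                "coding", "tier"])
        pos = np.sort(rng.choice(10_000, size=200, replace=False))
        acs = rng.integers(1, 30, size=200)
        table = snv_table(pos, acs, n_samples=1000)
        got = segments.concatenated_segment_counts(table, classes,
                                                   window_size=2000)
        af = acs / 2000
        for (coding, tier), sub in got.groupby(["coding", "tier"]):
            sel = np.zeros(len(pos), dtype=bool)
            for _, b in classes.iterrows():
                if b["coding"] == coding and b["tier"] == tier:
                    sel |= (pos >= b["start"]) & (pos < b["end"])
            assert sub["rare"].sum() == (sel & (af < 0.005)).sum()
            assert sub["common"].sum() == (sel & (af >= 0.005)).sum()

    def test_total_count_conserved(self, rng):
        classes = pd.DataFrame({
            "chrom": "chr1", "start": [0, 5000], "end": [5000, 10000],
            "coding": [True, False], "tier": ["high", "low"],
        })
        pos = np.sort(rng.choice(10_000, size=100, replace=False))
        table = snv_table(pos, [1] * 100, n_samples=1000)
        got = segments.concatenated_segment_counts(table, classes,
                                                   window_size=3000)
        assert (got["common"] + got["rare"]).sum() == 100

    def test_short_final_segment_scaled(self):
        classes = pd.DataFrame({
            "chrom": "chr1", "start": [0], "end": [1500],
            "coding": [False], "tier": ["low"],
        })
        table = snv_table([1200], [1], n_samples=1000)
        got = segments.concatenated_segment_counts(table, classes,
                                                   window_size=1000)
        tail = got[got["segment"] == 1].iloc[0]
        assert tail["length"] == 500
        assert tail["rare_scaled"] == pytest.approx(2.0)

    def test_unlabelled_base_rejected(self):
        classes = pd.DataFrame({
            "chrom": "chr1", "start": [0], "end": [100],
            "coding": [False], "tier": ["low"],
        })
        table = snv_table([150], [1])
        with pytest.raises(ValueError, match="unlabelled"):
            segments.concatenated_segment_counts(table, classes)
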