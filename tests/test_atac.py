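"""ATAC QC metrics, peak sharing, normalization, differential accessibility
and shuffle-based overlap enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdxfid import atac as A
from pdxfid.config import SimulationConfig
from pdxfid.simulate import simulate_atac


def peak_frame(rows, with_height=True):
    cols = ["chrom", "start", "end"] + (["height"] if with_height else [])
    return pd.DataFrame(rows, columns=cols)


class TestTssEnrichment:
    def test_uniform_coverage_scores_one(self):
        assert A.tss_enrichment(np.ones(4001)) == pytest.approx(1.0)

    def test_five_fold_center(self):
        profile = np.ones(4001)
        mid = 2000
        profile[mid - 50 : mid + 51] = 5.0
        assert A.tss_enrichment(profile) == pytest.approx(5.0)

    def test_gaussian_bump_matches_closed_form(self):
        x = np.arange(-2000, 2001)
        amp, sigma = 8.0, 120.0
        profile = 1.0 + amp * np.exp(-(x**2) / (2 * sigma**2))
        score = A.tss_enrichment(profile)
        center = x[(x >= -50) & (x <= 50)]
        expected_center = 1.0 + amp * np.exp(
            -(center.astype(float) ** 2) / (2 * sigma**2)
        )
        flank = np.concatenate([x[:100], x[-100:]])
        expected_flank = 1.0 + amp * np.exp(
            -(flank.astype(float) ** 2) / (2 * sigma**2)
        )
        expected = expected_center.mean() / expected_flank.mean()
        assert score == pytest.approx(expected, rel=0.02)

    def test_zero_flanks_undefined(self):
        profile = np.zeros(4001)
        profile[2000] = 10
        assert np.isnan(A.tss_enrichment(profile))


class TestFrip:
    def test_fraction(self):
        np.testing.assert_allclose(
            A.frip([3000, 10_000], [10_000, 10_000]), [0.3, 1.0]
        )

    def test_empty_peak_set_gives_zero(self):
        assert A.frip(0, 10_000)[0] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            A.frip([10], [0])


class TestPeakSharingCurve:
    def test_identical_sets_fully_shared(self):
        peaks = peak_frame([("chr1", 100, 200, 60.0), ("chr1", 300, 400, 10.0)])
        curve = A.peak_sharing_curve(peaks, peaks.copy(), [0, 50])
        assert (curve["fraction_shared"] == 1.0).all()

    def test_manual_overlap_example(self):
        pri = peak_frame([("chr1", 100, 200, 60.0), ("chr1", 300, 400, 10.0)])
        pdx = peak_frame([("chr1", 150, 250, 50.0)])
        curve = A.peak_sharing_curve(pri, pdx, [0, 50]).set_index(
            "height_threshold"
        )
        assert curve.loc[50, "fraction_shared"] == 1.0
        assert curve.loc[0, "fraction_shared"] == 0.5

    def test_disjoint_sets_unshared(self):
        pri = peak_frame([("chr1", 100, 200, 60.0)])
        pdx = peak_frame([("chr2", 100, 200, 60.0)])
        assert A.peak_sharing_curve(pri, pdx, [0])["fraction_shared"].iloc[0] == 0.0

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        pri = peak_frame([("chr1", 0, 10, 1.0)])
        pdx = peak_frame([("chr1", 10, 20, 1.0)])
        assert A.peak_sharing_curve(pri, pdx, [0])["fraction_shared"].iloc[0] == 0.0

    def test_matches_brute_force_oracle_on_random_peaks(self):
        rng = np.random.default_rng(0)
        def random_peaks(n):
            starts = rng.integers(0, 100_000, n)
            return peak_frame(
                [
                    (f"chr{rng.integers(1, 4)}", s, s + rng.integers(50, 500),
                     float(rng.lognormal(3, 1)))
                    for s in starts
                ]
            )
        pri, pdx = random_peaks(1000), random_peaks(1000)
        curve = A.peak_sharing_curve(pri, pdx, [0, 20, 50]).set_index(
            "height_threshold"
        )
        for t in (0, 20, 50):
            sel = pri.loc[pri["height"] >= t]
            shared = 0
            for p in sel.itertuples():
                for q in pdx.itertuples():
                    if (p.chrom == q.chrom and p.start < q.end
                            and q.start < p.end):
                        shared += 1
                        break
            assert curve.loc[t, "n_shared"] == shared


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(A.size_factors(counts), 1.0)

    def test_doubled_sample_anchored_at_geometric_mean(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = A.size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_single_sample_unit_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30]})
        assert A.size_factors(counts)["a"] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 1000))
    def test_invariant_to_per_peak_scaling_and_gmean_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 4)))
        sf = A.size_factors(counts)
        scaled = counts.mul(rng.integers(1, 10, size=50), axis=0)
        sf2 = A.size_factors(scaled)
        np.testing.assert_allclose(sf, sf2, rtol=1e-12)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-12)

    def test_fallback_warns_without_all_nonzero_peak(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with pytest.warns(UserWarning):
            A.size_factors(counts)


class TestPerPeakConcordance:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 500, 200)
        counts = pd.DataFrame({"a": col, "b": col})
        assert A.per_peak_concordance(counts, "a", "b")["pearson_r"] == \
            pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, 200)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert A.per_peak_concordance(counts, "a", "b")["pearson_r"] > 0.999

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {
                "a": rng.negative_binomial(10, 0.1, 10_000),
                "b": rng.negative_binomial(10, 0.1, 10_000),
            }
        )
        assert abs(A.per_peak_concordance(counts, "a", "b")["pearson_r"]) < 0.1


class TestDifferentialAccessibility:
    def make_meta(self, n_pairs):
        rows = []
        for p in range(n_pairs):
            for cond in ("PRI", "PDX"):
                rows.append(
                    {"sample_id": f"P{p}_{cond}", "patient": f"P{p}",
                     "condition": cond}
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def test_copied_conditions_give_zero_lfc(self):
        rng = np.random.default_rng(0)
        base = rng.negative_binomial(10, 0.1, size=(500, 3))
        cols = {}
        for p in range(3):
            cols[f"P{p}_PRI"] = base[:, p]
            cols[f"P{p}_PDX"] = base[:, p]
        counts = pd.DataFrame(cols)
        out = A.differential_accessibility(counts, self.make_meta(3))
        np.testing.assert_allclose(out["log2_fold_change"], 0.0, atol=1e-12)
        assert not out["significant"].any()

    def test_planted_drop_called_hypo(self):
        cfg = SimulationConfig(n_peaks=1500)
        _, counts, meta, truth = simulate_atac(cfg, seed=5)
        out = A.differential_accessibility(counts, meta)
        called = out.loc[out["significant"]]
        planted_called = called.loc[called.index.isin(truth["hypo_peaks"])]
        assert (planted_called["direction"] == "hypo").all()
        assert len(planted_called) / len(truth["hypo_peaks"]) >= 0.8

    def test_unpaired_design_rejected(self):
        counts = pd.DataFrame({"P0_PRI": [1, 2], "P1_PRI": [1, 2],
                               "P2_PRI": [3, 4], "P2_PDX": [3, 4]})
        meta = pd.DataFrame(
            {
                "patient": ["P0", "P1", "P2", "P2"],
                "condition": ["PRI", "PRI", "PRI", "PDX"],
            },
            index=counts.columns,
        )
        with pytest.raises(ValueError):
            A.differential_accessibility(counts, meta)

    def test_agrees_with_reference_nb_engine_on_effect_sizes(self):
        """Cross-check log2 fold changes against an independent NB GLM
        implementation (pydeseq2) on a small paired dataset."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimulationConfig(n_peaks=300, n_atac_pairs=4)
        _, counts, meta, _ = simulate_atac(cfg, seed=11)
        ours = A.differential_accessibility(counts, meta)

        metadata = meta.copy()
        metadata["condition"] = pd.Categorical(
            metadata["condition"], categories=["PRI", "PDX"]
        )
        dds = DeseqDataSet(
            counts=counts.T,
            metadata=metadata,
            design="~patient + condition",
            quiet=True,
        )
        dds.deseq2()
        res = DeseqStats(
            dds, contrast=["condition", "PDX", "PRI"], quiet=True
        )
        res.summary()
        ref_lfc = res.results_df["log2FoldChange"].reindex(counts.index)
        r = np.corrcoef(ours["log2_fold_change"], ref_lfc)[0, 1]
        assert r > 0.9


class TestShuffledOverlapEnrichment:
    def test_whole_genome_annotation_ratio_one(self):
        peaks = peak_frame(
            [("chr1", 100, 200, 1.0), ("chr1", 5000, 5100, 1.0)]
        )
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        out = A.shuffled_overlap_enrichment(
            peaks, ann, {"chr1": 100_000}, n_shuffles=50, seed=0
        )
        assert out["ratio"] == 1.0

    def test_random_peaks_are_calibrated(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 99_000, 300)
        peaks = peak_frame([("chr1", s, s + 500, 1.0) for s in starts])
        ann = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(0, 100_000, 10_000),
             "end": np.arange(1000, 101_000, 10_000)}
        )
        out = A.shuffled_overlap_enrichment(
            peaks, ann, {"chr1": 100_000}, n_shuffles=500, seed=2
        )
        assert out["ratio"] == pytest.approx(1.0, abs=0.15)

    def test_planted_enrichment_detected(self):
        peaks = peak_frame([("chr1", 100, 300, 1.0)] * 50)
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = A.shuffled_overlap_enrichment(
            peaks, ann, {"chr1": 1_000_000}, n_shuffles=200, seed=3
        )
        assert out["ratio"] > 10

    def test_expected_overlap_converges_by_1000_shuffles(self):
        """On the toy-genome peak set the shuffled expectation is stable:
        per-shuffle SD below 5% of the mean at 1000 shuffles."""
        peaks, _, _, truth = simulate_atac(SimulationConfig(), seed=4)
        ann = pd.concat(
            [
                pd.DataFrame(
                    {"chrom": chrom, "start": np.arange(0, size, 100_000),
                     "end": np.arange(20_000, size + 20_000, 100_000)}
                )
                for chrom, size in truth["chrom_sizes"].items()
            ],
            ignore_index=True,
        )
        out = A.shuffled_overlap_enrichment(
            peaks["PRI"], ann, truth["chrom_sizes"], n_shuffles=1000, seed=5
        )
        assert out["expected_sd"] / out["expected_mean"] < 0.05

    def test_peak_wider_than_chromosome_rejected(self):
        peaks = peak_frame([("chr1", 0, 2000, 1.0)])
        ann = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            A.shuffled_overlap_enrichment(peaks, ann, {"chr1": 1000},
                                          n_shuffles=10, seed=0)


class TestPcaEmbedding:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 500, 200)
        counts = pd.DataFrame(
            {
                "a": base,
                "a_dup": base,
                "b": rng.integers(0, 500, 200),
                "c": rng.integers(0, 500, 200),
            }
        )
        coords = A.pca_embedding(counts, top_n_variable_peaks=100)
        np.testing.assert_allclose(
            coords.loc["a"], coords.loc["a_dup"], atol=1e-9
        )

    def test_two_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(4, 0.5, 500)
        cols = {}
        for i in range(3):
            cols[f"g1_{i}"] = rng.poisson(base)
            shifted = base.copy()
            shifted[:100] *= 6
            cols[f"g2_{i}"] = rng.poisson(shifted)
        coords = A.pca_embedding(pd.DataFrame(cols), top_n_variable_peaks=200)
        g1 = coords.loc[[f"g1_{i}" for i in range(3)], "PC1"]
        g2 = coords.loc[[f"g2_{i}" for i in range(3)], "PC1"]
        assert g1.max() < g2.min() or g2.max() < g1.min()

    def test_coordinates_centered(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 500, size=(300, 5)))
        coords = A.pca_embedding(counts, top_n_variable_peaks=100)
        np.testing.assert_allclose(coords.sum(axis=0), 0.0, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            A.pca_embedding(pd.DataFrame({"a": [1], "b": [2]}))


class TestInsertSizeSummary:
    def test_all_short_fragments(self):
        out = A.insert_size_summary(np.full(2000, 75))
        assert out["fraction_sub100"] == 1.0
        assert out["nucleosome_periodicity"] is False

    def test_bimodal_mixture_flags_periodicity(self):
        rng = np.random.default_rng(0)
        lengths = np.concatenate(
            [rng.normal(60, 10, 3000), rng.normal(200, 15, 2000)]
        )
        out = A.insert_size_summary(lengths)
        assert out["nucleosome_periodicity"] is True
        assert 0.3 < out["fraction_mononucleosome"] < 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            A.insert_size_summary([])
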