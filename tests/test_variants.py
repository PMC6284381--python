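"""Variant filtering, pairing, preservation statistics and the relapse-type /
engraftment-mode classifiers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdxfid.config import ConcordanceConfig
from pdxfid import variants as V
from pdxfid.stats import pearson_r, wilcoxon_paired_p

from conftest import make_variant_row


def table(rows):
    return pd.DataFrame(rows)


class TestApplyDetectionFilters:
    def test_synonymous_removed(self, conc_config):
        df = table([make_variant_row(functional_class="synonymous")])
        assert V.apply_detection_filters(df, conc_config).empty

    def test_population_frequency_ceiling_inclusive(self, conc_config):
        df = table(
            [
                make_variant_row(pos=1, population_frequency=0.02),
                make_variant_row(pos=2, population_frequency=0.01),
            ]
        )
        out = V.apply_detection_filters(df, conc_config)
        assert out["pos"].tolist() == [2]

    def test_multi_sample_rescue(self, conc_config):
        df = table(
            [
                make_variant_row(sample_id="P1_INI_PRI", alt_reads=3),
                make_variant_row(sample_id="P1_REL_PRI", timepoint="REL",
                                 alt_reads=20),
            ]
        )
        out = V.apply_detection_filters(df, conc_config)
        assert len(out) == 2  # 3-read record rescued by the relapse call

    def test_low_support_without_rescue_removed(self, conc_config):
        df = table([make_variant_row(alt_reads=3)])
        assert V.apply_detection_filters(df, conc_config).empty

    def test_missing_annotation_field_named(self, conc_config):
        df = table([make_variant_row()]).drop(columns="population_frequency")
        with pytest.raises(ValueError, match="population_frequency"):
            V.apply_detection_filters(df, conc_config)


class TestClassifyClonality:
    @pytest.mark.parametrize(
        "af,expected",
        [(0.45, "clonal"), (0.30, "clonal"), (0.299, "subclonal"), (0.0, "subclonal")],
    )
    def test_threshold_inclusive(self, af, expected, conc_config):
        assert V.classify_clonality(af, conc_config) == expected

    def test_out_of_range_rejected(self, conc_config):
        with pytest.raises(ValueError):
            V.classify_clonality(1.2, conc_config)


class TestPairVariants:
    def test_identical_sets_all_preserved(self, conc_config):
        pri = table([make_variant_row(pos=p) for p in (1, 2, 3)])
        pdx = table(
            [make_variant_row(pos=p, origin="PDX", sample_id="P1_INI_PDX")
             for p in (1, 2, 3)]
        )
        pairing = V.pair_variants(pri, pdx, conc_config)
        assert (pairing["status"] == "preserved").all()

    def test_primary_only_is_lost_and_pdx_only_is_specific(self, conc_config):
        pri = table([make_variant_row(pos=1)])
        pdx = table(
            [make_variant_row(pos=2, origin="PDX", sample_id="P1_INI_PDX",
                              alt_reads=15, total_reads=100)]
        )
        pairing = V.pair_variants(pri, pdx, conc_config).set_index("pos")
        assert pairing.loc[1, "status"] == "lost"
        assert pairing.loc[2, "status"] == "pdx_specific"
        assert pairing.loc[1, "AF_pdx"] == 0.0

    def test_status_partitions_pairings(self, conc_config):
        rng = np.random.default_rng(0)
        pri = table(
            [make_variant_row(pos=int(p)) for p in rng.choice(100, 30, replace=False)]
        )
        pdx = table(
            [make_variant_row(pos=int(p), origin="PDX", sample_id="x")
             for p in rng.choice(100, 30, replace=False)]
        )
        pairing = V.pair_variants(pri, pdx, conc_config)
        counts = pairing["status"].value_counts()
        assert counts.sum() == len(pairing)
        assert counts.get("preserved", 0) + counts.get("lost", 0) == len(pri)
        assert counts.get("preserved", 0) + counts.get("pdx_specific", 0) == len(pdx)

    def test_mismatched_patients_rejected(self, conc_config):
        pri = table([make_variant_row(patient="P1")])
        pdx = table([make_variant_row(patient="P2", origin="PDX")])
        with pytest.raises(ValueError):
            V.pair_variants(pri, pdx, conc_config)


class TestPreservationSummary:
    def _pairing(self, n_total, n_preserved, conc_config):
        pri = table([make_variant_row(pos=i + 1) for i in range(n_total)])
        pdx = table(
            [make_variant_row(pos=i + 1, origin="PDX", sample_id="x")
             for i in range(n_preserved)]
        )
        return V.pair_variants(pri, pdx, conc_config)

    def test_overall_fraction(self, conc_config):
        summary = V.preservation_summary(self._pairing(10, 7, conc_config),
                                         conc_config)
        overall = summary.loc[summary["scope"] == "overall"].iloc[0]
        assert overall["n_total"] == 10
        assert overall["fraction"] == pytest.approx(0.7)

    def test_all_preserved_every_bin_full(self, conc_config):
        summary = V.preservation_summary(self._pairing(8, 8, conc_config),
                                         conc_config)
        populated = summary.loc[summary["n_total"] > 0]
        assert (populated["fraction"] == 1.0).all()

    def test_empty_input_warns(self, conc_config):
        with pytest.warns(UserWarning):
            out = V.preservation_summary(
                pd.DataFrame(columns=["detected_primary", "status",
                                      "AF_primary", "clonality_primary"]),
                conc_config,
            )
        assert out.empty


class TestAfConcordance:
    def test_identical_afs(self, conc_config):
        pri = table([make_variant_row(pos=i, alt_reads=10 + i) for i in range(5)])
        pdx = table(
            [make_variant_row(pos=i, alt_reads=10 + i, origin="PDX",
                              sample_id="x") for i in range(5)]
        )
        out = V.af_concordance(V.pair_variants(pri, pdx, conc_config))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["mean_af_primary"] == pytest.approx(out["mean_af_pdx"])
        assert out["wilcoxon_p"] == 1.0

    def test_anti_monotone_afs(self, conc_config):
        pri = table([make_variant_row(pos=i, alt_reads=10 + 5 * i,
                                      total_reads=100) for i in range(5)])
        pdx = table(
            [make_variant_row(pos=i, alt_reads=90 - 5 * i, total_reads=100,
                              origin="PDX", sample_id="x") for i in range(5)]
        )
        out = V.af_concordance(V.pair_variants(pri, pdx, conc_config))
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_too_few_pairs_undefined(self, conc_config):
        pri = table([make_variant_row(pos=1)])
        pdx = table([make_variant_row(pos=1, origin="PDX", sample_id="x")])
        out = V.af_concordance(V.pair_variants(pri, pdx, conc_config))
        assert np.isnan(out["pearson_r"])


class TestCorrelationOracles:
    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 50))
    def test_pearson_matches_covariance_formula(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(size=n), rng.uniform(size=n)
        r = pearson_r(x, y)
        # brute-force covariance formula
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_wilcoxon_matches_exact_enumeration(self, n):
        """Signed-rank p equals exhaustive enumeration over sign flips."""
        rng = np.random.default_rng(n)
        d = rng.normal(0.2, 1.0, size=n)  # continuous: no ties, no zeros
        p = wilcoxon_paired_p(d, np.zeros(n))
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        stats = np.array(stats)
        # two-sided: statistic at least as extreme in either direction
        dist = np.minimum(stats, total - stats)
        obs = min(w_obs, total - w_obs)
        expected = (dist <= obs).mean()
        assert p == pytest.approx(expected, abs=1e-9)


class TestPdxSpecificConsistency:
    def test_hand_computed_sd(self, conc_config):
        out = V.pdx_specific_consistency([0.30, 0.31, 0.29], conc_config)
        assert out["af_sd"] == pytest.approx(0.01, abs=1e-9)
        assert out["single_clone"] is True

    def test_dispersed_afs_not_single_clone(self, conc_config):
        out = V.pdx_specific_consistency([0.10, 0.45], conc_config)
        assert out["single_clone"] is False

    def test_single_variant_undefined(self, conc_config):
        assert V.pdx_specific_consistency([0.2], conc_config)["single_clone"] is None


class TestClassifyRelapseType:
    def test_maintained_clonal_set_is_type1(self):
        assert V.classify_relapse_type({"A", "B", "C"},
                                       {"A", "B", "C", "D", "E"}) == "type1"

    def test_lost_clonal_mutation_is_type2(self):
        assert V.classify_relapse_type({"A", "B", "C"}, {"A", "B", "D"}) == "type2"

    def test_singleton_maintained(self):
        assert V.classify_relapse_type({"A"}, {"A"}) == "type1"

    def test_empty_initial_set_rejected(self):
        with pytest.raises(ValueError):
            V.classify_relapse_type(set(), {"A"})


def _pairing_from_reads(rows, conc_config):
    """rows: (pos, alt_pri, tot_pri, alt_pdx, tot_pdx); zero alt = absent."""
    pri = table(
        [make_variant_row(pos=p, alt_reads=a, total_reads=t)
         for p, a, t, _, _ in rows if a > 0]
    )
    pdx = table(
        [make_variant_row(pos=p, alt_reads=a, total_reads=t, origin="PDX",
                          sample_id="P1_INI_PDX")
         for p, _, _, a, t in rows if a > 0]
    )
    return V.pair_variants(pri, pdx, conc_config)


class TestClassifyEngraftmentMode:
    def test_preserved_with_small_shifts_is_mode_a(self, conc_config):
        rows = [(i, 20 + i, 50, 22 + i, 50) for i in range(8)]
        pairing = _pairing_from_reads(rows, conc_config)
        out = V.classify_engraftment_mode(pairing, conc_config)
        assert out["mode"] == "modeA"
        assert out["reasons"] == []

    def test_lost_clonal_mutation_is_mode_b(self, conc_config):
        rows = [(i, 20, 50, 21, 50) for i in range(5)] + [(9, 22, 50, 0, 0)]
        pairing = _pairing_from_reads(rows, conc_config)
        out = V.classify_engraftment_mode(pairing, conc_config)
        assert out["mode"] == "modeB"
        assert "clonal_loss" in out["reasons"]

    def test_strong_subclone_amplification_is_mode_b(self, conc_config):
        # subclone at AF 0.05 sweeping to AF 0.45 in the PDX
        rows = [(i, 20, 50, 21, 50) for i in range(5)] + [
            (10, 10, 200, 90, 200),
            (11, 11, 200, 88, 200),
        ]
        pairing = _pairing_from_reads(rows, conc_config)
        out = V.classify_engraftment_mode(pairing, conc_config)
        assert out["mode"] == "modeB"
        assert "af_shift" in out["reasons"]

    def test_pdx_specific_clonal_cluster_is_mode_b(self, conc_config):
        rows = [(i, 20, 50, 21, 50) for i in range(5)] + [
            (10, 0, 0, 22, 50),
            (11, 0, 0, 23, 50),
        ]
        pairing = _pairing_from_reads(rows, conc_config)
        out = V.classify_engraftment_mode(pairing, conc_config)
        assert out["mode"] == "modeB"
        assert "subclone_selection" in out["reasons"]

    def test_missing_pdx_sample_rejected(self, conc_config):
        rows = [(1, 20, 50, 0, 0)]
        pairing = _pairing_from_reads(rows, conc_config)
        with pytest.raises(ValueError):
            V.classify_engraftment_mode(pairing, conc_config)


class TestCohortDirectionInvariant:
    def test_clonal_preservation_exceeds_subclonal_on_synthetic_cohort(self):
        from pdxfid.config import SimulationConfig
        from pdxfid.simulate import simulate_cohort

        cfg = SimulationConfig(n_patients=8)
        ccfg = ConcordanceConfig()
        cohort = simulate_cohort(cfg, seed=17)
        pairings = []
        for pt in cohort:
            allrec = pd.concat(pt["tables"].values(), ignore_index=True)
            filt = V.apply_detection_filters(allrec, ccfg)
            for tp in ("INI", "REL"):
                pri = filt[(filt.timepoint == tp) & (filt.origin == "PRI")]
                pdx = filt[(filt.timepoint == tp) & (filt.origin == "PDX")]
                if len(pri) and len(pdx):
                    pairings.append(V.pair_variants(pri, pdx, ccfg))
        summary = V.preservation_summary(
            pd.concat(pairings, ignore_index=True), ccfg
        ).set_index(["scope", "group"])
        clonal = summary.loc[("clonality", "clonal"), "fraction"]
        subclonal = summary.loc[("clonality", "subclonal"), "fraction"]
        assert clonal >= subclonal
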