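import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyldriver import methylome
from methyldriver.io_formats import CPG_REGIONS, GENE_REGIONS, ProbeAnnotation

from _oracles import pooled_t_p_value
from conftest import make_beta


class TestComputeBeta:
    @pytest.mark.parametrize(
        "meth,unmeth,expected",
        [
            (0.0, 0.0, 0.0),            # zero numerator
            (-50.0, 200.0, 0.0),        # negative channel clamped
            (400.0, 100.0, 400.0 / 600.0),
            (100.0, -30.0, 0.5),        # negative unmethylated clamped too
        ],
    )
    def test_known_values(self, meth, unmeth, expected):
        out = methylome.compute_beta(np.array([[meth]]), np.array([[unmeth]]))
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_dataframe_in_dataframe_out(self, small_sheet):
        m = make_beta(np.full((2, 5), 300.0), small_sheet)
        u = make_beta(np.full((2, 5), 100.0), small_sheet)
        beta = methylome.compute_beta(m, u)
        assert isinstance(beta, pd.DataFrame)
        assert list(beta.columns) == list(small_sheet.sample_ids)
        assert np.allclose(beta.to_numpy(), 0.6)

    def test_non_finite_names_probe_and_sample(self, small_sheet):
        m = make_beta(np.full((2, 5), 300.0), small_sheet, ["cgA", "cgB"])
        u = make_beta(np.full((2, 5), 100.0), small_sheet, ["cgA", "cgB"])
        u.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="cgB"):
            methylome.compute_beta(m, u)

    def test_offset_must_be_positive(self):
        with pytest.raises(ValueError):
            methylome.compute_beta(np.array([1.0]), np.array([1.0]), offset=0)

    @settings(deadline=None, max_examples=200)
    @given(
        m=st.floats(-1e6, 1e6, allow_nan=False),
        u=st.floats(-1e6, 1e6, allow_nan=False),
        dm=st.floats(0.0, 1e4),
    )
    def test_range_and_monotonicity(self, m, u, dm):
        """Beta is in [0,1), increases with methylated and decreases with
        unmethylated signal."""
        b = float(methylome.compute_beta(np.array([m]), np.array([u]))[0])
        assert 0.0 <= b < 1.0
        b_up = float(methylome.compute_beta(np.array([m + dm]), np.array([u]))[0])
        assert b_up >= b
        b_down = float(methylome.compute_beta(np.array([m]), np.array([u + dm]))[0])
        assert b_down <= b


class TestPooledTTest:
    def test_matches_textbook_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), 1, n2)
            _, p = methylome.pooled_t_test(a[None, :], b[None, :])
            assert p[0] == pytest.approx(pooled_t_p_value(list(a), list(b)), abs=1e-10)

    def test_zero_variance_equal_means_gives_p_one(self):
        _, p = methylome.pooled_t_test(np.array([[0.8, 0.8, 0.8]]), np.array([[0.8, 0.8]]))
        assert p[0] == 1.0

    def test_zero_variance_different_means_gives_p_zero(self):
        _, p = methylome.pooled_t_test(np.array([[0.8, 0.8, 0.8]]), np.array([[0.2, 0.2]]))
        assert p[0] == 0.0


class TestProbeScreen:
    def test_zero_delta_not_flagged(self, small_sheet):
        beta = make_beta([[0.8, 0.8, 0.8, 0.8, 0.8]], small_sheet)
        out = methylome.test_probes(beta, small_sheet)
        assert out.loc[0, "delta_beta"] == pytest.approx(0.0, abs=1e-12)
        assert not out.loc[0, "flagged"]

    def test_strong_hyper_probe_flagged_with_oracle_p(self, small_sheet):
        case, control = [0.9, 0.8, 0.85], [0.2, 0.25]
        beta = make_beta([case + control], small_sheet)
        out = methylome.test_probes(beta, small_sheet)
        assert out.loc[0, "flagged"]
        assert out.loc[0, "direction"] == "HYPER"
        assert out.loc[0, "p_value"] == pytest.approx(
            pooled_t_p_value(case, control), abs=1e-10
        )

    def test_impossible_threshold_flags_nothing(self, small_sheet):
        rng = np.random.default_rng(3)
        beta = make_beta(rng.uniform(0, 1, (50, 5)), small_sheet)
        out = methylome.test_probes(beta, small_sheet, dbeta_min=1.1)
        assert not out["flagged"].any()

    def test_label_swap_negates_delta_keeps_p(self, small_sheet):
        rng = np.random.default_rng(4)
        beta = make_beta(rng.uniform(0, 1, (30, 5)), small_sheet)
        fwd = methylome.test_probes(beta, small_sheet)
        rev = methylome.test_probes(beta, small_sheet.swapped())
        np.testing.assert_allclose(rev["delta_beta"], -fwd["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(rev["p_value"], fwd["p_value"], atol=1e-12)
        nonzero = fwd["delta_beta"] != 0
        assert (fwd.loc[nonzero, "direction"] != rev.loc[nonzero, "direction"]).all()


def annot_for(probes, genes, gene_regions, cpg_regions):
    return ProbeAnnotation(pd.DataFrame(
        {"gene": genes, "gene_region": gene_regions, "cpg_region": cpg_regions},
        index=pd.Index(probes, name="probe_id"),
    ))


class TestRegionAggregation:
    def test_single_probe_region_is_identity(self, small_sheet):
        beta = make_beta([[0.1, 0.2, 0.3, 0.4, 0.5]], small_sheet, ["cg1"])
        annot = annot_for(["cg1"], ["G1"], ["TSS200"], ["ISLAND"])
        region = methylome.aggregate_regions(beta, annot)
        np.testing.assert_allclose(region.loc[("G1", "TSS200")], beta.loc["cg1"])

    def test_mean_of_two_probes(self, small_sheet):
        beta = make_beta([[0.2] * 5, [0.4] * 5], small_sheet, ["cg1", "cg2"])
        annot = annot_for(["cg1", "cg2"], ["G1"] * 2, ["BODY"] * 2, ["OPEN_SEA"] * 2)
        region = methylome.aggregate_regions(beta, annot)
        assert np.allclose(region.loc[("G1", "BODY")], 0.3)

    def test_probe_order_invariance(self, small_sheet):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (6, 5))
        probes = [f"cg{i}" for i in range(6)]
        annot = annot_for(probes, ["G1", "G2"] * 3,
                          ["TSS200", "BODY", "TSS200", "BODY", "TSS200", "BODY"],
                          ["ISLAND"] * 6)
        beta = make_beta(vals, small_sheet, probes)
        perm = rng.permutation(6)
        beta_perm = beta.iloc[perm]
        r1 = methylome.aggregate_regions(beta, annot)
        r2 = methylome.aggregate_regions(beta_perm, annot)
        pd.testing.assert_frame_equal(r1, r2)

    def test_intergenic_probes_excluded(self, small_sheet):
        beta = make_beta([[0.5] * 5, [0.9] * 5], small_sheet, ["cg1", "cg2"])
        annot = annot_for(["cg1", "cg2"], ["G1", ""], ["BODY", "BODY"], ["OPEN_SEA"] * 2)
        region = methylome.aggregate_regions(beta, annot)
        assert len(region) == 1

    def test_probe_missing_from_manifest_is_error(self, small_sheet):
        beta = make_beta([[0.5] * 5], small_sheet, ["cg_unknown"])
        annot = annot_for(["cg1"], ["G1"], ["BODY"], ["OPEN_SEA"])
        with pytest.raises(ValueError, match="cg_unknown"):
            methylome.aggregate_regions(beta, annot)

    def test_cpg_scheme_groups_by_island_class(self, small_sheet):
        beta = make_beta([[0.2] * 5, [0.4] * 5], small_sheet, ["cg1", "cg2"])
        annot = annot_for(["cg1", "cg2"], ["G1"] * 2, ["TSS200", "BODY"], ["ISLAND"] * 2)
        region = methylome.aggregate_regions(beta, annot, methylome.CPG_REGION)
        assert list(region.index) == [("G1", "ISLAND")]
        assert np.allclose(region.iloc[0], 0.3)


class TestRegionScreen:
    def test_constructed_separation_flagged(self, small_sheet):
        regions = pd.DataFrame(
            [[0.8, 0.8, 0.8, 0.2, 0.2]],
            index=pd.MultiIndex.from_tuples([("G1", "TSS200")],
                                            names=["gene", "region_class"]),
            columns=list(small_sheet.sample_ids),
        )
        out = methylome.test_regions(regions, small_sheet, dbeta_min=0.5)
        row = out.iloc[0]
        assert row["delta_beta"] == pytest.approx(0.6)
        assert row["direction"] == "HYPER"
        assert row["p_value"] == 0.0  # zero-variance, unequal means
        assert row["flagged"]

    def test_config_threshold_respected(self, small_sheet):
        regions = pd.DataFrame(
            [[0.8, 0.8, 0.8, 0.2, 0.2]],
            index=pd.MultiIndex.from_tuples([("G1", "TSS200")],
                                            names=["gene", "region_class"]),
            columns=list(small_sheet.sample_ids),
        )
        out = methylome.test_regions(regions, small_sheet, dbeta_min=0.65)
        assert not out.iloc[0]["flagged"]

    def test_p_values_match_oracle_on_simulated_regions(self, cohort_sheet):
        rng = np.random.default_rng(6)
        n = 50
        case = 0.5 + rng.normal(0.3, 0.05, (n, 5))
        control = 0.5 + rng.normal(0.0, 0.05, (n, 6))
        regions = pd.DataFrame(
            np.hstack([case, control]),
            index=pd.MultiIndex.from_tuples(
                [(f"G{i}", "TSS200") for i in range(n)], names=["gene", "region_class"]
            ),
            columns=list(cohort_sheet.sample_ids),
        )
        out = methylome.test_regions(regions, cohort_sheet, dbeta_min=0.1)
        for i in range(n):
            expect = pooled_t_p_value(list(case[i]), list(control[i]))
            assert out.iloc[i]["p_value"] == pytest.approx(expect, abs=1e-10)


class TestRegionDistribution:
    def test_empty_input_enumerates_all_classes_with_zeros(self):
        out = methylome.summarize_region_distribution(pd.DataFrame(columns=["direction", "region_class"]))
        assert out.shape == (2, len(GENE_REGIONS) + len(CPG_REGIONS))
        assert (out.to_numpy() == 0).all()

    def test_counts_and_conservation(self):
        dmrs = pd.DataFrame({
            "direction": ["HYPO", "HYPO", "HYPO", "HYPER"],
            "region_class": ["N_SHELF", "N_SHELF", "N_SHELF", "ISLAND"],
        })
        out = methylome.summarize_region_distribution(dmrs)
        assert out.loc["HYPO", "N_SHELF"] == 3
        assert out.loc["HYPER", "ISLAND"] == 1
        assert out.to_numpy().sum() == len(dmrs)
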