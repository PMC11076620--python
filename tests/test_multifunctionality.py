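"""MLRR machinery: LRR oracle values, service aggregation, scale invariance,
antisymmetry, percent effects, bootstrap contracts, and the comparison
indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grassmf import multifunctionality as mf
from grassmf.services import default_service_map, service_weight_matrix
from grassmf.synthetic_data import ASPECTS


def _toy_map(rows):
    return pd.DataFrame(
        rows, columns=["indicator", "cices_service", "category", "disservice_flag", "log_flag"]
    )


class TestLrr:
    def test_oracle_values(self):
        t, r = np.full(10, 2.0), np.full(10, 1.0)
        assert mf.lrr(t, r) == pytest.approx(np.log(2.0), abs=1e-12)
        assert mf.lrr(t, r, disservice=True) == pytest.approx(-np.log(2.0), abs=1e-12)
        assert mf.lrr(t, t) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mf.lrr(np.array([]), np.array([1.0]))

    def test_zero_guard_offsets_zero_means(self):
        t = np.array([0.0, 0.0, 4.0])
        r = np.array([0.0, 2.0, 2.0])
        value = mf.lrr(t, r)  # guard: +0.5*min positive = +1
        assert value == pytest.approx(np.log((4 / 3 + 1) / (4 / 3 + 1)), abs=1e-12)

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            mf.lrr(np.zeros(3), np.ones(3), zero_guard=False)

    @given(st.floats(min_value=0.1, max_value=10.0), st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetry_under_group_swap(self, a, b):
        t, r = np.full(5, a), np.full(5, b)
        assert mf.lrr(t, r) == pytest.approx(-mf.lrr(r, t), abs=1e-12)


class TestAggregation:
    def test_service_mean(self):
        smap = _toy_map(
            [
                ("i1", "s1", "provisioning", False, False),
                ("i2", "s1", "provisioning", False, False),
                ("i3", "s2", "cultural", False, False),
            ]
        )
        svc = mf.aggregate_services(pd.Series({"i1": 0.2, "i2": 0.4, "i3": 0.7}), smap)
        assert svc["s1"] == pytest.approx(0.3)
        assert svc["s2"] == pytest.approx(0.7)  # single-member pass-through

    def test_unmapped_indicator_rejected(self, service_map):
        with pytest.raises(ValueError, match="mystery"):
            mf.aggregate_services(pd.Series({"mystery": 0.1}), service_map)

    def test_grand_mean_equals_weighted_indicator_mean(self, service_map):
        rng = np.random.default_rng(0)
        ind = pd.Series(rng.normal(size=22), index=service_map["indicator"])
        svc = mf.aggregate_services(ind, service_map)
        members = service_map.groupby("cices_service")["indicator"].count()
        weights = service_map.set_index("indicator")["cices_service"].map(members)
        weighted = (ind / weights).sum() / members.size
        assert mf.mlrr(svc) == pytest.approx(weighted, abs=1e-12)

    def test_overall_differs_from_category_mean_when_unbalanced(self):
        """Counterexample: with unequal service counts per category, the
        overall MLRR is not the mean of the category MLRRs."""
        smap = _toy_map(
            [
                ("i1", "s1", "provisioning", False, False),
                ("i2", "s2", "cultural", False, False),
                ("i3", "s3", "cultural", False, False),
                ("i4", "s4", "cultural", False, False),
            ]
        )
        svc = mf.aggregate_services(
            pd.Series({"i1": 0.8, "i2": 0.0, "i3": 0.1, "i4": 0.2}), smap
        )
        overall = mf.mlrr(svc)
        cats = mf.category_mlrrs(svc, smap)
        assert overall != pytest.approx(cats.mean())

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            mf.mlrr(pd.Series({"s1": 0.1}), services=[])


class TestPercentEffect:
    @pytest.mark.parametrize(
        "m, expected",
        [(0.0, 0.0), (np.log(1.43), 43.0), (np.log(0.60), -40.0)],
    )
    def test_oracle_values(self, m, expected):
        assert mf.percent_effect(m) == pytest.approx(expected, abs=1e-9)

    def test_consistency_with_mlrr(self):
        m = 0.37
        assert np.log(1 + mf.percent_effect(m) / 100) == pytest.approx(m, abs=1e-10)


class TestInvariances:
    def test_mlrr_scale_invariance(self, study_dataset, service_map):
        """Max-scaling each indicator leaves every LRR and MLRR unchanged
        (common positive factors cancel in the ratio)."""
        from grassmf.preprocessing import max_scale

        design, _, indicators = study_dataset
        for aspect in ASPECTS:
            raw = mf.indicator_lrrs(indicators, design, aspect, service_map)
            scaled = mf.indicator_lrrs(max_scale(indicators), design, aspect, service_map)
            assert np.abs(raw - scaled).max() < 1e-12

    def test_antisymmetry_of_full_hierarchy(self, study_dataset, service_map):
        """Swapping treated and reference levels negates LRRs, MLRRs, and
        maps percent p to 100 (1/(1+p/100) - 1)."""
        design, _, indicators = study_dataset
        flipped = design.copy()
        flipped["eco_scheme"] = flipped["eco_scheme"].map({"yes": "no", "no": "yes"})
        fwd = mf.indicator_lrrs(indicators, design, "eco_scheme", service_map)
        rev = mf.indicator_lrrs(indicators, flipped, "eco_scheme", service_map)
        assert np.abs(fwd + rev).max() < 1e-12
        m_f = mf.mlrr(mf.aggregate_services(fwd, service_map))
        m_r = mf.mlrr(mf.aggregate_services(rev, service_map))
        assert m_f == pytest.approx(-m_r, abs=1e-12)
        p_f, p_r = mf.percent_effect(m_f), mf.percent_effect(m_r)
        assert p_r == pytest.approx(100 * (1 / (1 + p_f / 100) - 1), abs=1e-9)

    def test_exp_overall_equals_geometric_mean_of_service_ratios(
        self, study_dataset, service_map
    ):
        design, _, indicators = study_dataset
        svc = mf.aggregate_services(
            mf.indicator_lrrs(indicators, design, "eco_scheme", service_map), service_map
        )
        geo = np.exp(np.mean(svc))
        assert np.exp(mf.mlrr(svc)) == pytest.approx(geo, abs=1e-12)


class TestBootstrap:
    def test_null_configuration_ci_straddles_zero(self, large_null_dataset, service_map):
        design, _, indicators = large_null_dataset
        _, overall_ci, _ = mf.bootstrap_ci(
            indicators, design, "eco_scheme", service_map, B=1000, seed=1
        )
        assert overall_ci[0] <= 0 <= overall_ci[1]

    def test_single_replicate_degenerate_interval(self, study_dataset, service_map):
        design, _, indicators = study_dataset
        _, overall_ci, _ = mf.bootstrap_ci(
            indicators, design, "eco_scheme", service_map, B=1, seed=2
        )
        assert overall_ci[0] == pytest.approx(overall_ci[1])

    def test_seed_determinism(self, study_dataset, service_map):
        design, _, indicators = study_dataset
        a = mf.bootstrap_ci(indicators, design, "harvest_type", service_map, B=200, seed=3)
        b = mf.bootstrap_ci(indicators, design, "harvest_type", service_map, B=200, seed=3)
        assert a == b

    @pytest.mark.parametrize("unit", ["plot", "pair"])
    def test_ci_contains_point_estimate(self, study_dataset, service_map, unit):
        design, _, indicators = study_dataset
        rep = mf.multifunctionality_report(
            indicators, design, "eco_scheme", service_map, B=2000, seed=4, unit=unit
        )
        lo, hi = rep.overall_ci
        assert lo <= rep.overall_mlrr <= hi
        for c, (clo, chi) in rep.category_ci.items():
            assert clo <= rep.category_mlrr[c] <= chi

    def test_invalid_unit_rejected(self, study_dataset, service_map):
        design, _, indicators = study_dataset
        with pytest.raises(ValueError):
            mf.bootstrap_ci(indicators, design, "eco_scheme", service_map, B=10, unit="farm")


class TestReport:
    def test_report_consistency(self, study_dataset, service_map):
        design, _, indicators = study_dataset
        rep = mf.multifunctionality_report(
            indicators, design, "harvest_type", service_map, B=500, seed=5
        )
        assert len(rep.service_lrr) == service_map["cices_service"].nunique()
        # percent effects consistent with their MLRRs to 1e-10
        for c, val in rep.category_mlrr.items():
            assert rep.percent_effects[c] == pytest.approx(
                mf.percent_effect(val), abs=1e-10
            )
        frame = rep.to_frame()
        assert set(frame["scope"]) == {"service", "category", "overall"}

    def test_livestock_dominance_flagged_for_pasture(self, study_dataset, service_map):
        """Under the default effect pattern the cultural category of the
        pasture contrast is dominated by the heritage service."""
        design, _, indicators = study_dataset
        rep = mf.multifunctionality_report(
            indicators, design, "harvest_type", service_map, B=10, seed=6
        )
        flags = mf.dominance_flags(rep, service_map)
        assert bool(flags["cultural"])


class TestComparatorIndices:
    def test_averaging_index_row_mean_and_permutation_invariance(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.2, 0.5, 0.8], [0.8, 0.2, 0.5]])
        idx = mf.averaging_index(m)
        assert idx[0] == pytest.approx(1.0)
        assert idx[1] == pytest.approx(idx[2])  # permuted values, same mean

    def test_averaging_index_information_loss(self):
        """Opposite deviations cancel: (0.4, 0.6) and (0.5, 0.5) share the
        same average -- the transparency argument for the MLRR."""
        m = pd.DataFrame([[0.4, 0.6], [0.5, 0.5]])
        idx = mf.averaging_index(m)
        assert idx[0] == pytest.approx(idx[1]) == pytest.approx(0.5)

    def test_averaging_index_missing_rejected(self):
        with pytest.raises(ValueError):
            mf.averaging_index(pd.DataFrame([[1.0, np.nan]]))

    def test_estimate_index_constants(self, service_map):
        rows = []
        for pred, value in [("eco_scheme", 0.0), ("harvest_type", 0.3)]:
            for ind in service_map["indicator"]:
                rows.append({"indicator": ind, "predictor": pred, "estimate": value})
        idx = mf.estimate_index(pd.DataFrame(rows), service_map)
        assert idx["eco_scheme"] == pytest.approx(0.0)
        assert idx["harvest_type"] == pytest.approx(0.3)

    def test_estimate_index_concordant_with_mlrr(self, study_dataset, service_map):
        """The model-estimate comparator ranks the aspects like the MLRR on
        the default synthetic study."""
        from grassmf.latent_model import build_design_matrix, effect_table, fit_gllvm
        from grassmf.preprocessing import preprocess_indicators

        design, _, indicators = study_dataset
        pre = preprocess_indicators(indicators, service_map).set_axis(design.index)
        fit = fit_gllvm(pre, build_design_matrix(design), blocks=design["pair_id"], seed=0)
        est = mf.estimate_index(
            effect_table(fit)[lambda t: t["predictor"].isin(ASPECTS)], service_map
        )
        mls = {
            a: mf.mlrr(
                mf.aggregate_services(
                    mf.indicator_lrrs(indicators, design, a, service_map), service_map
                )
            )
            for a in ASPECTS
        }
        assert est.sort_values().index.tolist() == pd.Series(mls).sort_values().index.tolist()


def test_service_weight_matrix_rows_sum_to_one(service_map):
    a = service_weight_matrix(service_map)
    assert a.shape == (12, 22)
    assert np.allclose(a.sum(axis=1), 1.0)
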