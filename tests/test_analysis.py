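import numpy as np
import pandas as pd
import pytest

from autobend import (BendingConfig, SensitivityDesign,
                      StiffnessInputs, aggregate_directions,
                      estimate_stiffness, normalize_stiffness,
                      run_sensitivity, tally_constraints,
                      variance_decomposition)
from oracles import projection_sequential_ss


class TestAggregation:
    def test_lateral_is_left_plus_right(self):
        angles = {"left-lateral": 10.0, "right-lateral": 12.0,
                  "left-axial": 0.0, "right-axial": 0.0,
                  "dorsiflexion": 0.0, "ventroflexion": 0.0}
        assert aggregate_directions(angles).lateral == 22.0

    def test_sagittal_is_dorsi_plus_ventro(self):
        angles = dict.fromkeys(
            ["left-lateral", "right-lateral", "left-axial", "right-axial"], 0.0)
        angles.update(dorsiflexion=5.0, ventroflexion=7.0)
        agg = aggregate_directions(angles)
        assert agg.sagittal == 12.0 and agg.lateral == 0.0 and agg.axial == 0.0

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate_directions({"left-lateral": 1.0})

    def test_exact_identities_from_engine(self, block, intersection_only):
        from autobend import run_all_directions
        segment, _ = block
        res = run_all_directions(segment, intersection_only)
        agg = aggregate_directions(res)
        a = res.stop_angles()
        assert agg.lateral == a["left-lateral"] + a["right-lateral"]
        assert agg.axial == a["left-axial"] + a["right-axial"]
        assert agg.sagittal == a["dorsiflexion"] + a["ventroflexion"]


class TestTally:
    def _table(self, labels, direction="left-lateral"):
        return pd.DataFrame({"direction": [direction] * len(labels),
                             "constraint_label": labels})

    def test_single_label(self):
        props = tally_constraints(self._table(["max-angle"] * 5))
        assert props.loc["lateroflexion", "max-angle"] == 1.0

    def test_proportions(self):
        props = tally_constraints(
            self._table(["intersection"] * 6 + ["centrum-tension"] * 2))
        assert props.loc["lateroflexion", "intersection"] == pytest.approx(0.75)
        assert props.loc["lateroflexion", "centrum-tension"] == pytest.approx(0.25)

    def test_rows_counted_once_and_sum_to_one(self):
        # priority-resolved labels: each run contributes exactly once
        df = pd.DataFrame({
            "direction": ["dorsiflexion"] * 4 + ["ventroflexion"] * 4,
            "constraint_label": ["intersection", "zyg-overlap", "zyg-overlap",
                                 "max-angle", "zyg-disarticulation"] * 1
            + ["zyg-disarticulation"] * 3})
        props = tally_constraints(df)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            tally_constraints(pd.DataFrame())


class TestSensitivity:
    def test_default_design_has_eight_variants(self):
        assert len(list(SensitivityDesign().variants())) == 8

    def test_single_parameter_design_has_two(self):
        d = SensitivityDesign(spacing_levels=None, strain_levels=None)
        assert len(list(d.variants())) == 2

    def test_no_varied_parameters_single_base_variant(self):
        d = SensitivityDesign(spacing_levels=None, intersection_levels=None,
                              strain_levels=None)
        assert [lab for lab, _ in d.variants()] == ["base"]

    def test_threshold_and_strain_widening_dominates(self, block):
        """Holding spacing fixed, the high-threshold/high-strain variant
        allows at least as much motion as the low/low variant."""
        segment, _ = block
        design = SensitivityDesign(spacing_levels=None)
        table = run_sensitivity(segment, design, BendingConfig())
        lo = table[table.run_variant == "intersection=low,strain=low"]
        hi = table[table.run_variant == "intersection=high,strain=high"]
        merged = lo.merge(hi, on="direction", suffixes=("_lo", "_hi"))
        assert (merged.stop_angle_hi >= merged.stop_angle_lo).all()


class TestVarianceDecomposition:
    def _balanced(self, seed=11, reps=1):
        rng = np.random.default_rng(seed)
        rows = []
        for j in ("j1", "j2"):
            for d in ("lat", "sag", "ax"):
                for s in ("low", "high"):
                    for t in ("low", "high"):
                        for _ in range(reps):
                            rows.append({"joint": j, "direction": d,
                                         "spacing": s, "intersection": t,
                                         "stop_angle": rng.normal(10, 3)})
        return pd.DataFrame(rows)

    def test_constant_response_all_zero(self):
        df = self._balanced()
        df["stop_angle"] = 7.0
        out = variance_decomposition(df, params=("spacing", "intersection"))
        assert np.allclose(out["sum_sq"], 0.0, atol=1e-9)

    def test_single_binary_factor_closed_form(self):
        # n = 4 per level, level means differ by delta = 2 -> SS = n*delta^2/2
        df = pd.DataFrame({"joint": ["a", "b"] * 4,
                           "stop_angle": [1.0, 3.0] * 4})
        out = variance_decomposition(df, factors=("joint",), params=(),
                                     interaction=False)
        assert out.loc["joint", "sum_sq"] == pytest.approx(8.0)

    def test_matches_projection_oracle(self):
        df = self._balanced(seed=5, reps=2)
        out = variance_decomposition(df, params=("spacing", "intersection"))
        oracle = projection_sequential_ss(
            df, "stop_angle",
            [["joint"], ["direction"], ["joint", "direction"],
             ["spacing"], ["intersection"]])
        for name, ss in oracle.items():
            got = float(out.loc[name, "sum_sq"])
            assert got == pytest.approx(ss, rel=1e-6, abs=1e-8), name

    def test_total_ss_is_partitioned(self):
        df = self._balanced(seed=3)
        out = variance_decomposition(df, params=("spacing", "intersection"))
        total = ((df.stop_angle - df.stop_angle.mean()) ** 2).sum()
        assert out["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
        assert (out["sum_sq"] >= -1e-12).all()

    def test_unbalanced_rejected(self):
        df = self._balanced().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            variance_decomposition(df, params=("spacing", "intersection"))


class TestStiffness:
    def test_printed_arithmetic_worked_example(self):
        res = estimate_stiffness(StiffnessInputs(8, 10, 3, 15, 12),
                                 printed_arithmetic=True)
        assert res.force == 716
        assert res.sagittal == 334
        assert res.lateral == 298

    def test_inverse_proportionality_to_orom(self):
        res = estimate_stiffness(StiffnessInputs(8, 10, 3, 30, 12),
                                 printed_arithmetic=True)
        assert res.sagittal == 167

    def test_small_analytic_case(self):
        # h=w=2: force = 4^1.5 = 8; arms 1, 1; oROM 8 -> stiffness 1, 1
        res = estimate_stiffness(StiffnessInputs(2, 2, 0, 8, 8))
        assert res.force == pytest.approx(8.0)
        assert res.sagittal == pytest.approx(1.0)
        assert res.lateral == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 3.7])
    def test_c4_homogeneity(self, c):
        base = estimate_stiffness(StiffnessInputs(8, 10, 3, 15, 12))
        scaled = estimate_stiffness(StiffnessInputs(8 * c, 10 * c, 3 * c,
                                                    15, 12))
        assert scaled.sagittal == pytest.approx(base.sagittal * c ** 4,
                                                rel=1e-12)
        assert scaled.lateral == pytest.approx(base.lateral * c ** 4,
                                               rel=1e-12)

    def test_zero_orom_rejected(self):
        with pytest.raises(ValueError):
            StiffnessInputs(8, 10, 3, 0, 12)


class TestNormalization:
    def test_log_then_divide(self):
        out = normalize_stiffness([1000.0], 10.0, "log-then-divide")
        assert out[0] == pytest.approx(0.3)

    def test_divide_then_log(self):
        out = normalize_stiffness([10.0], 10.0, "divide-then-log")
        assert out[0] == pytest.approx(0.0)

    def test_both_modes_preserve_rank_order(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 1e4, 20)
        order = np.argsort(vals)
        for mode in ("log-then-divide", "divide-then-log"):
            out = normalize_stiffness(vals, 12.5, mode)
            assert np.array_equal(np.argsort(out), order)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            normalize_stiffness([0.0], 10.0)
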