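"""Aux, toxicity, reversibility, dependence, and SDL score semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import zevphen as z


def _aux_table(**kwargs):
    base = {"strain_id": ["s"], "G_M0": [100.0], "G_M1": [100.0],
            "G_R0": [100.0], "G_R1": [100.0]}
    base.update({k: [v] for k, v in kwargs.items()})
    return pd.DataFrame(base)


class TestAuxScore:
    def test_equal_ratios_score_one(self):
        out = z.aux_scores(_aux_table())
        assert out["aux_score"].iloc[0] == 1.0

    def test_ratio_of_ratios(self):
        out = z.aux_scores(_aux_table(G_M1=400.0, G_M0=100.0, G_R1=300.0, G_R0=300.0))
        assert out["aux_score"].iloc[0] == pytest.approx(4.0)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.1, 1e4),
           st.floats(0.1, 1e4), st.floats(0.5, 20.0))
    def test_scale_invariance(self, m0, m1, r0, r1, scale):
        a = z.aux_scores(_aux_table(G_M0=m0, G_M1=m1, G_R0=r0, G_R1=r1))
        b = z.aux_scores(
            _aux_table(G_M0=m0 * scale, G_M1=m1 * scale, G_R0=r0 * scale, G_R1=r1 * scale)
        )
        assert a["aux_score"].iloc[0] == pytest.approx(b["aux_score"].iloc[0], rel=1e-9)

    def test_zero_growth_floored_and_flagged(self):
        out = z.aux_scores(_aux_table(G_M0=0.0))
        assert out["floored_flag"].iloc[0]
        assert out["aux_score"].iloc[0] > 0

    def test_missing_condition_omitted_with_warning(self):
        tab = _aux_table()
        tab.loc[0, "G_R1"] = np.nan
        with pytest.warns(UserWarning, match="omitted"):
            out = z.aux_scores(tab)
        assert len(out) == 0

    def test_output_sorted_descending(self):
        tab = pd.concat(
            [_aux_table(strain_id="lo"), _aux_table(strain_id="hi", G_M1=500.0)],
            ignore_index=True,
        )
        out = z.aux_scores(tab)
        assert out["strain_id"].tolist() == ["hi", "lo"]


class TestToxicityCall:
    def test_points_on_line_have_zero_distance(self):
        x = pd.Series(np.linspace(1000, 20000, 200))
        res = z.toxicity_call(x, 0.7 * x + 30.0)
        assert res["distance"].abs().max() < 1e-6
        assert not res["toxic_flag"].any()

    def test_hand_worked_example(self):
        # fit slope 0.5, intercept 0 (the outlier x=4000, y=500 sits in the
        # trimmed bottom tail, so the fit is exact on the on-line points)
        x = pd.Series(np.linspace(5000, 50000, 200))
        y = 0.5 * x
        x_all = pd.concat([x, pd.Series([4000.0])], ignore_index=True)
        y_all = pd.concat([y, pd.Series([500.0])], ignore_index=True)
        res = z.toxicity_call(x_all, y_all)
        row = res.iloc[-1]
        assert row["y_corrected"] == pytest.approx(1000.0, rel=1e-3)
        assert row["distance"] == pytest.approx(3000.0 / np.sqrt(2), rel=1e-3)
        assert bool(row["toxic_flag"])  # 2121 > 2000 and below the diagonal

    def test_perfect_diagonal_flags_nothing(self):
        x = pd.Series(np.linspace(1000, 20000, 100))
        res = z.toxicity_call(x, x.copy())
        assert not res["toxic_flag"].any()

    def test_above_diagonal_never_toxic(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.uniform(5000, 20000, 300))
        y = x * 1.0
        y.iloc[0] = x.iloc[0] + 8000.0  # strong *improvement*
        res = z.toxicity_call(x, y)
        assert not res["toxic_flag"].iloc[0]

    def test_synthetic_screen_performance(self):
        df = z.toxicity_screen(5000, toxic_fraction=0.05, seed=11)
        res = z.toxicity_call(df["growth_0nM"], df["growth_100nM"])
        called = res["toxic_flag"].to_numpy()
        truth = df["is_toxic"].to_numpy()
        tp = (called & truth).sum()
        sens = tp / truth.sum()
        fdp = (called & ~truth).sum() / max(called.sum(), 1)
        assert sens >= 0.9
        assert fdp <= 0.1

    def test_too_few_strains_rejected(self):
        x = pd.Series(np.linspace(1, 10, 10))
        with pytest.raises(ValueError, match=">= 50"):
            z.toxicity_call(x, x)

    def test_degenerate_fit_aborts(self):
        x = pd.Series(np.linspace(1000, 2000, 100))
        y = pd.Series(np.linspace(2000, 1000, 100))  # negative slope
        with pytest.raises(RuntimeError, match="degenerate"):
            z.toxicity_call(x, y)


class TestReversibility:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.40, "reversible"),
            (0.55, "reversible"),
            (0.60, "partially_reversible"),
            (0.75, "partially_reversible"),
            (0.80, "not_reversible"),
        ],
    )
    def test_printed_cutoff_semantics(self, ratio, expected):
        out = z.classify_reversibility([ratio], [1.0])
        assert out["class"].iloc[0] == expected

    def test_zero_denominator_flagged_undefined(self):
        out = z.classify_reversibility([1.0], [0.0])
        assert out["class"].iloc[0] == "undefined"


class TestDependence:
    def test_no_growth(self):
        s = pd.Series({0.0: 0.01, 100.0: 0.02})
        assert z.classify_dependence(s) == "no_growth"

    def test_classes_by_fraction_at_zero(self):
        mk = lambda f0: pd.Series({0.0: f0, 100.0: 1.0})
        assert z.classify_dependence(mk(0.05)) == "dependent"
        assert z.classify_dependence(mk(0.5)) == "partially_dependent"
        assert z.classify_dependence(mk(0.9)) == "constitutive"

    def test_single_dose_refused(self):
        with pytest.raises(ValueError):
            z.classify_dependence(pd.Series({0.0: 1.0}))


class TestSDL:
    def _table(self, r1, r2):
        return pd.DataFrame(
            {
                "array_gene": ["g", "g"],
                "replicate": [1, 2],
                "size_1000": [r1, r2],
                "size_0": [1.0, 1.0],
            }
        )

    def test_neutral_ratio_not_called(self):
        out = z.sdl_call(self._table(1.0, 1.0))
        assert not out["sdl_flag"].iloc[0]

    def test_consistent_mild_depletion_called(self):
        # log2(0.9) = -0.152 < -0.08 in both replicates
        out = z.sdl_call(self._table(0.9, 0.9))
        assert out["sdl_flag"].iloc[0]

    def test_single_replicate_hit_not_called(self):
        out = z.sdl_call(self._table(0.9, 1.1))
        assert not out["sdl_flag"].iloc[0]

    def test_zero_denominator_excludes_gene(self):
        tab = self._table(0.9, 0.9)
        tab.loc[0, "size_0"] = 0.0
        out = z.sdl_call(tab)
        assert out["excluded_flag"].iloc[0]
        assert not out["sdl_flag"].iloc[0]

    def test_ratio_minus_one_variant(self):
        out = z.sdl_call(self._table(0.9, 0.9), score="ratio_minus_1")
        assert out["min_score"].iloc[0] == pytest.approx(-0.1)
        assert out["sdl_flag"].iloc[0]
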