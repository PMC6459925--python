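import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirecur import (
    NormalizationParams,
    ProbePanel,
    SignalMatrix,
    Stage,
    background_correct,
    internal_control_scale,
    log2_transform,
    negctrl_floor,
    normalize_chain,
    quantile_normalize,
    simulate,
    SimulationConfig,
)
from mirecur.types import StageError, ValidationError


def make_panel(n_target=3, n_ic=2, n_neg=20):
    rows = []
    for i in range(n_target):
        rows.append((f"t{i}", "target", f"miR-t{i}"))
    for i in range(n_ic):
        rows.append((f"ic{i}", "internal_control", f"miR-ic{i}"))
    for i in range(n_neg):
        rows.append((f"neg{i}", "negative_control", ""))
    return ProbePanel(
        pd.DataFrame(rows, columns=["probe_id", "probe_class", "mirna_name"])
    )


def make_matrix(values: pd.DataFrame, stage=Stage.RAW) -> SignalMatrix:
    return SignalMatrix(
        values=values,
        detected=pd.DataFrame(True, index=values.index, columns=values.columns),
        stage=stage,
    )


class TestNegctrlFloor:
    def test_hand_computed_trimmed_mean(self):
        panel = make_panel(n_target=0, n_ic=0, n_neg=20)
        col = pd.Series(
            np.arange(1.0, 21.0), index=[f"neg{i}" for i in range(20)]
        )
        # ceil(0.05 * 20) = 1 from each tail -> mean of 2..19
        assert negctrl_floor(col, panel) == pytest.approx(10.5)

    def test_constant_controls(self):
        panel = make_panel(n_target=0, n_ic=0, n_neg=10)
        col = pd.Series(7.0, index=[f"neg{i}" for i in range(10)])
        assert negctrl_floor(col, panel) == 7.0

    def test_zero_trim_is_plain_mean(self):
        panel = make_panel(n_target=0, n_ic=0, n_neg=4)
        col = pd.Series([1.0, 2.0, 3.0, 10.0],
                        index=[f"neg{i}" for i in range(4)])
        params = NormalizationParams(negctrl_trim_fraction=0.0)
        assert negctrl_floor(col, panel, params) == 4.0

    def test_tiny_n_falls_back_to_plain_mean(self):
        panel = make_panel(n_target=0, n_ic=0, n_neg=2)
        col = pd.Series([1.0, 3.0], index=["neg0", "neg1"])
        params = NormalizationParams(negctrl_trim_fraction=0.4)
        assert negctrl_floor(col, panel, params) == 2.0

    def test_no_negative_controls_is_config_error(self):
        panel = make_panel(n_target=2, n_ic=0, n_neg=0)
        col = pd.Series([1.0, 2.0], index=["t0", "t1"])
        with pytest.raises(ValidationError):
            negctrl_floor(col, panel)


class TestBackgroundCorrect:
    @pytest.fixture
    def simple(self):
        panel = make_panel(n_target=3, n_ic=0, n_neg=5)
        values = pd.DataFrame(
            {
                "s1": [10.0, 15.0, 5.0] + [10.0] * 5,
            },
            index=["t0", "t1", "t2"] + [f"neg{i}" for i in range(5)],
        )
        return panel, make_matrix(values)

    def test_strictly_above_floor_required(self, simple):
        panel, matrix = simple
        out = background_correct(matrix, panel)
        # floor is 10: t0 at exactly 10 is absent, t1 detected at 15-10=5
        assert not out.detected.loc["t0", "s1"]
        assert out.values.loc["t0", "s1"] == 0.0
        assert out.detected.loc["t1", "s1"]
        assert out.values.loc["t1", "s1"] == 5.0
        assert not out.detected.loc["t2", "s1"]

    def test_negative_controls_dropped(self, simple):
        panel, matrix = simple
        out = background_correct(matrix, panel)
        assert out.probe_ids == ["t0", "t1", "t2"]

    def test_all_background_array_survives(self):
        panel = make_panel(n_target=3, n_ic=0, n_neg=5)
        values = pd.DataFrame(
            {"s1": [1.0] * 8},
            index=["t0", "t1", "t2"] + [f"neg{i}" for i in range(5)],
        )
        out = background_correct(make_matrix(values), panel)
        assert not out.detected["s1"].any()

    def test_stage_mismatch_raises(self, simple):
        panel, matrix = simple
        out = background_correct(matrix, panel)
        with pytest.raises(StageError):
            background_correct(out, panel)


class TestQuantileNormalize:
    def test_textbook_two_array_example(self):
        values = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [3.0, 4.0, 5.0]},
            index=["p1", "p2", "p3"],
        )
        out = quantile_normalize(make_matrix(values, Stage.BACKGROUND_CORRECTED))
        expected = pd.DataFrame(
            {"a": [2.0, 3.0, 4.0], "b": [2.0, 3.0, 4.0]},
            index=["p1", "p2", "p3"],
        )
        pd.testing.assert_frame_equal(out.values, expected)

    def test_identical_arrays_are_fixed_point(self):
        values = pd.DataFrame(
            {"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]},
            index=["p1", "p2", "p3"],
        )
        out = quantile_normalize(make_matrix(values, Stage.BACKGROUND_CORRECTED))
        pd.testing.assert_frame_equal(out.values, values)

    def test_ties_get_mean_of_spanned_quantiles(self):
        values = pd.DataFrame(
            {"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]},
            index=["p1", "p2", "p3"],
        )
        out = quantile_normalize(make_matrix(values, Stage.BACKGROUND_CORRECTED))
        ref = np.array([1.5, 2.5, 5.5])
        assert out.values.loc["p1", "a"] == pytest.approx(ref[:2].mean())
        assert out.values.loc["p2", "a"] == pytest.approx(ref[:2].mean())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_order_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.uniform(0, 100, size=(15, 4)),
            index=[f"p{i}" for i in range(15)],
            columns=list("abcd"),
        )
        m = make_matrix(values, Stage.BACKGROUND_CORRECTED)
        once = quantile_normalize(m)
        twice = quantile_normalize(
            make_matrix(once.values, Stage.BACKGROUND_CORRECTED)
        )
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )
        perm = make_matrix(values[list("dbca")], Stage.BACKGROUND_CORRECTED)
        out_perm = quantile_normalize(perm)
        pd.testing.assert_frame_equal(
            out_perm.values[list("abcd")], once.values
        )

    def test_sorted_columns_all_equal_after(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(0, 50, size=(20, 5)),
            index=[f"p{i}" for i in range(20)],
        )
        out = quantile_normalize(make_matrix(values, Stage.BACKGROUND_CORRECTED))
        arr = np.sort(out.values.to_numpy(), axis=0)
        assert np.allclose(arr, arr[:, [0]])

    def test_single_array_warns_and_passes_through(self):
        values = pd.DataFrame({"a": [1.0, 2.0]}, index=["p1", "p2"])
        with pytest.warns(UserWarning):
            out = quantile_normalize(
                make_matrix(values, Stage.BACKGROUND_CORRECTED)
            )
        pd.testing.assert_frame_equal(out.values, values)


class TestInternalControlScale:
    @pytest.fixture
    def ic_setup(self):
        panel = make_panel(n_target=2, n_ic=2, n_neg=0)
        values = pd.DataFrame(
            {"a": [10.0, 20.0, 40.0, 60.0], "b": [1.0, 2.0, 4.0, 6.0]},
            index=["t0", "t1", "ic0", "ic1"],
        )
        return panel, make_matrix(values, Stage.QUANTILE_NORMALIZED)

    def test_preset_arithmetic(self, ic_setup):
        panel, matrix = ic_setup
        params = NormalizationParams(preset_value=100.0)
        out = internal_control_scale(matrix, panel, params)
        # array a: control mean 50 -> everything x2
        assert out.values.loc["t0", "a"] == pytest.approx(20.0)
        assert out.values.loc["ic1", "a"] == pytest.approx(120.0)

    def test_postcondition_control_mean_hits_preset(self, ic_setup):
        panel, matrix = ic_setup
        params = NormalizationParams(preset_value=77.0)
        out = internal_control_scale(matrix, panel, params)
        means = out.values.loc[["ic0", "ic1"]].mean(axis=0)
        assert np.allclose(means, 77.0, rtol=1e-9)

    def test_already_at_preset_is_identity(self, ic_setup):
        panel, matrix = ic_setup
        params = NormalizationParams(preset_value=50.0)
        out = internal_control_scale(matrix, panel, params)
        pd.testing.assert_frame_equal(out.values[["a"]], matrix.values[["a"]])

    def test_scale_invariance(self, ic_setup):
        panel, matrix = ic_setup
        doubled = matrix.values.copy()
        doubled["a"] *= 2.0
        m2 = make_matrix(doubled, Stage.QUANTILE_NORMALIZED)
        out1 = internal_control_scale(matrix, panel,
                                      NormalizationParams(preset_value=10.0))
        out2 = internal_control_scale(m2, panel,
                                      NormalizationParams(preset_value=10.0))
        np.testing.assert_allclose(
            out1.values["a"].to_numpy(), out2.values["a"].to_numpy()
        )

    def test_rescaling_twice_is_fixed_point(self, ic_setup):
        panel, matrix = ic_setup
        params = NormalizationParams(preset_value=10.0)
        once = internal_control_scale(matrix, panel, params)
        again = internal_control_scale(
            make_matrix(once.values, Stage.QUANTILE_NORMALIZED), panel, params
        )
        np.testing.assert_allclose(
            once.values.to_numpy(), again.values.to_numpy(), rtol=1e-12
        )

    def test_nonpositive_control_mean_names_array(self, ic_setup):
        panel, matrix = ic_setup
        bad = matrix.values.copy()
        bad.loc[["ic0", "ic1"], "b"] = 0.0
        with pytest.raises(ValidationError, match="b"):
            internal_control_scale(
                make_matrix(bad, Stage.QUANTILE_NORMALIZED), panel
            )


class TestLog2Transform:
    def test_arithmetic(self):
        values = pd.DataFrame({"a": [0.0, 3.0]}, index=["p1", "p2"])
        out = log2_transform(make_matrix(values, Stage.CONTROL_SCALED))
        assert out.values.loc["p1", "a"] == 0.0
        assert out.values.loc["p2", "a"] == 2.0

    def test_monotone(self):
        rng = np.random.default_rng(2)
        v = np.sort(rng.uniform(0, 100, size=20))
        values = pd.DataFrame({"a": v}, index=[f"p{i}" for i in range(20)])
        out = log2_transform(make_matrix(values, Stage.CONTROL_SCALED))
        assert (np.diff(out.values["a"].to_numpy()) > 0).all()


class TestFullChain:
    def test_null_batch_arrays_become_indistinguishable(self):
        """After the chain, per-array value distributions agree by KS test.

        Detection dropout is disabled: absent probes produce per-array
        zero-inflation that is real signal variation, not an array effect
        the chain is meant to remove.
        """
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 2**31, size=8):
            cfg = SimulationConfig(
                n_target_probes=120, n_internal_controls=10,
                n_negative_controls=30, marker_effect_log2=0.0,
                dynamics_amplitude_log2=0.0, detect_drop_fraction=0.0,
                seed=int(seed),
            )
            panel, cohort, samples, raw, _ = simulate(cfg)
            norm = normalize_chain(raw, panel)
            cols = rng.choice(norm.values.columns, size=2, replace=False)
            _, p = stats.ks_2samp(norm.values[cols[0]], norm.values[cols[1]])
            assert p > 0.01

    def test_stage_advances_in_order(self, tiny_sim):
        panel, _, _, raw, _ = tiny_sim
        out = normalize_chain(raw, panel)
        assert out.stage == Stage.LOG2
        with pytest.raises(StageError):
            quantile_normalize(out)
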