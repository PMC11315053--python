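import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trotsym.simulate import (
    label_reference_from_truth,
    shape_from_metrics,
    simulate_normalized_diffs,
    simulate_stride_signal,
    simulate_study,
)
from trotsym.segmentation import segment_strides
from trotsym.symmetry import stride_metrics
from trotsym.types import (
    DIFF_COLUMNS,
    NoiseModel,
    StrideShape,
    StudyDesign,
    VariableEffect,
    zero_effect_table,
)

from conftest import true_stride_set


class TestStrideShape:
    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            StrideShape(min1=10.0, max1=5.0, min2=-50.0, max2=50.0)
        with pytest.raises(ValueError):
            StrideShape(min1=-50.0, max1=50.0, min2=-50.0, max2=50.0, stride_time_ms=0)
        with pytest.raises(ValueError):
            StrideShape(min1=-50.0, max1=np.nan, min2=-50.0, max2=50.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        dmin=st.floats(-15, 15),
        dmax=st.floats(-15, 15),
        rom=st.floats(60, 120),
    )
    def test_shape_from_metrics_round_trip(self, dmin, dmax, rom):
        sh = shape_from_metrics(dmin, dmax, rom)
        assert sh.dmin == pytest.approx(dmin, abs=1e-9)
        assert sh.dmax == pytest.approx(dmax, abs=1e-9)
        assert sh.rom == pytest.approx(rom, abs=1e-9)
        assert sh.dup == pytest.approx(dmax - dmin, abs=1e-9)


class TestSimulateStrideSignal:
    def test_symmetric_shape_gives_identical_strides(self, symmetric_trial):
        tr = symmetric_trial
        x = tr.signal.samples
        per_stride = x.reshape(30, -1)
        assert np.allclose(per_stride, per_stride[0])
        assert per_stride.max() == pytest.approx(50.0)
        assert per_stride.min() == pytest.approx(-50.0)

    def test_extrema_exact_by_construction(self, asymmetric_shape):
        tr = simulate_stride_signal(asymmetric_shape, 10)
        x = tr.signal.samples
        # default phases land on exact samples at 100 Hz / 720 ms
        for i in range(10):
            s = i * 72
            assert x[s] == pytest.approx(-40.0)
            assert x[s + 18] == pytest.approx(30.0)
            assert x[s + 36] == pytest.approx(-45.0)
            assert x[s + 54] == pytest.approx(28.0)

    def test_determinism(self):
        sh = shape_from_metrics(3, -2, 90)
        nz = NoiseModel(sigma_stride=2, sigma_meas=1, drift_amp=3, seed=77)
        a = simulate_stride_signal(sh, 20, nz)
        b = simulate_stride_signal(sh, 20, nz)
        assert np.array_equal(a.signal.samples, b.signal.samples)
        assert np.array_equal(a.truth.extrema, b.truth.extrema)

    def test_scaling_property(self):
        sh = StrideShape(min1=-40.0, max1=30.0, min2=-45.0, max2=28.0)
        c = 2.5
        scaled = StrideShape(
            min1=c * sh.min1, max1=c * sh.max1, min2=c * sh.min2, max2=c * sh.max2
        )
        a = simulate_stride_signal(sh, 5).truth.metrics
        b = simulate_stride_signal(scaled, 5).truth.metrics
        for m in ("Dmin", "Dmax", "Dup", "ROM"):
            assert np.allclose(b[m], c * a[m])

    def test_noisy_extrema_recovered_within_three_sigma(self):
        """With 1 mm sample noise, the per-stride extrema recovered by the
        symmetry stage fall within 3 sigma of truth for >=95% of strides."""
        sigma = 1.0
        sh = shape_from_metrics(5, -3, 90)
        tr = simulate_stride_signal(sh, 100, NoiseModel(sigma_meas=sigma, seed=9))
        strides = true_stride_set(tr)
        m = stride_metrics(tr.signal, strides)
        truth = tr.truth.extrema[m["stride_idx"].to_numpy()]
        meas = m[["first_min", "first_max", "second_min", "second_max"]].to_numpy()
        err = np.abs(meas - truth[:, [0, 1, 2, 3]])
        assert np.mean(err <= 3.0 * sigma) >= 0.95

    def test_rejects_bad_inputs(self, asymmetric_shape):
        with pytest.raises(ValueError):
            simulate_stride_signal(asymmetric_shape, 0)
        with pytest.raises(ValueError):
            simulate_stride_signal(asymmetric_shape, 5, fs=4.0)


class TestSimulateStudy:
    def test_zero_effects_give_zero_truth(self):
        design = StudyDesign(n_horses=3)
        study = simulate_study(design, zero_effect_table(), with_signals=False)
        diffs = study.truth_diffs[list(DIFF_COLUMNS)].to_numpy()
        assert np.allclose(diffs, 0.0)
        assert np.allclose(study.truth_summaries["PROM"], 100.0)
        assert np.allclose(study.truth_summaries["HROM"], 80.0)

    def test_full_design_produces_80_records(self):
        study = simulate_study(StudyDesign(), with_signals=False)
        assert len(study.truth_diffs) == 80
        counts = study.truth_diffs.groupby(["surface", "direction"]).size()
        assert counts.to_dict() == {
            ("hard", "straight"): 20,
            ("soft", "inside"): 20,
            ("soft", "outside"): 20,
            ("soft", "straight"): 20,
        }

    def test_study_determinism(self):
        a = simulate_study(StudyDesign(n_horses=2), noise=NoiseModel(seed=4))
        b = simulate_study(StudyDesign(n_horses=2), noise=NoiseModel(seed=4))
        pd.testing.assert_frame_equal(a.truth_summaries, b.truth_summaries)
        key = next(iter(a.trials))
        assert np.array_equal(
            a.trials[key]["head"].signal.samples,
            b.trials[key]["head"].signal.samples,
        )

    def test_first_limb_assignment_respected(self):
        design = StudyDesign(n_horses=2, first_limb_assignment=("right", "left"))
        study = simulate_study(design, with_signals=False)
        assert study.first_limbs == ("right", "left")
        between = study.truth_summaries.query("session == 'between'")
        assert set(between[between.horse_id == "H01"]["reshod_limb"]) == {"right"}

    def test_normalized_diff_generator_matches_cells_at_zero_noise(self):
        cells = {
            ("hard", "straight"): -2.0,
            ("soft", "straight"): 1.0,
            ("soft", "inside"): 0.5,
            ("soft", "outside"): -0.5,
        }
        eff = VariableEffect(cells)
        df = simulate_normalized_diffs(
            StudyDesign(n_horses=4), eff, np.random.default_rng(0)
        )
        got = df.groupby(["surface", "direction"])["value"].mean().to_dict()
        assert got == pytest.approx(cells)


class TestLabelReference:
    def test_reference_recovers_truth_parity(self):
        sh = shape_from_metrics(6, 2, 90)
        tr = simulate_stride_signal(sh, 30, NoiseModel(sigma_meas=0.5, seed=2))
        strides = segment_strides(tr.signal)
        ref = label_reference_from_truth(tr.truth, strides)
        # nearest true boundary decides: reference must be one of the two
        # and consistent with the detected starting half
        first = strides.starts[0]
        d_start = np.min(np.abs(tr.truth.start_samples - first))
        d_mid = np.min(np.abs(tr.truth.mid_samples - first))
        expected = "first_half_is_left" if d_start < d_mid else "first_half_is_right"
        assert ref == expected
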