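"""SSE objective and Nelder–Mead descent."""

import numpy as np
import pandas as pd
import pytest

from succdyn import (
    CalibratedParams,
    NoiseModel,
    ObservationSet,
    ParamError,
    calibrate,
    generate_dataset,
    simulate,
    sse,
)
from succdyn.calibrate import OBSERVATION_COLUMNS, read_observations, write_observations


@pytest.fixture(scope="module")
def clean_g1_data(params, fixed, configs):
    """Noise-free synthetic observations for G1."""
    return generate_dataset(
        params, fixed, {"G1": configs["G1"]}, noise=NoiseModel(cv=0.0)
    )


class TestObjective:
    def test_noise_free_data_at_truth_scores_zero(self, params, fixed, configs, clean_g1_data):
        assert sse(params, clean_g1_data, fixed, configs) <= 1e-10

    def test_single_observation_contributes_d_squared_over_max(self, params, fixed, configs):
        t = 10.0
        traj = simulate(configs["G1"], params, fixed)
        truth = traj.observables_at(np.array([t]))
        d = 0.05
        frame = pd.DataFrame({"time_h": [t]})
        for col in OBSERVATION_COLUMNS:
            frame[col] = np.nan
        c = float(truth["glucose_gL"].iloc[0]) + d
        frame["glucose_gL"] = [c]
        obs = ObservationSet("G1", frame)
        assert sse(params, [obs], fixed, configs) == pytest.approx(d**2 / c, rel=1e-6)

    def test_all_missing_experiment_adds_nothing(self, params, fixed, configs, clean_g1_data):
        empty = pd.DataFrame({"time_h": [5.0, 10.0]})
        for col in OBSERVATION_COLUMNS:
            empty[col] = np.nan
        augmented = list(clean_g1_data) + [ObservationSet("G2", empty)]
        assert sse(params, augmented, fixed, configs) == pytest.approx(
            sse(params, clean_g1_data, fixed, configs), abs=1e-15
        )

    def test_worse_parameters_score_worse(self, params, fixed, configs, clean_g1_data):
        off = params.replace(v_G=params.v_G * 2.0)
        assert sse(off, clean_g1_data, fixed, configs) > sse(
            params, clean_g1_data, fixed, configs
        )

    def test_observation_beyond_horizon_rejected(self, params, fixed, configs):
        frame = pd.DataFrame({"time_h": [999.0]})
        for col in OBSERVATION_COLUMNS:
            frame[col] = 1.0
        with pytest.raises(ParamError, match="horizon"):
            sse(params, [ObservationSet("G1", frame)], fixed, configs)

    def test_unsorted_times_rejected(self):
        frame = pd.DataFrame({"time_h": [5.0, 2.0]})
        for col in OBSERVATION_COLUMNS:
            frame[col] = 1.0
        with pytest.raises(ParamError, match="increasing"):
            ObservationSet("G1", frame)


class TestObservationIO:
    def test_roundtrip_preserves_missing_values(self, tmp_path, params, fixed, configs):
        data = generate_dataset(params, fixed, {"G1": configs["G1"]},
                                noise=NoiseModel(cv=0.03, seed=5))[0]
        data.data.loc[2, "biomass_gL"] = np.nan
        path = tmp_path / "G1.csv"
        write_observations(data, path)
        back = read_observations(path)
        assert back.experiment == "G1"
        pd.testing.assert_frame_equal(
            back.data, data.data[["time_h", *OBSERVATION_COLUMNS]], check_exact=False
        )


class TestCalibrate:
    def test_descent_from_perturbed_start(self, params, fixed, configs, clean_g1_data):
        """Nelder–Mead over one log-parameter strictly improves the start."""
        start = params.replace(v_G=params.v_G * 1.5)
        result = calibrate(
            start, clean_g1_data, fixed, configs, free=["v_G"], max_iter=40
        )
        assert result.sse <= result.report["start_sse"]
        assert result.sse < 0.5 * result.report["start_sse"]
        assert result.params.v_G > 0
        # only the free parameter moved
        assert result.params.replace(v_G=params.v_G) == params.replace()

    def test_start_at_truth_stays_at_truth(self, params, fixed, configs, clean_g1_data):
        result = calibrate(
            params, clean_g1_data, fixed, configs, free=["v_G", "v_P1"], max_iter=30
        )
        assert result.sse <= 1e-10
        assert result.params.v_G == pytest.approx(params.v_G, rel=0.02)

    def test_unknown_free_parameter_rejected(self, params, fixed, configs, clean_g1_data):
        with pytest.raises(ParamError, match="bogus"):
            calibrate(params, clean_g1_data, fixed, configs, free=["bogus"])

    def test_prefit_start_improves_tenfold_on_clean_data(self, params, fixed, configs):
        """Scaled-down re-fit: starting selected parameters from the
        packaged pre-fit guesses, the simplex cuts the objective >= 10x
        against data generated by the calibrated values."""
        from succdyn import NoiseModel, generate_dataset, precalibration_params

        pre = precalibration_params()
        data = generate_dataset(params, fixed, {"G2": configs["G2"]},
                                noise=NoiseModel(cv=0.0))
        free = ["v_Gly1", "v_G", "eta_X", "ATP_mid", "a1"]
        start = params.replace(**{n: getattr(pre, n) for n in free})
        result = calibrate(start, data, fixed, configs, free=free, max_iter=120)
        assert result.sse <= result.report["start_sse"] / 10.0

    def test_report_contents(self, params, fixed, configs, clean_g1_data):
        result = calibrate(params, clean_g1_data, fixed, configs,
                           free=["v_G"], max_iter=5)
        for key in ("start_sse", "iterations", "function_evaluations",
                    "converged", "simplex_spread", "free"):
            assert key in result.report
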