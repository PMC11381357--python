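import numpy as np
import pytest

from tmsdkit.features import FeatureVector
from tmsdkit.kinetics import R_GAS
from tmsdkit.synthetic import (
    SyntheticConfig,
    arrhenius_rate,
    gen_systems,
    planted_log_rate,
    simulate_standard_curve,
    simulate_temperature_series,
    simulate_trace,
    system_rng,
    write_systems_csv,
    write_traces_csv,
)


def flat_fv():
    return FeatureVector(values=(0.0,) * 16)


# ---------------------------------------------------------------------------
# system generation


def test_zero_systems_gives_empty_list():
    assert gen_systems(SyntheticConfig(n_systems=0)) == []


def test_generation_is_deterministic_and_prefix_stable():
    a = gen_systems(SyntheticConfig(n_systems=8, seed=4))
    b = gen_systems(SyntheticConfig(n_systems=8, seed=4))
    assert [s.invader.sequence for s in a] == [s.invader.sequence for s in b]
    # extending the study must not perturb earlier systems
    c = gen_systems(SyntheticConfig(n_systems=16, seed=4))
    assert [s.invader.sequence for s in c[:8]] == [s.invader.sequence for s in a]


def test_generated_systems_satisfy_complementarity():
    for sys_ in gen_systems(SyntheticConfig(n_systems=25, seed=9)):
        # DisplacementSystem enforces the invariants at construction; check
        # the partition explicitly
        assert len(sys_.toehold) == 6
        assert sys_.branch == SyntheticConfig().branch_seq


def test_toehold_base_frequencies_are_uniform():
    cfg = SyntheticConfig(n_systems=4000, seed=17)
    toeholds = [s.toehold for s in gen_systems(cfg)]
    n = len(toeholds)
    sigma = np.sqrt(n * 0.25 * 0.75)
    for pos in range(6):
        for base in "ACGT":
            count = sum(th[pos] == base for th in toeholds)
            assert abs(count - n / 4) < 4 * sigma


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_systems=-1),
        dict(branch_seq="ACGX"),
        dict(branch_seq=""),
        dict(toehold_len=0),
        dict(c0=0.0),
        dict(dt=0.0),
        dict(temps_c=()),
        dict(planted_coeffs={"X99": 1.0}),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SyntheticConfig(**kwargs)


def test_config_json_round_trip(tmp_path):
    cfg = SyntheticConfig(n_systems=3, seed=2, noise_sd_log10k=0.1)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    assert SyntheticConfig.from_json(path) == cfg


# ---------------------------------------------------------------------------
# planted rate model


def test_planted_rate_closed_form_with_zero_noise():
    cfg = SyntheticConfig(planted_coeffs={}, planted_intercept=5.0, noise_sd_log10k=0.0)
    assert planted_log_rate(flat_fv(), cfg) == pytest.approx(1.0e5)


def test_planted_rate_noise_statistics_recovered():
    cfg = SyntheticConfig(planted_coeffs={}, planted_intercept=5.0, noise_sd_log10k=0.3)
    rng = np.random.default_rng(8)
    draws = np.log10([planted_log_rate(flat_fv(), cfg, rng) for _ in range(1000)])
    assert draws.mean() == pytest.approx(5.0, abs=4 * 0.3 / np.sqrt(1000))
    assert draws.std() == pytest.approx(0.3, abs=0.04)


def test_planted_rate_reproducible_per_seed():
    cfg = SyntheticConfig(planted_coeffs={"X5": 0.05}, noise_sd_log10k=0.2)
    fv = flat_fv()
    k1 = planted_log_rate(fv, cfg, np.random.default_rng(77))
    k2 = planted_log_rate(fv, cfg, np.random.default_rng(77))
    assert k1 == k2


# ---------------------------------------------------------------------------
# traces


def test_zero_rate_gives_flat_trace():
    cfg = SyntheticConfig()
    tr = simulate_trace(0.0, cfg, rng=None)
    assert np.allclose(tr.intensities, cfg.calibration[1] + cfg.background)


def test_half_completion_time_matches_closed_form():
    cfg = SyntheticConfig()
    tr = simulate_trace(1e5, cfg, rng=None)  # 1/(k c0) = 200 s
    idx = int(200 / cfg.dt)
    assert tr.times[idx] == 200.0
    half_intensity = cfg.calibration[0] * 25.0 + cfg.calibration[1] + cfg.background
    assert tr.intensities[idx] == pytest.approx(half_intensity)


def test_noise_is_unbiased():
    cfg = SyntheticConfig()
    clean = simulate_trace(1e5, cfg, rng=None).intensities
    resid = np.concatenate(
        [simulate_trace(1e5, cfg, rng=np.random.default_rng(s)).intensities - clean
         for s in range(100)]
    )
    se = cfg.trace_noise_sd / np.sqrt(resid.size)
    assert abs(resid.mean()) < 4 * se


def test_noise_free_progress_is_monotone_and_bounded():
    cfg = SyntheticConfig()
    for k in (1e3, 1e5, 1e7):
        tr = simulate_trace(k, cfg, rng=None)
        conc_nm = (tr.intensities - cfg.background - cfg.calibration[1]) / cfg.calibration[0]
        assert np.all(np.diff(conc_nm) >= -1e-12)
        assert conc_nm.max() <= cfg.c0 * 1e9 + 1e-9


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        simulate_trace(-1.0, SyntheticConfig())


# ---------------------------------------------------------------------------
# temperature series


def test_flat_arrhenius_with_zero_activation_energy():
    cfg = SyntheticConfig(ea=0.0)
    series = simulate_temperature_series(cfg, rng=None)
    traces = list(series.values())
    for tr in traces[1:]:
        assert np.allclose(tr.intensities, traces[0].intensities)


def test_arrhenius_rate_ratio_closed_form():
    cfg = SyntheticConfig(ea=60000.0)
    ratio = arrhenius_rate(cfg, 30.0) / arrhenius_rate(cfg, 15.0)
    expected = np.exp(60000.0 / R_GAS * (1 / 288.15 - 1 / 303.15))
    assert ratio == pytest.approx(expected, rel=1e-12)


def test_temperature_series_reproducible():
    cfg = SyntheticConfig()
    a = simulate_temperature_series(cfg, rng=31)
    b = simulate_temperature_series(cfg, rng=31)
    assert set(a) == {15.0, 20.0, 25.0, 30.0}
    for t in a:
        assert np.array_equal(a[t].intensities, b[t].intensities)


# ---------------------------------------------------------------------------
# serialization and streams


def test_per_system_streams_are_independent():
    cfg = SyntheticConfig(seed=6)
    a = system_rng(cfg, 0, 1).normal(size=4)
    b = system_rng(cfg, 1, 1).normal(size=4)
    c = system_rng(cfg, 0, 2).normal(size=4)
    assert not np.allclose(a, b) and not np.allclose(a, c)
    assert np.allclose(a, system_rng(cfg, 0, 1).normal(size=4))


def test_writers_produce_expected_tables(tmp_path):
    import pandas as pd

    cfg = SyntheticConfig(n_systems=3, seed=1)
    systems = gen_systems(cfg)
    write_systems_csv(systems, tmp_path / "s.csv")
    df = pd.read_csv(tmp_path / "s.csv")
    assert list(df.columns) == ["id", "invader", "substrate", "incumbent", "toehold_len"]
    assert len(df) == 3

    traces = [simulate_trace(1e5, cfg, rng=None, sample_id=s.system_id) for s in systems]
    write_traces_csv(traces, tmp_path / "t.csv")
    tdf = pd.read_csv(tmp_path / "t.csv")
    assert set(tdf.columns) == {"time_s", "intensity", "temp_C", "sample_id"}
    assert tdf["sample_id"].nunique() == 3


def test_standard_curve_simulation_follows_calibration_line():
    cfg = SyntheticConfig()
    concs, intensities = simulate_standard_curve(cfg, rng=None)
    assert np.allclose(intensities, cfg.calibration[0] * concs + cfg.calibration[1])
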