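import numpy as np
import pytest

from airseq import SyntheticConfig, generate_fleet, generate_station
from airseq.errors import ConfigurationError
from airseq.periodicity import daily_means
from airseq.station import POLLUTANTS


def _flat_peaks():
    return {ch: [] for ch in POLLUTANTS}


def test_degenerate_config_gives_constant_baseline():
    """All amplitudes zero, no noise, flat weekly -> every value is baseline."""
    cfg = SyntheticConfig(
        n_days=10, diurnal_peaks=_flat_peaks(), noise_sd=0.0,
        weekly_weights=(1.0,) * 7, meteo_coupling={}, missing_rate=0.0, seed=0,
    )
    s = generate_station(cfg)
    for ch, level in cfg.baseline.items():
        assert np.allclose(s.channel(ch).to_numpy(), level)


def test_pm25_peaks_lag_co_peaks_by_configured_hour(clean_series):
    """CO peaks at 8/18 put the PM2.5 diurnal maxima at exactly 9/19."""
    from airseq import diurnal_profile

    co = diurnal_profile(clean_series, "co")
    pm = diurnal_profile(clean_series, "pm25")
    assert co.argmax_hours() == [8, 18]
    assert pm.argmax_hours() == [9, 19]


def test_seeding_contract():
    cfg = SyntheticConfig(n_days=10, seed=5, missing_rate=0.05)
    a = generate_station(cfg)
    b = generate_station(cfg)
    assert a.equals(b)
    c = generate_station(cfg.replace(seed=6))
    assert not np.array_equal(
        a.data.to_numpy(), c.data.to_numpy(), equal_nan=True
    )


def test_weekly_means_proportional_to_weights():
    """Noise-free day-of-week means of daily averages track weekly_weights."""
    weights = (1.0, 0.9, 0.95, 1.05, 1.2, 1.0, 1.1)
    cfg = SyntheticConfig(
        n_days=28, noise_sd=0.0, meteo_coupling={}, weekly_weights=weights,
        missing_rate=0.0, seed=2,
    )
    s = generate_station(cfg)
    from airseq import weekly_profile

    prof = weekly_profile(s, "pm25")
    ratio = prof.means / np.asarray(weights)
    assert np.all(np.abs(ratio / ratio[0] - 1.0) < 1e-9)


def test_weekly_argmax_and_flat_profile():
    from airseq import weekly_profile

    weights = [1.0] * 7
    weights[4] = 1.3  # Friday peak
    cfg = SyntheticConfig(
        n_days=21, noise_sd=0.0, meteo_coupling={}, weekly_weights=tuple(weights),
        missing_rate=0.0, seed=2,
    )
    prof = weekly_profile(generate_station(cfg), "pm25")
    assert int(np.argmax(prof.means)) == 4

    flat_cfg = cfg.replace(weekly_weights=(1.0,) * 7)
    flat = weekly_profile(generate_station(flat_cfg), "pm25")
    assert np.allclose(flat.means, flat.means[0])


def test_ar1_noise_lag1_autocorrelation():
    """With no deterministic structure, the lag-1 ACF converges to ar_coef."""
    from airseq import acf

    cfg = SyntheticConfig(
        n_days=365, diurnal_peaks=_flat_peaks(), weekly_weights=(1.0,) * 7,
        meteo_coupling={}, ar_coef=0.7, noise_sd=8.0, missing_rate=0.0, seed=3,
    )
    s = generate_station(cfg)
    r = acf(s.channel("pm25").to_numpy(), 2)
    assert abs(r.r[1] - 0.7) < 0.05


def test_missing_rate_matches_expectation():
    cfg = SyntheticConfig(n_days=200, missing_rate=0.1, seed=4)
    s = generate_station(cfg)
    frac = float(s.missing_mask.to_numpy().mean())
    assert abs(frac - 0.1) < 0.005


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("n_days", 5, "n_days"),
        ("weekly_weights", (1.0,) * 6, "weekly_weights"),
        ("weekly_weights", (1.0,) * 6 + (0.0,), "weekly_weights"),
        ("ar_coef", 1.0, "ar_coef"),
        ("missing_rate", 1.5, "missing_rate"),
        ("noise_sd", -1.0, "noise_sd"),
    ],
)
def test_invalid_config_names_offending_field(field, value, match):
    cfg = SyntheticConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=match):
        generate_station(cfg)


def test_fleet_seeding_and_identity():
    cfg = SyntheticConfig(n_days=12, seed=9)
    fleet = generate_fleet(cfg, 1)
    assert len(fleet) == 1
    solo = generate_station(cfg)
    assert np.array_equal(
        fleet[0].data.to_numpy(), solo.data.to_numpy(), equal_nan=True
    )

    fleet8 = generate_fleet(cfg, 3)
    arrays = [s.data.to_numpy() for s in fleet8]
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            assert not np.array_equal(arrays[i], arrays[j], equal_nan=True)
    again = generate_fleet(cfg, 3)
    for a, b in zip(fleet8, again):
        assert a.equals(b)

    with pytest.raises(ValueError):
        generate_fleet(cfg, 0)


def test_fleet_shares_deterministic_component():
    """With noise and coupling off, all fleet members coincide."""
    cfg = SyntheticConfig(
        n_days=10, noise_sd=0.0, meteo_coupling={}, missing_rate=0.0, seed=1
    )
    fleet = generate_fleet(cfg, 3)
    base = fleet[0].data[POLLUTANTS].to_numpy()
    for s in fleet[1:]:
        assert np.allclose(s.data[POLLUTANTS].to_numpy(), base)


def test_nonnegative_concentrations(noisy_series):
    vals = noisy_series.data[POLLUTANTS].to_numpy()
    assert np.nanmin(vals) >= 0.0
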