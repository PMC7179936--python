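import numpy as np
import pytest

from proclean.model import consortium_rhs
from proclean.params import ReactorInputs
from proclean.simulate import exponential_regime_stats, simulate

BATCH = ReactorInputs(mode="batch")
FEDBATCH = ReactorInputs(mode="fedbatch", G_held=20.0)


@pytest.fixture(scope="module")
def fedbatch_traj(producer, cleaner):
    return simulate(
        [20.0, 0.0, 0.01, 0.0, 0.01], FEDBATCH, producer, cleaner,
        horizon=50.0, n_points=2501,
    )


def test_starvation_decay_closed_form(producer_wt):
    # no substrate: biomass decays exponentially at k_deg
    traj = simulate([0.0, 0.0, 0.5, 0.0, 0.0], BATCH, producer_wt, horizon=100.0)
    expected = 0.5 * np.exp(-producer_wt.k_deg * traj.times)
    assert np.allclose(traj.states[:, 2], expected, rtol=1e-6)


def test_input_validation(producer_wt):
    with pytest.raises(ValueError):
        simulate([-1, 0, 0.1, 0, 0], BATCH, producer_wt, horizon=1.0)
    with pytest.raises(ValueError):
        simulate([1, 0, 0.1, 0, 0], BATCH, producer_wt, horizon=0.0)
    with pytest.raises(ValueError):
        simulate([1, 0, 0.1], BATCH, producer_wt, horizon=1.0)


def _rk4(x0, u, p, c, t_end, dt):
    x = np.asarray(x0, float).copy()
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = consortium_rhs(x, u, p, c)
        k2 = consortium_rhs(x + 0.5 * dt * k1, u, p, c)
        k3 = consortium_rhs(x + 0.5 * dt * k2, u, p, c)
        k4 = consortium_rhs(x + dt * k3, u, p, c)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        x = np.clip(x, 0.0, None)
    return x


def test_agrees_with_fine_step_explicit_integrator(producer, cleaner):
    x0 = [2.7, 0.1, 0.1, 0.0, 0.05]
    u = ReactorInputs(D=0.2, G_in=5.0, mode="chemostat")
    traj = simulate(x0, u, producer, cleaner, horizon=2.0, n_points=21)
    brute = _rk4(x0, u, producer, cleaner, 2.0, dt=1e-4)
    assert np.allclose(traj.states[-1], brute, rtol=1e-5, atol=1e-8)


def test_abiotic_chemostat_relaxation():
    # with all biological rates zeroed, glucose relaxes to G_in at rate D
    from proclean.params import default_config, producer_params

    cfg = dict(default_config())
    cfg.update(k_g=0.0, k_a=0.0, k_deg=0.0, Y_h=0.0)
    dead = producer_params(cfg)
    u = ReactorInputs(D=0.5, G_in=10.0, mode="chemostat")
    traj = simulate([0.0, 2.0, 1.0, 0.0, 0.0], u, dead, horizon=8.0)
    t = traj.times
    assert np.allclose(traj.states[:, 0], 10.0 * (1 - np.exp(-0.5 * t)), rtol=1e-5, atol=1e-7)
    assert np.allclose(traj.states[:, 1], 2.0 * np.exp(-0.5 * t), rtol=1e-5, atol=1e-7)
    assert np.allclose(traj.states[:, 2], 1.0 * np.exp(-0.5 * t), rtol=1e-5, atol=1e-7)


def test_diauxic_growth_in_batch(producer_wt):
    """Glucose-phase growth with acetate secretion, then growth on acetate."""
    traj = simulate([2.7, 0.0, 0.1, 0.0, 0.0], BATCH, producer_wt, horizon=12.0, n_points=2401)
    G, A, B = traj.states[:, 0], traj.states[:, 1], traj.states[:, 2]
    i_dep = np.argmax(G < 0.05)
    assert i_dep > 0, "glucose never depleted"
    t_dep = traj.times[i_dep]
    assert 3.0 < t_dep < 6.0
    # acetate accumulates during the glucose phase and peaks around depletion
    i_peak = np.argmax(A)
    assert A[i_peak] > 0.05
    assert abs(traj.times[i_peak] - t_dep) < 1.0
    # acetate is consumed afterwards, biomass keeps increasing more slowly
    assert A[-1] < 0.05 * A[i_peak]
    assert B[-1] > B[i_dep]


def test_dilution_consistency_along_trajectory(producer, cleaner):
    """Total producer biomass obeys d(B_totP)/dt = (mu_P - D) B_totP."""
    from proclean.model import growth_rates

    u = ReactorInputs(D=0.3, G_in=20.0, mode="chemostat")
    traj = simulate([0, 0, 0.05, 0, 0.05], u, producer, cleaner, horizon=30.0, n_points=3001)
    t, Btot = traj.times, traj.B_totP
    dBdt = np.gradient(Btot, t)
    mu = np.array([growth_rates(s, u, producer, cleaner)[0] for s in traj.states])
    mask = (Btot > 1e-4) & (t > 0.5)  # skip the sharp start-up transient
    assert np.allclose(dBdt[mask], (mu[mask] - u.D) * Btot[mask], rtol=2e-2, atol=1e-5)


def test_trajectory_export(tmp_path, producer, cleaner):
    u = ReactorInputs(D=0.3, G_in=20.0, mode="chemostat")
    traj = simulate([0, 0, 0.05, 0, 0.05], u, producer, cleaner, horizon=5.0, n_points=51)
    df = traj.to_dataframe()
    assert list(df.columns) == ["time", "G", "A", "B_P", "H", "B_C", "B_totP", "feed_rate"]
    assert (np.diff(df["time"]) > 0).all()
    assert (df[["G", "A", "B_P", "H", "B_C"]] >= 0).all().all()
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    assert path.read_text().startswith("time,")


def test_fedbatch_settles_into_exponential_growth(fedbatch_traj, producer):
    stats = exponential_regime_stats(fedbatch_traj)
    # growth rate equals the rate of increase of H in the exponential regime
    assert stats.mu_plus == pytest.approx(stats.dlogH_plus, abs=1e-3)
    assert stats.window[1] - stats.window[0] >= 5.0
    # product fraction of producer biomass equals Y_h throughout the window
    i = np.searchsorted(fedbatch_traj.times, stats.window[0])
    ratio = fedbatch_traj.states[i:, 3] / fedbatch_traj.B_totP[i:]
    assert np.allclose(ratio, producer.Y_h, atol=1e-3)
    assert 0 < stats.yield_plus < producer.Y_h


def test_exp_regime_requires_fedbatch_and_enough_time(producer, cleaner):
    u = ReactorInputs(D=0.3, G_in=20.0, mode="chemostat")
    traj = simulate([0, 0, 0.05, 0, 0.05], u, producer, cleaner, horizon=5.0, n_points=51)
    with pytest.raises(ValueError):
        exponential_regime_stats(traj)
    short = simulate([20, 0, 0.01, 0, 0.01], FEDBATCH, producer, cleaner,
                     horizon=6.0, n_points=301)
    with pytest.raises(ValueError, match="window"):
        exponential_regime_stats(short)
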