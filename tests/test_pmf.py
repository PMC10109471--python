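"""WHAM reconstruction, bootstrap errors and binding-energy readout."""

import numpy as np
import pytest

from bmcshell import synthetic
from bmcshell.pmf import (
    KB_KJ_PER_MOL_K,
    ConvergenceError,
    PMFCurve,
    UmbrellaWindow,
    Wham,
    WindowOverlapError,
    binding_energy,
    loglikelihood_wham,
    read_windows,
    restrained_profile,
    wham,
    write_windows,
)

KBT = KB_KJ_PER_MOL_K * 298.0


@pytest.fixture(scope="module")
def double_well_windows():
    """The reference window geometry: 15 windows, 1 Å apart, k = 1000 kJ/mol/nm²."""
    u = synthetic.double_well_potential(barrier=3 * KBT, half_separation=4.0,
                                        center=7.0)
    wins = synthetic.make_umbrella_samples(
        u, centers=np.arange(0.0, 15.0, 1.0), k_spring=1000.0,
        n_per_window=400, seed=11,
    )
    return u, wins


@pytest.fixture(scope="module")
def double_well_result(double_well_windows):
    _, wins = double_well_windows
    result = Wham(wins).fit()
    result.bootstrap(n_boot=40, seed=2)
    return result


def test_window_validation():
    with pytest.raises(ValueError):
        UmbrellaWindow(center=0.0, k_spring=-1.0, samples=np.zeros(10))
    with pytest.raises(ValueError, match="fewer than"):
        Wham([UmbrellaWindow(center=0.0, k_spring=1000.0, samples=np.zeros(10))])


def test_window_tsv_round_trip(tmp_path, double_well_windows):
    _, wins = double_well_windows
    path = tmp_path / "windows.tsv"
    write_windows(wins, path)
    back = read_windows(path)
    assert len(back) == len(wins)
    assert np.allclose(back[3].samples, wins[3].samples)
    assert back[3].center == wins[3].center


def test_unbiased_limit_reduces_to_log_histogram():
    """With a vanishing bias, WHAM is exactly −k_BT ln(histogram) + const."""
    rng = np.random.default_rng(5)
    samples = rng.normal(0.0, 1.0, 4000)
    w = UmbrellaWindow(center=0.0, k_spring=1e-9, samples=samples)
    curve = Wham([w], bin_width=0.25).fit().curve
    hist, _ = np.histogram(samples, bins=np.linspace(samples.min(),
                                                     samples.max() + 1e-9,
                                                     len(curve.xi) + 1))
    g = -KBT * np.log(np.where(hist > 0, hist, np.nan))
    g -= np.nanmin(g)
    assert np.nanmax(np.abs(curve.free_energy - g)) < 1e-8


def test_harmonic_recovery_within_bootstrap_error():
    """A harmonic well is recovered within 3×SE over the central 90 % mass."""
    kappa = 2.0  # kJ/mol/Å²
    u = synthetic.harmonic_potential(kappa, center=5.0)
    wins = synthetic.make_umbrella_samples(
        u, centers=np.arange(1.0, 9.5, 1.0), k_spring=1000.0,
        n_per_window=400, seed=3,
    )
    result = Wham(wins).fit()
    se = result.bootstrap(n_boot=40, seed=1)
    allsamp = np.concatenate([w.samples for w in wins])
    lo, hi = np.percentile(allsamp, [5, 95])
    sel = (result.xi >= lo) & (result.xi <= hi) & np.isfinite(result.free_energy)
    truth = u(result.xi[sel])
    # align by the mean offset (the PMF zero is set by its own minimum)
    diff = result.free_energy[sel] - truth
    diff -= diff.mean()
    assert np.abs(diff).max() < np.maximum(3 * se[sel], 0.3).max()


def test_two_identical_windows_merge(double_well_windows):
    _, wins = double_well_windows
    single = Wham([wins[7]], bin_width=0.2).fit().curve
    doubled = Wham([wins[7], UmbrellaWindow(wins[7].center, wins[7].k_spring,
                                            wins[7].samples.copy())],
                   bin_width=0.2).fit().curve
    sel = np.isfinite(single.free_energy)
    assert np.allclose(single.free_energy[sel], doubled.free_energy[sel],
                       atol=1e-6)


def test_double_well_barrier_within_two_se(double_well_windows, double_well_result):
    u, _ = double_well_windows
    result = double_well_result
    xi = result.xi
    g = result.free_energy
    se = result.curve.se
    inner = (xi > 1.5) & (xi < 12.5) & np.isfinite(g)
    g_in = g[inner] - np.nanmin(g[inner])
    true_in = u(xi[inner]) - u(3.0)
    # barrier: reconstructed value at the center vs the known 3 k_BT
    center_bin = np.argmin(np.abs(xi[inner] - 7.0))
    barrier_err = abs(g_in[center_bin] - true_in[center_bin])
    assert barrier_err < max(2 * se[inner][center_bin], 0.25)


def test_gauge_invariance(double_well_windows):
    """Shifting the order-parameter origin shifts the grid, not the profile."""
    _, wins = double_well_windows
    shift = 100.0
    shifted = [UmbrellaWindow(w.center + shift, w.k_spring, w.samples + shift)
               for w in wins]
    c0 = Wham(wins, bin_width=0.2).fit().curve
    c1 = Wham(shifted, bin_width=0.2).fit().curve
    sel = np.isfinite(c0.free_energy)
    assert np.allclose(c1.xi[sel] - shift, c0.xi[sel], atol=1e-9)
    assert np.allclose(c1.free_energy[sel], c0.free_energy[sel], atol=1e-9)


def test_loglikelihood_cross_check(double_well_windows, double_well_result):
    _, wins = double_well_windows
    ml = loglikelihood_wham(wins)
    sc = double_well_result.curve
    sel = np.isfinite(sc.free_energy) & np.isfinite(ml.free_energy)
    assert np.nanmax(np.abs(ml.free_energy[sel] - sc.free_energy[sel])) < 0.05


def test_non_overlapping_windows_raise():
    rng = np.random.default_rng(0)
    wins = [
        UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.3, 200)),
        UmbrellaWindow(10.0, 1000.0, rng.normal(10.0, 0.3, 200)),
    ]
    with pytest.raises(WindowOverlapError, match="no occupied bin"):
        Wham(wins).fit()


def test_non_convergence_reports_residual(double_well_windows):
    _, wins = double_well_windows
    with pytest.raises(ConvergenceError, match="residual"):
        Wham(wins).fit(tol=1e-12, max_iter=3)


def test_bootstrap_determinism_and_degeneracy(double_well_windows):
    _, wins = double_well_windows
    r1 = Wham(wins).fit()
    r2 = Wham(wins).fit()
    se1 = r1.bootstrap(n_boot=10, seed=7)
    se2 = r2.bootstrap(n_boot=10, seed=7)
    assert np.array_equal(se1, se2, equal_nan=True)
    with pytest.raises(ValueError):
        r1.bootstrap(n_boot=1)
    # degenerate data: resampling cannot change anything
    const = [UmbrellaWindow(c, 1000.0, np.full(60, 0.2))
             for c in (0.0, 0.4, 0.8)]
    res = Wham(const, bin_width=0.5).fit()
    se = res.bootstrap(n_boot=4, seed=0)
    assert np.nanmax(se) == 0.0


def test_bootstrap_se_shrinks_with_sample_size():
    u = synthetic.harmonic_potential(1.0, center=3.0)
    small = synthetic.make_umbrella_samples(u, np.arange(0.0, 7.0, 1.0),
                                            n_per_window=200, seed=9)
    large = synthetic.make_umbrella_samples(u, np.arange(0.0, 7.0, 1.0),
                                            n_per_window=800, seed=9)
    se_small = Wham(small).fit().bootstrap(n_boot=30, seed=1)
    se_large = Wham(large).fit().bootstrap(n_boot=30, seed=1)
    ratio = np.nanmedian(se_large) / np.nanmedian(se_small)
    assert 0.3 < ratio < 0.8  # ~1/sqrt(4) = 0.5


def test_binding_energy_flat_curve():
    curve = PMFCurve(xi=np.arange(10.0), free_energy=np.zeros(10),
                     temperature=298.0)
    value, plateaued = binding_energy(curve)
    assert value == 0.0 and plateaued


def test_binding_energy_recovers_well_depth():
    depth = 10 * KBT
    u = synthetic.morse_potential(depth=depth, width=1.5, x0=2.0)
    wins = synthetic.make_umbrella_samples(
        u, centers=np.arange(1.0, 16.0, 1.0), k_spring=1000.0,
        n_per_window=400, seed=21,
    )
    result = Wham(wins).fit()
    se = result.bootstrap(n_boot=30, seed=4)
    value, plateaued = result.binding_energy()
    assert plateaued
    tail_se = np.nanmedian(se[np.isfinite(result.free_energy)][-15:])
    assert abs(value - depth) < max(3 * tail_se, 0.1 * depth)


def test_truncated_curve_is_flagged():
    curve = PMFCurve(xi=np.arange(8.0), free_energy=np.arange(8.0) ** 2 / 4,
                     temperature=298.0)
    _, plateaued = binding_energy(curve)
    assert not plateaued


def test_restrained_profile_symmetry_and_annotation():
    u = synthetic.double_well_potential(barrier=2 * KBT, half_separation=4.0,
                                        center=0.0)
    wins = synthetic.make_umbrella_samples(
        u, centers=np.arange(-7.0, 7.5, 1.0), k_spring=1000.0,
        n_per_window=800, seed=6,
    )
    curve = restrained_profile(wins)
    assert "arrangements" in curve.annotations
    assert curve.annotations["arrangements"]["Arr-A"] == 0.0
    g = curve.free_energy
    sel = np.isfinite(g) & (np.abs(curve.xi) < 6.0)
    xi, gg = curve.xi[sel], g[sel]

    def refined_minimum(side):
        m = xi < 0 if side == "left" else xi > 0
        k = np.argmin(gg[m])
        x0 = xi[m][k]
        near = np.abs(xi - x0) <= 1.2
        coeff = np.polyfit(xi[near], gg[near], 2)
        return -coeff[1] / (2 * coeff[0])

    # two minima resolved near the constructed loci ±4
    assert abs(refined_minimum("left") + 4.0) < 0.5
    assert abs(refined_minimum("right") - 4.0) < 0.5
    # mirror symmetry within a loose statistical band
    interp = np.interp(-xi, xi, gg)
    assert np.nanmedian(np.abs(gg - interp)) < 1.0


def test_property_random_smooth_potentials_recovered():
    """Smooth random potentials are recovered within 3×SE in ≥ 9/10 cases."""
    rng = np.random.default_rng(2024)
    successes = 0
    for trial in range(10):
        amps = rng.uniform(-1.5, 1.5, 3)
        freqs = rng.uniform(0.2, 0.6, 3)
        phases = rng.uniform(0, 2 * np.pi, 3)

        def u(x, a=amps, f=freqs, p=phases):
            x = np.asarray(x, dtype=float)
            return sum(ai * np.sin(fi * x + pi) for ai, fi, pi in zip(a, f, p)) * KBT

        wins = synthetic.make_umbrella_samples(
            u, centers=np.arange(0.0, 12.0, 1.0), k_spring=1000.0,
            n_per_window=300, seed=int(rng.integers(0, 2**31 - 1)),
        )
        result = Wham(wins).fit()
        se = result.bootstrap(n_boot=25, seed=trial)
        allsamp = np.concatenate([w.samples for w in wins])
        lo, hi = np.percentile(allsamp, [5, 95])
        sel = (result.xi >= lo) & (result.xi <= hi) & np.isfinite(result.free_energy)
        diff = result.free_energy[sel] - u(result.xi[sel])
        diff -= diff.mean()
        # max error against 3× the (largest) bootstrap SE over the range
        if np.abs(diff).max() <= 3 * np.nanmax(se[sel]):
            successes += 1
    assert successes >= 9
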