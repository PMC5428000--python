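"""WHAM free-energy reconstruction, barriers, and diagnostics."""

import numpy as np
import pytest

from poremsm import synthetic as syn, wham
from poremsm.wham import KT_300K, UmbrellaWindow


def test_window_validation():
    with pytest.raises(ValueError):
        UmbrellaWindow(center=0.0, k_spring=-1.0, samples=[0.0])
    with pytest.raises(ValueError):
        UmbrellaWindow(center=0.0, k_spring=1.0, samples=[0.0, 0.1],
                       n_equil=2)


def test_equilibration_discard():
    w = UmbrellaWindow(center=0.0, k_spring=1.0,
                       samples=np.arange(6.0), n_equil=1)
    assert np.array_equal(w.retained, [1, 2, 3, 4, 5])


# -- solver ----------------------------------------------------------------


def test_single_unbiased_window_is_boltzmann_inversion():
    rng = np.random.default_rng(0)
    samples = rng.normal(0.0, 0.1, 20_000)
    win = UmbrellaWindow(center=0.0, k_spring=0.0, samples=samples)
    grid = (-0.5, 0.5, 40)
    prof = wham.wham_solve([win], kT=KT_300K, grid=grid, tol=1e-12)
    hist, _ = np.histogram(samples, bins=np.linspace(-0.5, 0.5, 41))
    ref = -KT_300K * np.log(hist / hist.sum(), where=hist > 0,
                            out=np.full(40, np.nan))
    ref -= np.nanmin(ref)
    m = prof.defined
    assert np.allclose(prof.free_energy[m], ref[m], atol=1e-10)


def test_flat_potential_recovered_flat():
    flat = lambda z: np.zeros_like(np.asarray(z, dtype=float))
    wins = syn.gen_umbrella_samples(flat, [-0.05, 0.0, 0.05], 2000.0,
                                    20_000, kT=KT_300K, seed=1)
    prof = wham.wham_solve(wins, kT=KT_300K, grid=(-0.12, 0.12, 48),
                           tol=1e-10)
    m = prof.defined & (prof.counts > 50)
    spread = prof.free_energy[m].max() - prof.free_energy[m].min()
    assert spread < 0.15  # kcal/mol, flat to well within thermal noise


def test_double_well_profile_rms_accuracy():
    well = syn.TiltedDoubleWell.from_barriers(2.5, 2.0)
    centers = well.default_window_centers()
    wins = syn.gen_umbrella_samples(well, centers, 8000.0, 5000,
                                    kT=KT_300K, seed=1)
    prof = wham.wham_solve(wins, kT=KT_300K, tol=1e-8)
    assert prof.converged
    m = prof.defined & (prof.counts > 20)
    ref = well(prof.z[m])
    diff = prof.free_energy[m] - ref
    rms = np.sqrt(np.mean((diff - diff.mean()) ** 2))
    assert rms < 0.2


def test_non_overlapping_windows_flagged_not_solved():
    w1 = UmbrellaWindow(center=-0.3, k_spring=1e5,
                        samples=np.random.default_rng(2).normal(-0.3,
                                                                0.002, 500))
    w2 = UmbrellaWindow(center=0.3, k_spring=1e5,
                        samples=np.random.default_rng(3).normal(0.3,
                                                                0.002, 500))
    prof = wham.wham_solve([w1, w2], kT=KT_300K, grid=(-0.5, 0.5, 100))
    assert not prof.converged
    assert "overlap" in prof.diagnostics["error"]


def test_window_reordering_leaves_profile_unchanged():
    well = syn.TiltedDoubleWell.from_barriers(1.5, 1.0)
    wins = syn.gen_umbrella_samples(well, well.default_window_centers(),
                                    8000.0, 2000, kT=KT_300K, seed=4)
    grid = (-0.2, 0.2, 80)
    a = wham.wham_solve(wins, kT=KT_300K, grid=grid, tol=1e-10)
    b = wham.wham_solve(wins[::-1], kT=KT_300K, grid=grid, tol=1e-10)
    m = a.defined
    assert np.allclose(a.free_energy[m], b.free_energy[m], atol=1e-10)


def test_grid_refinement_stability():
    # estimator property, checked with well-overlapped windows (soft
    # springs) so the answer is statistically pinned down
    well = syn.TiltedDoubleWell.from_barriers(2.0, 1.5)
    wins = syn.gen_umbrella_samples(well, well.default_window_centers(),
                                    500.0, 20_000, kT=KT_300K, seed=5)
    lo, hi = -0.25, 0.25
    coarse = wham.wham_solve(wins, kT=KT_300K, grid=(lo, hi, 64), tol=1e-10)
    fine = wham.wham_solve(wins, kT=KT_300K, grid=(lo, hi, 128), tol=1e-10)
    # compare free-energy differences on shared well-sampled regions
    pick = [-0.1, 0.0, 0.1]
    cz = [np.argmin(np.abs(coarse.z - p)) for p in pick]
    fz = [np.argmin(np.abs(fine.z - p)) for p in pick]
    dc = np.diff(coarse.free_energy[cz])
    df = np.diff(fine.free_energy[fz])
    assert np.allclose(dc, df, atol=0.05)


def test_grid_must_cover_samples():
    win = UmbrellaWindow(center=0.0, k_spring=100.0,
                         samples=np.array([-1.0, 0.0, 1.0]))
    with pytest.raises(ValueError, match="cover"):
        wham.wham_solve([win], grid=(-0.5, 0.5, 10))


# -- barriers --------------------------------------------------------------


def _profile_from_function(f, lo, hi, n):
    z = np.linspace(lo, hi, n)
    F = np.asarray(f(z), dtype=float)
    F -= F.min()
    return wham.PMFProfile(z=z, free_energy=F,
                           window_free_energies=np.zeros(1), kT=KT_300K,
                           n_iterations=0, converged=True,
                           counts=np.ones(n))


def test_symmetric_double_well_barriers_equal():
    prof = _profile_from_function(lambda z: (z ** 2 - 1) ** 2, -1.4, 1.4,
                                  201)
    rep = wham.barrier_heights(prof, ((-1.2, -0.8), (0.8, 1.2)))
    assert rep.forward == pytest.approx(rep.reverse, abs=1e-12)
    assert rep.forward == pytest.approx(1.0, abs=1e-3)


def test_flat_profile_has_zero_barriers():
    prof = _profile_from_function(lambda z: np.zeros_like(z), -1, 1, 101)
    rep = wham.barrier_heights(prof, ((-1, -0.5), (0.5, 1)))
    assert rep.forward == 0.0 and rep.reverse == 0.0


def test_adjacent_wells_without_interior_fail():
    prof = _profile_from_function(lambda z: z ** 2, -1, 1, 11)
    with pytest.raises(ValueError, match="between"):
        wham.barrier_heights(prof, ((-1.0, -0.9), (-0.9, -0.7)))


def test_barriers_recovered_through_full_path():
    true_f, true_r = 2.5, 2.0
    well = syn.TiltedDoubleWell.from_barriers(true_f, true_r)
    centers = well.default_window_centers()
    zl, zt, zr = well.stationary_points()
    gap = 0.45 * (zt - zl)
    profs = [wham.wham_solve(
        syn.gen_umbrella_samples(well, centers, 8000.0, 5000, kT=KT_300K,
                                 seed=100 + r),
        kT=KT_300K, grid=(-0.16, 0.16, 75), tol=1e-8) for r in range(4)]
    agg = wham.pmf_error_bars(profs, well_windows=((zl - gap, zl + gap),
                                                   (zr - gap, zr + gap)))
    b = agg["barriers"]
    assert b.forward == pytest.approx(true_f, abs=0.35)
    assert b.reverse == pytest.approx(true_r, abs=0.35)
    assert b.forward_sd is not None and b.forward_sd > 0


# -- overlap, replicates, drift --------------------------------------------


def test_identical_windows_overlap_fully():
    s = np.random.default_rng(6).normal(0, 0.05, 5000)
    w = UmbrellaWindow(center=0.0, k_spring=1.0, samples=s)
    coeffs, flag = wham.histogram_overlap([w, w], (-0.3, 0.3, 60))
    assert coeffs[0] == pytest.approx(1.0)
    assert flag


def test_disjoint_windows_do_not_overlap():
    rng = np.random.default_rng(7)
    w1 = UmbrellaWindow(center=-0.2, k_spring=1.0,
                        samples=rng.normal(-0.2, 0.01, 1000))
    w2 = UmbrellaWindow(center=0.2, k_spring=1.0,
                        samples=rng.normal(0.2, 0.01, 1000))
    coeffs, flag = wham.histogram_overlap([w1, w2], (-0.4, 0.4, 80))
    assert coeffs[0] == 0.0
    assert not flag


def test_gaussian_windows_one_sigma_apart():
    # analytic overlap of unit-variance Gaussians 1 sigma apart:
    # 2 Phi(-1/2) ~ 0.617
    rng = np.random.default_rng(8)
    n = 200_000
    w1 = UmbrellaWindow(center=0.0, k_spring=1.0, samples=rng.normal(0, 1, n))
    w2 = UmbrellaWindow(center=1.0, k_spring=1.0, samples=rng.normal(1, 1, n))
    coeffs, _ = wham.histogram_overlap([w1, w2], (-6, 7, 130))
    assert coeffs[0] == pytest.approx(0.6171, abs=0.01)


def test_identical_replicates_have_zero_spread():
    prof = _profile_from_function(lambda z: z ** 2, -1, 1, 51)
    agg = wham.pmf_error_bars([prof, prof, prof])
    assert np.nanmax(agg["sd"]) == pytest.approx(0.0, abs=1e-14)


def test_constant_shift_removed_by_reanchoring():
    prof1 = _profile_from_function(lambda z: z ** 2, -1, 1, 51)
    shifted = wham.PMFProfile(z=prof1.z,
                              free_energy=prof1.free_energy + 3.7,
                              window_free_energies=np.zeros(1), kT=KT_300K,
                              n_iterations=0, converged=True,
                              counts=prof1.counts)
    agg = wham.pmf_error_bars([prof1, shifted])
    assert np.nanmax(agg["sd"]) == pytest.approx(0.0, abs=1e-12)


def test_mismatched_replicate_grids_rejected():
    p1 = _profile_from_function(lambda z: z ** 2, -1, 1, 51)
    p2 = _profile_from_function(lambda z: z ** 2, -1, 1, 41)
    with pytest.raises(ValueError, match="grid"):
        wham.pmf_error_bars([p1, p2])


def test_replicate_barrier_spread_consistent_with_bootstrap():
    # spread over independently seeded replicates ~ bootstrap resampling sd
    well = syn.TiltedDoubleWell.from_barriers(2.0, 1.5)
    centers = well.default_window_centers()
    zl, zt, zr = well.stationary_points()
    gap = 0.45 * (zt - zl)
    wellw = ((zl - gap, zl + gap), (zr - gap, zr + gap))
    grid = (-0.16, 0.16, 75)

    def fit(wins):
        prof = wham.wham_solve(wins, kT=KT_300K, grid=grid, tol=1e-6)
        return wham.barrier_heights(prof, wellw).forward

    reps = [fit(syn.gen_umbrella_samples(well, centers, 8000.0, 3000,
                                         kT=KT_300K, seed=300 + r))
            for r in range(8)]
    rep_sd = np.std(reps, ddof=1)
    rng = np.random.default_rng(9)
    base = syn.gen_umbrella_samples(well, centers, 8000.0, 3000,
                                    kT=KT_300K, seed=400)
    boot = []
    for _ in range(8):
        wins = [UmbrellaWindow(w.center, w.k_spring,
                               rng.choice(w.samples, len(w.samples)))
                for w in base]
        boot.append(fit(wins))
    boot_sd = np.std(boot, ddof=1)
    assert rep_sd < 3.0 * boot_sd + 0.05


def test_drift_check():
    assert wham.drift_check(np.full(100, 0.1), 0.5) == (True, None)
    series = np.zeros(200)
    series[100:] = 2.0
    ok, idx = wham.drift_check(series, 0.5)
    assert not ok and idx == 100
    assert wham.drift_check(series, np.inf) == (True, None)
    # equilibration portion is exempt
    ok2, idx2 = wham.drift_check(series, 0.5, n_equil=150)
    assert not ok2 and idx2 == 150
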