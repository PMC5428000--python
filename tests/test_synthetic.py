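"""Generators: Langevin sampler, coupled chain, umbrella windows."""

import numpy as np
import pytest
from scipy import stats

from poremsm import synthetic as syn
from poremsm.wham import KT_300K


# -- Langevin on Gaussian-mixture potentials -------------------------------


def test_harmonic_well_equipartition():
    # U = kT (x/w)^2 / 2  ->  stiffness k = kT / w^2, variance kT/k = w^2
    w = 0.3
    spec = syn.PotentialSpec([syn.Well((0.0,), 1.0, w)], kT=KT_300K)
    traj = syn.gen_langevin_features(spec, 100_000, 0.01, seed=2)
    assert traj.data.var() == pytest.approx(w ** 2, rel=0.05)


def test_zero_temperature_stays_at_minimum():
    spec = syn.PotentialSpec([syn.Well((0.5,), 1.0, 0.2)], kT=0.0)
    traj = syn.gen_langevin_features(spec, 500, 0.01, seed=0, x0=[0.5])
    assert np.allclose(traj.data, 0.5)


def test_four_well_occupancies_match_quadrature_weights():
    depths = [2.0, 1.7, 1.4, 2.0]
    centers = [(-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (1.0, 1.0)]
    spec = syn.PotentialSpec(
        [syn.Well(c, d, 0.35) for c, d in zip(centers, depths)], kT=KT_300K)
    # oracle: grid quadrature of exp(-U/kT) over nearest-center basins
    g = np.linspace(-2.5, 2.5, 201)
    X, Y = np.meshgrid(g, g)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    dens = np.exp([-spec.potential(p) / KT_300K for p in pts])
    basin = spec.assign_well(pts)
    weights = np.array([dens[basin == i].sum() for i in range(4)])
    weights /= weights.sum()
    assert np.allclose(weights, spec.well_weights(), atol=1e-3)

    traj = syn.gen_langevin_features(spec, 200_000, 0.01, seed=9)
    lab = spec.assign_well(traj.data)
    occ = np.bincount(lab, minlength=4) / len(lab)
    # sampling error from block averaging (accounts for dwell correlation)
    blocks = np.array([np.bincount(b, minlength=4) / len(b)
                       for b in np.array_split(lab, 20)])
    sigma = blocks.std(axis=0, ddof=1) / np.sqrt(len(blocks))
    assert np.all(np.abs(occ - weights) < 3 * sigma)


def test_boltzmann_distribution_on_double_well():
    # chi^2 goodness of fit against exp(-U/kT), decorrelated by thinning
    spec = syn.PotentialSpec([syn.Well((-0.5,), 1.0, 0.18),
                              syn.Well((0.5,), 1.0, 0.18)], kT=KT_300K)
    traj = syn.gen_langevin_features(spec, 100_000, 0.01, seed=12)
    x = traj.data[::25, 0]  # thin past the intra-well relaxation time
    edges = np.linspace(-1.1, 1.1, 23)
    obs, _ = np.histogram(x, bins=edges)
    g = np.linspace(edges[0], edges[-1], 4001)
    dens = np.exp([-spec.potential([z]) / KT_300K for z in g])
    cum = np.interp(edges, g, np.cumsum(dens) / dens.sum())
    exp_p = np.diff(cum)
    keep = exp_p * len(x) > 5
    f_exp = obs[keep].sum() * exp_p[keep] / exp_p[keep].sum()
    chi2, p = stats.chisquare(obs[keep], f_exp, ddof=0)
    assert p > 0.01


def test_unstable_timestep_reports_divergence_step():
    spec = syn.PotentialSpec([syn.Well((0.0,), 1.0, 0.01)], kT=KT_300K)
    with pytest.raises(syn.LangevinDivergenceError) as err:
        syn.gen_langevin_features(spec, 5000, 50.0, seed=0, x0=[0.02])
    assert err.value.step >= 0


def test_langevin_determinism():
    spec = syn.PotentialSpec([syn.Well((0.0, 0.0), 1.0, 0.3)], kT=KT_300K)
    a = syn.gen_langevin_features(spec, 2000, 0.01, seed=7)
    b = syn.gen_langevin_features(spec, 2000, 0.01, seed=7)
    assert np.array_equal(a.data, b.data)


def test_potential_spec_validation():
    with pytest.raises(ValueError):
        syn.PotentialSpec([], kT=1.0)
    with pytest.raises(ValueError):
        syn.PotentialSpec([syn.Well((0.0,), 1.0, -0.1)])


# -- tilted double well ----------------------------------------------------


@pytest.mark.parametrize("fwd,rev", [(2.5, 2.0), (3.5, 3.0), (1.0, 1.0)])
def test_tilted_double_well_matches_requested_barriers(fwd, rev):
    w = syn.TiltedDoubleWell.from_barriers(fwd, rev)
    f, r = w.barriers()
    assert f == pytest.approx(fwd, abs=1e-8)
    assert r == pytest.approx(rev, abs=1e-8)
    zl, zt, zr = w.stationary_points()
    assert zl < zt < zr
    centers = w.default_window_centers()
    assert np.all(np.diff(centers) > 0)
    # the five-window layout spaces windows by roughly 0.05 nm
    assert np.allclose(np.diff(centers), 0.05, atol=0.02)


# -- coupled (macro, SF, ion) chain ----------------------------------------


def test_non_stochastic_rows_rejected():
    spec = syn.default_coupled_chain_spec()
    bad = spec.macro_T.copy()
    bad[1, 1] += 0.1
    with pytest.raises(ValueError, match="rows"):
        syn.CoupledChainSpec(spec.macro_labels, bad, spec.sf_flip,
                             spec.ion_T)


def _single_macro_spec(a, b):
    ion_T = np.stack([[syn.ion_hop_matrix({6: 0.0, 14: 1.0}),
                       syn.ion_hop_matrix({6: 0.0, 14: 1.0})]])
    return syn.CoupledChainSpec(("only",), np.array([[1.0]]),
                                np.array([[a, b]]), ion_T)


def test_sf_stationary_odds_equal_flip_ratio():
    # two-state chain: stationary pinched:open odds = a / b
    a, b = 0.12, 0.03
    spec = _single_macro_spec(a, b)
    chain = syn.gen_coupled_chain(spec, 200_000, seed=5)
    n_p = np.sum(chain.sf == 1)
    odds = n_p / (len(chain.sf) - n_p)
    assert odds == pytest.approx(a / b, rel=0.1)


def test_zero_flip_probabilities_freeze_labels():
    spec = _single_macro_spec(0.0, 0.0)
    chain = syn.gen_coupled_chain(spec, 2000, seed=1, start=(0, 1, 6))
    assert np.all(chain.sf == chain.sf[0])


def test_symmetric_flips_give_even_odds():
    spec = _single_macro_spec(0.25, 0.25)
    chain = syn.gen_coupled_chain(spec, 100_000, seed=8)
    frac = np.mean(chain.sf)
    assert frac == pytest.approx(0.5, abs=0.01)


def test_chain_determinism_and_length():
    spec = syn.default_coupled_chain_spec()
    a = syn.gen_coupled_chain(spec, 5000, seed=42)
    b = syn.gen_coupled_chain(spec, 5000, seed=42)
    assert np.array_equal(a.macro, b.macro)
    assert np.array_equal(a.sf, b.sf)
    assert np.array_equal(a.ion, b.ion)
    assert len(a) == 5000


def test_empirical_transition_frequencies_match_spec():
    # within a single macrostate the sampled ion chain reproduces its
    # transition table to 3 binomial sigma
    energies = {6: 0.0, 14: 0.8, 7: 0.8, 13: 1.5}
    T = syn.ion_hop_matrix(energies, move_prob=0.5)
    spec = syn.CoupledChainSpec(("only",), np.array([[1.0]]),
                                np.array([[0.0, 0.0]]),
                                np.stack([[T, T]]))
    chain = syn.gen_coupled_chain(spec, 100_000, seed=6, start=(0, 0, 6))
    ion = chain.ion
    for s in energies:
        rows = np.nonzero(ion[:-1] == s)[0]
        n = len(rows)
        emp = np.bincount(ion[rows + 1], minlength=16) / n
        sig = np.sqrt(T[s] * (1 - T[s]) / n)
        assert np.all(np.abs(emp - T[s]) <= 3 * sig + 1e-12)


def test_ion_hop_matrix_is_gibbs_reversible():
    energies = {6: 0.0, 14: 1.2, 7: 1.2, 13: 2.2, 11: 2.2}
    T = syn.ion_hop_matrix(energies)
    codes = sorted(energies)
    pi = np.exp([-energies[c] for c in codes])
    pi /= pi.sum()
    for i, ci in enumerate(codes):
        for j, cj in enumerate(codes):
            assert pi[i] * T[ci, cj] == pytest.approx(pi[j] * T[cj, ci],
                                                      abs=1e-12)


def test_exact_conditional_odds_track_design_ratio():
    # the default spec's Down-state conditional odds stay within a few
    # percent of the designed 75:1 flip ratio (timescale separation)
    spec = syn.default_coupled_chain_spec()
    down = spec.macro_labels.index("Down")
    exact = spec.conditional_sf_odds(down)
    assert exact == pytest.approx(75.0, rel=0.05)


# -- umbrella-window sampler -----------------------------------------------


def test_flat_potential_window_is_gaussian():
    k, kT = 8000.0, KT_300K
    wins = syn.gen_umbrella_samples(lambda z: np.zeros_like(np.asarray(z)),
                                    [0.2], k, 50_000, kT=kT, seed=3)
    s = wins[0].retained
    assert s.mean() == pytest.approx(0.2, abs=3 * np.sqrt(kT / k / 50_000))
    assert s.var() == pytest.approx(kT / k, rel=0.05)


def test_very_stiff_spring_pins_samples():
    wins = syn.gen_umbrella_samples(lambda z: np.zeros_like(np.asarray(z)),
                                    [0.1], 1e9, 2000, seed=1)
    assert np.max(np.abs(wins[0].samples - 0.1)) < 1e-3


def test_linear_potential_shifts_mean_by_slope_over_k():
    m, k, kT = 30.0, 8000.0, KT_300K
    wins = syn.gen_umbrella_samples(lambda z: m * np.asarray(z), [0.0], k,
                                    50_000, kT=kT, seed=4)
    expect = -m / k
    assert wins[0].samples.mean() == pytest.approx(
        expect, abs=3 * np.sqrt(kT / k / 50_000))


def test_metropolis_mode_records_sampler():
    wins = syn.gen_umbrella_samples(lambda z: np.asarray(z) ** 2, [0.0],
                                    1000.0, 500, seed=5,
                                    method="metropolis", stride=5)
    assert wins[0].metadata["sampler"] == "metropolis"
    assert wins[0].metadata["stride"] == 5
    assert len(wins[0].samples) == 500


@pytest.mark.filterwarnings("ignore:invalid value encountered in log")
def test_non_finite_potential_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        syn.gen_umbrella_samples(lambda z: np.log(np.asarray(z)), [-0.5],
                                 100.0, 100, seed=0)


# -- toy frames ------------------------------------------------------------


def test_vacant_schedule_has_no_ions():
    frame = syn.gen_toy_channel_frames(["OOOO"])[0]
    assert frame.ion_xyz.shape == (0, 3)


def test_toy_frame_pdb_round_trip(tmp_path):
    import mdtraj as md

    frame = syn.gen_toy_channel_frames(["OXXO"], n_cavity_waters=2)[0]
    path = tmp_path / "frame.pdb"
    frame.to_pdb(path)
    loaded = md.load(str(path))
    # 20 carbonyls + 2 markers + 2 ions + 2 waters
    assert loaded.n_atoms == 26
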