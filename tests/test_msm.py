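"""MSM estimation: clustering, counting, reversible MLE, kinetics."""

import numpy as np
import pytest

from poremsm import msm, synthetic as syn, tica
from poremsm.wham import KT_300K


# -- clustering ------------------------------------------------------------


def test_kmeans_k_equals_distinct_points_zero_inertia():
    pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
    a = msm.cluster_minibatch_kmeans([pts], k=4, seed=0)
    assert a.inertia == pytest.approx(0.0, abs=1e-12)


def test_kmeans_separated_blobs_partition_exactly():
    rng = np.random.default_rng(1)
    blob1 = rng.normal(0, 0.05, (400, 2))
    blob2 = rng.normal(0, 0.05, (400, 2)) + [2.0, 0]
    X = np.vstack([blob1, blob2])
    a = msm.cluster_minibatch_kmeans([X], k=2, seed=3)
    lbl = a.dtrajs[0]
    assert len(np.unique(lbl[:400])) == 1
    assert len(np.unique(lbl[400:])) == 1
    assert lbl[0] != lbl[400]


def test_kmeans_duplication_leaves_converged_centers_unchanged():
    # with well-separated blobs the converged centers are the blob means,
    # independent of frame multiplicity
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(0, 0.05, (300, 2)),
                   rng.normal(0, 0.05, (300, 2)) + [3.0, 0]])
    c1 = msm.cluster_minibatch_kmeans([X], k=2, seed=4).centers
    c2 = msm.cluster_minibatch_kmeans([np.vstack([X, X])], k=2,
                                      seed=4).centers
    c1 = c1[np.argsort(c1[:, 0])]
    c2 = c2[np.argsort(c2[:, 0])]
    assert np.allclose(c1, c2, atol=1e-8)


def test_kmeans_more_clusters_than_frames():
    with pytest.raises(ValueError):
        msm.cluster_minibatch_kmeans([np.zeros((3, 2))], k=5)


# -- counting and connectivity ---------------------------------------------


def test_sliding_counts_enumerate_pairs():
    C = msm.count_transitions([np.array([0, 0, 1, 1])], 1)
    assert np.array_equal(C.counts, [[1, 1], [0, 1]])
    C2 = msm.count_transitions([np.array([0, 0, 1, 1])], 2)
    assert np.array_equal(C2.counts, [[0, 2], [0, 0]])


def test_constant_sequence_counts_on_diagonal():
    C = msm.count_transitions([np.zeros(10, dtype=int)], 1)
    assert C.counts[0, 0] == 9
    assert C.total == 9


def test_counts_total_in_sliding_mode():
    d1, d2 = np.array([0, 1, 0, 1, 1]), np.array([1, 0, 0])
    C = msm.count_transitions([d1, d2], 2)
    assert C.total == (len(d1) - 2) + (len(d2) - 2)


def test_counting_rejects_too_short_sequences():
    with pytest.raises(ValueError):
        msm.count_transitions([np.array([0, 1])], 5)


def test_largest_ergodic_set():
    full = np.ones((3, 3))
    assert np.array_equal(msm.largest_ergodic_set(full), [0, 1, 2])
    blocks = np.zeros((5, 5))
    blocks[:3, :3] = 1
    blocks[3:, 3:] = 1
    assert np.array_equal(msm.largest_ergodic_set(blocks), [0, 1, 2])
    # one-way edge into an absorbing, strongly connected pair
    chain = np.array([[1, 1, 0], [0, 1, 1], [0, 1, 1]])
    assert np.array_equal(msm.largest_ergodic_set(chain), [1, 2])


# -- reversible MLE --------------------------------------------------------


def test_symmetric_counts_give_row_normalization():
    C = np.array([[6, 2, 2], [2, 8, 0], [2, 0, 4]], dtype=float)
    m = msm.mle_reversible_tmatrix(C)
    assert np.allclose(m.transition_matrix, C / C.sum(axis=1, keepdims=True),
                       atol=1e-12)


def test_two_state_mle_oracle():
    # every 2-state chain is reversible, so the MLE is row normalization
    # and pi follows from the balance 0.1 pi1 = 0.2 pi2
    m = msm.mle_reversible_tmatrix(np.array([[90, 10], [20, 80]]))
    assert np.allclose(m.transition_matrix, [[0.9, 0.1], [0.2, 0.8]],
                       atol=1e-10)
    assert np.allclose(m.stationary_distribution, [2 / 3, 1 / 3], atol=1e-10)


def test_mle_invariants_and_local_optimality():
    rng = np.random.default_rng(5)
    C = rng.integers(0, 30, (6, 6)) + np.eye(6, dtype=int) * 10
    C[C.sum(axis=1) == 0, 0] = 1
    model = msm.mle_reversible_tmatrix(C + 1)  # ensure irreducible
    T, pi = model.transition_matrix, model.stationary_distribution
    counts = np.asarray(C + 1, dtype=float)

    def loglik(Tm):
        return np.sum(counts * np.log(Tm))

    best = loglik(T)
    # random detailed-balance-preserving perturbations never improve it
    for k in range(20):
        E = rng.normal(0, 1e-4, (6, 6))
        x = pi[:, None] * T + (E + E.T) / 2
        x = np.abs(x)
        x /= x.sum()
        Tp = x / x.sum(axis=1, keepdims=True)
        assert loglik(Tp) <= best + 1e-9


def test_mle_recovers_generating_matrix():
    rng = np.random.default_rng(6)
    x = rng.random((4, 4))
    x = x + x.T
    x /= x.sum()
    T_true = x / x.sum(axis=1, keepdims=True)
    pi_true = x.sum(axis=1)
    # direct chain sampling, 1e5 transitions
    n = 100_000
    cum = np.cumsum(T_true, axis=1)
    s = 0
    dtraj = np.empty(n, dtype=int)
    u = rng.random(n)
    for t in range(n):
        s = int(np.searchsorted(cum[s], u[t]))
        dtraj[t] = s
    model = msm.fit_msm([dtraj], 1)
    N_i = np.bincount(dtraj[:-1], minlength=4)[:, None]
    sigma = np.sqrt(T_true * (1 - T_true) / N_i)
    assert np.max(np.abs(model.transition_matrix - T_true) /
                  (3 * sigma + 1e-12)) < 1.0


def test_mle_requires_connected_counts():
    with pytest.raises(ValueError):
        msm.mle_reversible_tmatrix(np.array([[5, 0], [0, 0]]))


# -- derived kinetics ------------------------------------------------------


def test_implied_timescale_arithmetic():
    T = np.array([[0.95, 0.05], [0.05, 0.95]])  # lambda_2 = 0.9
    model = msm.MarkovModel(T, np.array([0.5, 0.5]), lag_time=20.0,
                            active_set=np.arange(2))
    assert model.timescales()[0] == pytest.approx(-20 / np.log(0.9),
                                                  rel=1e-12)


def test_implied_timescales_table_nonincreasing():
    rng = np.random.default_rng(7)
    x = rng.random((5, 5)) + np.eye(5) * 4
    x = x + x.T
    T = x / x.sum(axis=1, keepdims=True)
    cum = np.cumsum(T, axis=1)
    s, n = 0, 50_000
    dtraj = np.empty(n, dtype=int)
    u = rng.random(n)
    for t in range(n):
        s = int(np.searchsorted(cum[s], u[t]))
        dtraj[t] = s
    table = msm.implied_timescales([dtraj], lags=[1, 2, 5], n_timescales=3)
    for _, row in table.iterrows():
        vals = row.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert np.all(np.diff(vals) <= 1e-9)


def test_mfpt_geometric_waiting_time():
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    model = msm.mle_reversible_tmatrix(np.array([[90, 10], [20, 80]]))
    assert msm.mfpt(model, [0], [1]) == pytest.approx(10.0, abs=1e-8)


def test_mfpt_source_equals_target_is_zero():
    model = msm.mle_reversible_tmatrix(np.array([[90, 10], [20, 80]]))
    assert msm.mfpt(model, [0], [0]) == 0.0


def test_mfpt_matches_dense_absorbing_solve():
    rng = np.random.default_rng(8)
    x = rng.random((3, 3)) + 0.1
    x = x + x.T
    x /= x.sum()
    T = x / x.sum(axis=1, keepdims=True)
    pi = x.sum(axis=1)
    model = msm.MarkovModel(T, pi, lag_time=1.0, active_set=np.arange(3))
    # independent oracle: fundamental-matrix solve m = (I - Q)^-1 1
    Q = T[np.ix_([0, 1], [0, 1])]
    m = np.linalg.inv(np.eye(2) - Q) @ np.ones(2)
    expected = (pi[:2] / pi[:2].sum()) @ m
    assert msm.mfpt(model, [0, 1], [2]) == pytest.approx(expected, abs=1e-10)


def test_representative_trajectory_sampling():
    T = np.eye(3)
    model = msm.MarkovModel(T, np.full(3, 1 / 3), lag_time=1.0,
                            active_set=np.arange(3))
    states = msm.sample_msm_trajectory(model, 100, seed=3)
    assert len(np.unique(states)) == 1
    again = msm.sample_msm_trajectory(model, 100, seed=3)
    assert np.array_equal(states, again)


def test_sampled_frequencies_match_stationary_distribution():
    rng = np.random.default_rng(9)
    x = rng.random((5, 5)) + 0.2
    x = x + x.T
    x /= x.sum()
    T = x / x.sum(axis=1, keepdims=True)
    pi = x.sum(axis=1)
    model = msm.MarkovModel(T, pi, lag_time=1.0, active_set=np.arange(5))
    states = msm.sample_msm_trajectory(model, 100_000, seed=10)
    freq = np.bincount(states, minlength=5) / len(states)
    assert 0.5 * np.abs(freq - pi).sum() < 0.02  # total variation


def test_empty_frame_library_raises():
    model = msm.mle_reversible_tmatrix(np.array([[5, 5], [5, 5]]))
    with pytest.raises(ValueError, match="library"):
        msm.sample_msm_trajectory(model, 50, seed=0,
                                  frame_library={0: [1, 2], 1: []})


# -- end-to-end parameter recovery -----------------------------------------


def double_well_relaxation_oracle(spec, dt, friction=1.0, n_grid=400):
    """Slowest relaxation time of the overdamped dynamics on a fine grid.

    Discretizes the 1-D Smoluchowski generator with detailed-balance rates
    q_{i,i+-1} = (D / h^2) exp(-(U_{i+-1} - U_i) / 2kT) and returns
    -1 / lambda_2 in physical time units.
    """
    z = np.linspace(-1.2, 1.2, n_grid)
    h = z[1] - z[0]
    U = np.array([spec.potential([zz]) for zz in z])
    D = spec.kT / friction
    Q = np.zeros((n_grid, n_grid))
    for i in range(n_grid - 1):
        Q[i, i + 1] = D / h ** 2 * np.exp(-(U[i + 1] - U[i]) / (2 * spec.kT))
        Q[i + 1, i] = D / h ** 2 * np.exp(-(U[i] - U[i + 1]) / (2 * spec.kT))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    w = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
    return -1.0 / w[1]


def test_pipeline_recovers_double_well_relaxation_time():
    spec = syn.PotentialSpec([syn.Well((-0.5,), 1.0, 0.16),
                              syn.Well((0.5,), 1.0, 0.16)], kT=KT_300K)
    dt = 0.005
    traj = syn.gen_langevin_features(spec, 200_000, dt, seed=20)
    t_oracle = double_well_relaxation_oracle(spec, dt)

    rng = np.random.default_rng(21)
    lift = rng.standard_normal((1, 5))
    feats = traj.data @ lift + 0.05 * rng.standard_normal((len(traj), 5))
    model = tica.fit([feats], lag=5, n_components=2)
    tics = tica.project([feats], model)
    assign = msm.cluster_minibatch_kmeans(tics, k=40, seed=22)
    mm = msm.fit_msm(assign.dtrajs, lag_frames=40, dt=dt)
    t2 = mm.timescales(1)[0]
    assert t_oracle / 1.5 < t2 < t_oracle * 1.5
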