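"""Markov state model estimation and kinetics.

Discretizes tIC space with mini-batch k-means, counts sliding-window
transitions at a lag time, trims to the largest strongly connected (ergodic)
set, and fits the reversible maximum-likelihood transition matrix — the
estimator that maximizes prod T_ij^{C_ij} subject to row-stochasticity and
detailed balance pi_i T_ij = pi_j T_ji, via the standard self-consistent
fixed-point iteration on the symmetric auxiliary variables
x_ij = pi_i T_ij. Derived kinetics: implied timescales, mean first-passage
times, and representative-trajectory sampling from the fitted chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import MiniBatchKMeans

__all__ = [
    "MicrostateAssignment",
    "CountMatrix",
    "MarkovModel",
    "MSMConvergenceError",
    "cluster_minibatch_kmeans",
    "count_transitions",
    "largest_ergodic_set",
    "mle_reversible_tmatrix",
    "fit_msm",
    "implied_timescales",
    "mfpt",
    "sample_msm_trajectory",
]


class MSMConvergenceError(RuntimeError):
    pass


@dataclass
class MicrostateAssignment:
    """k-means microstates: per-trajectory integer labels + centers."""

    dtrajs: list[np.ndarray]
    centers: np.ndarray
    inertia: float
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag_frames: int
    mode: str = "sliding"

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class MarkovModel:
    """Reversible MSM at a stated lag.

    ``transition_matrix`` is row-stochastic on the active set;
    ``stationary_distribution`` satisfies pi T = pi and detailed balance;
    ``active_set`` maps model state indices back to original labels;
    ``lag_time`` is the physical lag (lag_frames * frame spacing) used to
    express timescales and MFPTs in physical time.
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    lag_time: float
    active_set: np.ndarray
    counts: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = self.transition_matrix
        pi = self.stationary_distribution
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1 (1e-12)")
        if np.max(np.abs(pi @ T - pi)) > 1e-10:
            raise ValueError("pi is not stationary for T (1e-10)")
        flux = pi[:, None] * T
        if np.max(np.abs(flux - flux.T)) > 1e-8:
            raise ValueError("detailed balance violated beyond 1e-8")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real spectrum, descending, via the pi-symmetrized form."""
        pi = self.stationary_distribution
        s = np.sqrt(pi)
        sym = (s[:, None] * self.transition_matrix) / s[None, :]
        sym = 0.5 * (sym + sym.T)
        w = scipy.linalg.eigvalsh(sym)[::-1]
        return w if k is None else w[:k]

    def right_eigenvectors(self, k: int):
        """(eigenvalues, right eigenvectors) of T, first vector constant."""
        pi = self.stationary_distribution
        s = np.sqrt(pi)
        sym = (s[:, None] * self.transition_matrix) / s[None, :]
        sym = 0.5 * (sym + sym.T)
        w, u = scipy.linalg.eigh(sym)
        order = np.argsort(w)[::-1][:k]
        w, u = w[order], u[:, order]
        psi = u / s[:, None]
        # normalize the first (Perron) vector to exactly 1
        psi[:, 0] = psi[:, 0] / psi[0, 0] if psi[0, 0] != 0 else 1.0
        return w, psi

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales -lag / ln lambda_i for i >= 2 (physical time)."""
        w = self.eigenvalues()[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -self.lag_time / np.log(w)
        t[w <= 0] = np.nan
        t[w >= 1] = np.inf
        return t if k is None else t[:k]

    def save(self, path) -> None:
        np.savez(path, T=self.transition_matrix,
                 pi=self.stationary_distribution, lag_time=self.lag_time,
                 active_set=self.active_set,
                 counts=(np.zeros((0, 0)) if self.counts is None
                         else self.counts))

    @classmethod
    def load(cls, path) -> "MarkovModel":
        with np.load(path) as f:
            counts = f["counts"]
            return cls(transition_matrix=f["T"],
                       stationary_distribution=f["pi"],
                       lag_time=float(f["lag_time"]),
                       active_set=f["active_set"],
                       counts=None if counts.size == 0 else counts)


# ---------------------------------------------------------------------------


def _nearest_center(X, centers, chunk=2_000_000):
    """Labels and squared distances to the nearest center (ties: lower idx)."""
    n, k = X.shape[0], centers.shape[0]
    labels = np.empty(n, dtype=np.int64)
    mind2 = np.empty(n)
    step = max(1, chunk // max(k, 1))
    for i in range(0, n, step):
        d2 = ((X[i:i + step, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels[i:i + step] = np.argmin(d2, axis=1)
        mind2[i:i + step] = np.min(d2, axis=1)
    return labels, mind2


def cluster_minibatch_kmeans(tic_trajs, k: int, batch_size: int = 1024,
                             seed: int = 0,
                             polish_iters: int = 25) -> MicrostateAssignment:
    """Mini-batch k-means in tIC space, polished to a Lloyd fixed point.

    Centers come from scikit-learn's mini-batch fit (deterministic given the
    seed), then a few full-data Lloyd iterations remove the stochastic
    update residue; clusters emptied along the way are reseeded from the
    farthest frame. Every frame is finally assigned to its nearest center,
    ties going to the lower center index.
    """
    if isinstance(tic_trajs, np.ndarray):
        tic_trajs = [tic_trajs]
    arrays = [np.atleast_2d(np.asarray(t, dtype=float)) for t in tic_trajs]
    X = np.concatenate(arrays, axis=0)
    if k > X.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of frames {X.shape[0]}")
    km = MiniBatchKMeans(n_clusters=k, batch_size=batch_size,
                         random_state=seed, n_init=3)
    km.fit(X)
    centers = km.cluster_centers_.astype(float)
    for _ in range(polish_iters):
        labels, mind2 = _nearest_center(X, centers)
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
            else:
                new_centers[j] = X[int(np.argmax(mind2))]
        if np.allclose(new_centers, centers, rtol=0.0, atol=1e-14):
            centers = new_centers
            break
        centers = new_centers
    labels, mind2 = _nearest_center(X, centers)
    inertia = float(mind2.sum())
    dtrajs, off = [], 0
    for a in arrays:
        dtrajs.append(labels[off:off + a.shape[0]])
        off += a.shape[0]
    return MicrostateAssignment(dtrajs=dtrajs, centers=centers,
                                inertia=inertia, seed=seed)


def count_transitions(dtrajs, lag_frames: int) -> CountMatrix:
    """Sliding-window transition counts C_ij = #{t : s_t = i, s_{t+lag} = j}.

    Pairs never cross trajectory boundaries; in sliding mode the total count
    is sum_traj (len - lag) over trajectories longer than the lag.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    if isinstance(dtrajs, np.ndarray):
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    usable = [d for d in dtrajs if len(d) > lag_frames]
    if not usable:
        raise ValueError(f"all sequences are shorter than lag {lag_frames}")
    n = int(max(d.max() for d in usable)) + 1
    C = np.zeros((n, n), dtype=np.int64)
    for d in usable:
        np.add.at(C, (d[:-lag_frames], d[lag_frames:]), 1)
    return CountMatrix(counts=C, lag_frames=lag_frames, mode="sliding")


def largest_ergodic_set(C: CountMatrix | np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph.

    Edges are i -> j iff C_ij > 0. Ties between equally sized components go
    to the one with more total counts, then to the one containing the
    smallest state index.
    """
    counts = C.counts if isinstance(C, CountMatrix) else np.asarray(C)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    n_comp, labels = connected_components(counts > 0, directed=True,
                                          connection="strong")
    best = None
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        size = members.size
        mass = counts[np.ix_(members, members)].sum()
        key = (size, mass, -members.min())
        if best is None or key > best[0]:
            best = (key, members)
    return best[1]


def mle_reversible_tmatrix(C, tol: float = 1e-12, max_iter: int = 100_000,
                           lag_time: float = 1.0,
                           active_set=None) -> MarkovModel:
    """Reversible maximum-likelihood transition matrix from counts.

    Implements the self-consistent iteration on x_ij = pi_i T_ij:

        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j),

    with c_i the count row sums and x_i the x row sums, iterated until the
    log-likelihood change falls below ``tol``. The count matrix must be
    irreducible on its support (trim with :func:`largest_ergodic_set`
    first). For symmetric counts the iteration is immediately stationary
    and T equals the row-normalized counts.
    """
    counts = C.counts if isinstance(C, CountMatrix) else np.asarray(C)
    counts = counts.astype(float)
    n = counts.shape[0]
    if active_set is None:
        active_set = np.arange(n)
    if isinstance(C, CountMatrix) and lag_time == 1.0:
        lag_time = float(C.lag_frames)
    c_row = counts.sum(axis=1)
    if np.any(c_row == 0):
        raise ValueError("count matrix has empty rows; trim to the ergodic "
                         "set first")
    sym = counts + counts.T
    x = sym / sym.sum()
    support = sym > 0

    def loglik(x):
        xr = x.sum(axis=1)
        T = x / xr[:, None]
        m = (counts > 0) & (T > 0)
        return float((counts[m] * np.log(T[m])).sum())

    ll_old = loglik(x)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        xr = x.sum(axis=1)
        denom = c_row[:, None] / xr[:, None] + c_row[None, :] / xr[None, :]
        x_new = np.where(support, sym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        dx = np.max(np.abs(x_new - x))
        x = x_new
        ll = loglik(x)
        # the likelihood flattens quadratically near the optimum, so the
        # parameter update is tracked as well: both must fall below tol
        if abs(ll - ll_old) < tol and dx < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise MSMConvergenceError(
            f"reversible MLE did not converge in {max_iter} iterations; "
            f"last log-likelihood change {abs(ll - ll_old):.3e}"
        )
    # x is symmetric by construction, so with pi = row sums of x and
    # T = x / pi both detailed balance and stationarity hold identically
    # (pi T)_j = column sum = row sum = pi_j, up to rounding.
    x = 0.5 * (x + x.T)
    xr = x.sum(axis=1)
    T = x / xr[:, None]
    pi = xr / xr.sum()
    return MarkovModel(transition_matrix=T, stationary_distribution=pi,
                       lag_time=lag_time, active_set=np.asarray(active_set),
                       counts=counts,
                       metadata={"estimator": "reversible_mle",
                                 "n_iterations": n_iter})


def fit_msm(dtrajs, lag_frames: int, dt: float = 1.0, tol: float = 1e-12,
            max_iter: int = 100_000) -> MarkovModel:
    """Count, trim to the largest ergodic set, and fit the reversible MLE.

    Trimmed states are recorded in ``metadata["trimmed_states"]``, never
    dropped silently. ``dt`` converts frames to physical time.
    """
    C = count_transitions(dtrajs, lag_frames)
    active = largest_ergodic_set(C)
    trimmed = np.setdiff1d(np.arange(C.n_states), active)
    sub = C.counts[np.ix_(active, active)]
    model = mle_reversible_tmatrix(sub, tol=tol, max_iter=max_iter,
                                   lag_time=lag_frames * dt,
                                   active_set=active)
    model.metadata["trimmed_states"] = trimmed
    model.metadata["lag_frames"] = lag_frames
    return model


def implied_timescales(dtrajs, lags, n_timescales: int = 5,
                       dt: float = 1.0) -> pd.DataFrame:
    """Implied-timescale table t_i(tau) = -tau / ln lambda_{i+1}(T(tau)).

    One row per lag (physical time); eigenvalues <= 0 are reported as NaN
    (undefined). The standard check behind choosing the MSM lag: timescales
    should plateau once the lag resolves the slow processes.
    """
    rows = {}
    for lag in lags:
        model = fit_msm(dtrajs, int(lag), dt=dt)
        ts = model.timescales()[:n_timescales]
        ts = np.pad(ts, (0, max(0, n_timescales - len(ts))),
                    constant_values=np.nan)
        rows[lag * dt] = ts
    df = pd.DataFrame(rows).T
    df.index.name = "lag"
    df.columns = [f"t{i + 2}" for i in range(n_timescales)]
    return df


def mfpt(model: MarkovModel, source, target) -> float:
    """Mean first-passage time from ``source`` to ``target`` (physical time).

    Solves the absorbing linear system m = lag + T m on the complement of
    the target set and averages over the source states weighted by the
    stationary distribution restricted to the source. Source and target are
    model state indices (positions in the active set).
    """
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be nonempty")
    n = model.n_states
    if source.max() >= n or target.max() >= n:
        raise ValueError("state index outside the active set")
    if np.intersect1d(source, target).size == source.size:
        return 0.0
    if np.intersect1d(source, target).size:
        raise ValueError("source and target sets must be disjoint")
    keep = np.setdiff1d(np.arange(n), target)
    T = model.transition_matrix
    A = np.eye(keep.size) - T[np.ix_(keep, keep)]
    try:
        m = np.linalg.solve(A, np.full(keep.size, model.lag_time))
    except np.linalg.LinAlgError as err:
        raise ValueError("target is unreachable from the source "
                         "(singular system)") from err
    m_full = np.zeros(n)
    m_full[keep] = m
    pi = model.stationary_distribution[source]
    return float((pi / pi.sum()) @ m_full[source])


def sample_msm_trajectory(model: MarkovModel, n_steps: int, seed: int = 0,
                          frame_library: dict | None = None,
                          start: int | None = None):
    """Sample a representative trajectory from the fitted chain.

    Starts from a stationary draw (or ``start``) and samples ``n_steps``
    states; 25,000 steps at a 20 ns lag renders 500 us of representative
    dynamics. If ``frame_library`` maps states to frame identifiers, each
    visited state is rendered by a uniform draw from its library (raising
    if a visited state has none). Returns (states,) or (states, frames).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    T = model.transition_matrix
    cum = np.cumsum(T, axis=1)
    s = int(rng.choice(model.n_states, p=model.stationary_distribution)) \
        if start is None else int(start)
    states = np.empty(n_steps, dtype=np.int64)
    u = rng.random(n_steps)
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, model.n_states - 1)
        states[t] = s
    if frame_library is None:
        return states
    frames = []
    for s in states:
        lib = frame_library.get(int(s), [])
        if len(lib) == 0:
            raise ValueError(f"state {s} has an empty frame library")
        frames.append(lib[int(rng.integers(len(lib)))])
    return states, frames
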