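"""Time-lagged independent component analysis (tICA).

Finds the slowly decorrelating linear modes of high-dimensional feature
time series by solving the generalized symmetric eigenproblem

    C_tau v = lambda (C_0 + ridge I) v,

where C_0 is the instantaneous covariance and C_tau the symmetrized
time-lagged covariance at lag tau. The leading components (tICs) maximize
time-lagged autocorrelation and approximate the slowest kinetic
coordinates; for a channel trajectory featurized on cross-chain pore
distances the first tIC is the whole-molecule "up-down" coordinate, while
the same machinery on SF-only distances separates open from pinched filter
conformations.

The lagged covariance is symmetrized — (C_tau + C_tau^T)/2 — which forces a
real spectrum and matches the estimator generation of the original
analysis toolchain; a scale-free ridge guards against rank-deficient
feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .trajectory import FeatureTrajectory

__all__ = ["TICAModel", "estimate_covariances", "solve_tica", "project",
           "fit"]


@dataclass
class TICAModel:
    """Fitted tICA transform.

    ``components`` has one C0-orthonormal eigenvector per column, ordered by
    descending eigenvalue; ``eigenvalues`` are the lagged autocorrelations
    of the tICs; the implied timescale of tIC i is -lag / ln lambda_i.
    """

    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    lag: float
    ridge: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def timescales(self) -> np.ndarray:
        """-lag / ln(lambda); NaN where lambda <= 0 or >= 1."""
        lam = self.eigenvalues
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -self.lag / np.log(lam)
        t[(lam <= 0) | (lam >= 1)] = np.nan
        return t

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, c0=self.c0, ctau=self.ctau,
                 eigenvalues=self.eigenvalues, components=self.components,
                 lag=self.lag, ridge=self.ridge)

    @classmethod
    def load(cls, path) -> "TICAModel":
        with np.load(path) as f:
            return cls(mean=f["mean"], c0=f["c0"], ctau=f["ctau"],
                       eigenvalues=f["eigenvalues"],
                       components=f["components"],
                       lag=float(f["lag"]), ridge=float(f["ridge"]))


def _as_arrays(trajs):
    """(list of 2-D arrays, frame spacing)."""
    if isinstance(trajs, (FeatureTrajectory, np.ndarray)):
        trajs = [trajs]
    arrays, dt = [], None
    for t in trajs:
        if isinstance(t, FeatureTrajectory):
            arrays.append(t.data)
            if dt is not None and t.dt != dt:
                raise ValueError("trajectories have inconsistent frame spacing")
            dt = t.dt
        else:
            arrays.append(np.atleast_2d(np.asarray(t, dtype=float)))
    return arrays, (1.0 if dt is None else dt)


def estimate_covariances(trajs, lag: float):
    """Pooled mean-free covariance estimators at a given lag time.

    ``lag`` is in the trajectories' time unit and must be a nonnegative
    multiple of the frame spacing (plain arrays are treated as dt = 1).
    Frame pairs (t, t + lag) never straddle trajectory boundaries, and
    pooling across trajectories weights each by its pair count. Returns
    (mean, C0, Ctau_sym) with C0 the symmetric average of the head and tail
    covariances (guaranteeing PSD) and Ctau symmetrized.
    """
    arrays, dt = _as_arrays(trajs)
    lag_frames = lag / dt
    if abs(lag_frames - round(lag_frames)) > 1e-9 or lag_frames < 0:
        raise ValueError(
            f"lag {lag} is not a nonnegative multiple of frame spacing {dt}"
        )
    lf = int(round(lag_frames))
    usable = [a for a in arrays if a.shape[0] > lf]
    if not usable:
        raise ValueError(f"all trajectories are shorter than the lag "
                         f"({lf} frames)")
    d = usable[0].shape[1]
    n_pairs = 0
    s_head = np.zeros(d)
    s_tail = np.zeros(d)
    for a in usable:
        head, tail = (a, a) if lf == 0 else (a[:-lf], a[lf:])
        n_pairs += head.shape[0]
        s_head += head.sum(axis=0)
        s_tail += tail.sum(axis=0)
    mean = (s_head + s_tail) / (2.0 * n_pairs)
    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    for a in usable:
        head, tail = (a, a) if lf == 0 else (a[:-lf], a[lf:])
        h = head - mean
        t = tail - mean
        c0 += h.T @ h + t.T @ t
        ctau += h.T @ t
    c0 /= 2.0 * n_pairs
    c0 = 0.5 * (c0 + c0.T)
    if lf == 0:  # C_tau coincides with C_0 identically at lag 0
        return mean, c0, c0.copy()
    ctau /= n_pairs
    ctau = 0.5 * (ctau + ctau.T)
    return mean, c0, ctau


def solve_tica(c0, ctau, n_components: int, ridge: float | None = None,
               lag: float = 1.0, mean=None) -> TICAModel:
    """Solve the generalized eigenproblem and keep the top components.

    ``ridge`` defaults to 1e-10 * trace(C0) / dim, a scale-free guard
    against rank deficiency; if C0 + ridge I is still not positive
    definite the error advises a larger ridge. The sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    c0 = np.asarray(c0, dtype=float)
    ctau = np.asarray(ctau, dtype=float)
    if c0.shape != ctau.shape or c0.shape[0] != c0.shape[1]:
        raise ValueError("C0 and Ctau must be square matrices of equal size")
    d = c0.shape[0]
    if ridge is None:
        ridge = 1e-10 * np.trace(c0) / d
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    reg = c0 + ridge * np.eye(d)
    try:
        scipy.linalg.cholesky(reg)
    except scipy.linalg.LinAlgError as err:
        raise ValueError(
            "C0 + ridge*I is not positive definite; increase the ridge"
        ) from err
    w, v = scipy.linalg.eigh(ctau, reg)
    order = np.argsort(w)[::-1][:n_components]
    w, v = w[order], v[:, order]
    for j in range(v.shape[1]):
        k = int(np.argmax(np.abs(v[:, j])))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    return TICAModel(mean=np.zeros(d) if mean is None else np.asarray(mean),
                     c0=c0, ctau=ctau, eigenvalues=w, components=v,
                     lag=lag, ridge=float(ridge),
                     metadata={"estimator": "symmetrized"})


def project(trajs, model: TICAModel):
    """Project trajectories onto the tICs: (x - mean) @ components.

    Returns a list of (n_frames, n_components) arrays (or a single array if
    a single trajectory was passed).
    """
    single = isinstance(trajs, (FeatureTrajectory, np.ndarray))
    arrays, _ = _as_arrays(trajs)
    out = []
    for a in arrays:
        if a.shape[1] != model.mean.shape[0]:
            raise ValueError(
                f"feature dimension {a.shape[1]} does not match model "
                f"dimension {model.mean.shape[0]}"
            )
        out.append((a - model.mean) @ model.components)
    return out[0] if single else out


def fit(trajs, lag: float, n_components: int = 3,
        ridge: float | None = None) -> TICAModel:
    """Convenience: estimate covariances and solve in one call."""
    mean, c0, ctau = estimate_covariances(trajs, lag)
    return solve_tica(c0, ctau, n_components, ridge=ridge, lag=lag, mean=mean)
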