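"""Umbrella-sampling reweighting with WHAM and barrier analysis.

Reconstructs a 1-D potential of mean force F(z) along the ion-transition
coordinate dz from harmonically biased windows, by self-consistent solution
of the WHAM equations

    P(z) ∝  sum_i n_i(z) / sum_i N_i exp[(f_i - U_i(z)) / kT],
    f_i  = -kT ln sum_z P(z) exp(-U_i(z) / kT),

where n_i(z) are window histograms, N_i retained sample counts and
U_i(z) = k_i/2 (z - z_i)^2 the bias potentials. Energies are kcal/mol,
lengths nm. The converged profile is F(z) = -kT ln P(z), anchored so its
minimum over covered bins is zero; bins no window visited stay NaN rather
than being interpolated.

Convergence diagnostics follow common umbrella-sampling practice: adjacent
window-histogram overlap coefficients, replicate spread over independently
seeded profiles, and drift checks on monitored series (reaction coordinate
or protein RMSD) to catch bias-induced artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "KT_300K",
    "UmbrellaWindow",
    "PMFProfile",
    "BarrierReport",
    "WHAMConvergenceError",
    "wham_solve",
    "barrier_heights",
    "histogram_overlap",
    "pmf_error_bars",
    "drift_check",
]

#: k_B * 300 K in kcal/mol.
KT_300K = 0.0019872041 * 300.0


class WHAMConvergenceError(RuntimeError):
    pass


@dataclass
class UmbrellaWindow:
    """One harmonic umbrella window along the reaction coordinate.

    ``samples`` are reaction-coordinate values (nm); the first ``n_equil``
    of them are treated as equilibration and discarded from analysis
    (mirroring the 1-ns-of-6-ns discard convention: by default callers pass
    ``n_equil = len(samples) // 6``).
    """

    center: float
    k_spring: float  # kcal mol^-1 nm^-2
    samples: np.ndarray
    n_equil: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k_spring < 0:
            raise ValueError("spring constant must be >= 0")
        if not 0 <= self.n_equil < len(self.samples):
            raise ValueError(
                "equilibration discard must leave at least one sample"
            )

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.n_equil:]

    def bias(self, z) -> np.ndarray:
        """Bias energy U_i(z) in kcal/mol."""
        return 0.5 * self.k_spring * (np.asarray(z, dtype=float) - self.center) ** 2

    # two-column text (time index, coordinate) with a metadata sidecar — the
    # dialect used by common umbrella tooling
    def to_text(self, path, sidecar=None) -> None:
        t = np.arange(len(self.samples))
        np.savetxt(path, np.column_stack([t, self.samples]),
                   header="time rc_nm")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                fh.write(f"center_nm\t{self.center}\n"
                         f"k_spring_kcal_per_mol_nm2\t{self.k_spring}\n"
                         f"n_equil\t{self.n_equil}\n")


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate on a uniform grid."""

    z: np.ndarray               # bin centers, nm
    free_energy: np.ndarray     # kcal/mol, min over defined bins = 0
    window_free_energies: np.ndarray
    kT: float
    n_iterations: int
    converged: bool
    counts: np.ndarray = None   # pooled histogram counts per bin
    diagnostics: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "F": self.free_energy,
                             "n": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class BarrierReport:
    """Forward/reverse barrier heights extracted from a PMF."""

    forward: float
    reverse: float
    well1_z: float
    well2_z: float
    ts_z: float
    per_replicate: pd.DataFrame | None = None
    forward_sd: float | None = None
    reverse_sd: float | None = None


def _histograms(windows, edges):
    return np.stack([np.histogram(w.retained, bins=edges)[0]
                     for w in windows])


def _connected(hist) -> bool:
    """True iff the window set is linked through shared occupied bins."""
    n_win = hist.shape[0]
    adj = (hist > 0) @ (hist > 0).T  # windows sharing >= 1 occupied bin
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n_win


def wham_solve(windows, kT: float = KT_300K,
               grid: tuple[float, float, int] = None,
               tol: float = 1e-8, max_iter: int = 500_000) -> PMFProfile:
    """Self-consistent WHAM solution over a fixed uniform grid.

    ``grid`` is (zmin, zmax, n_bins); when omitted it spans the pooled
    samples with a 25 % margin, and the bin width is half the narrowest
    window's thermal width sqrt(kT/k) — fine enough that the bias factor is
    resolved, coarse enough that overlap-region bins keep usable counts.
    Iteration stops when the largest
    change in any window free energy f_i is below ``tol`` (kcal/mol).
    Windows whose histograms do not overlap anywhere cannot be placed on a
    common scale; the profile is then returned with ``converged=False`` and
    a diagnostic instead of a silently wrong answer.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("at least one umbrella window is required")
    pooled = np.concatenate([w.retained for w in windows])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("non-finite reaction-coordinate samples")
    if grid is None:
        lo, hi = pooled.min(), pooled.max()
        pad = 0.25 * (hi - lo + 1e-12)
        ks = [w.k_spring for w in windows if w.k_spring > 0]
        if ks:
            width = 0.5 * np.sqrt(kT / max(ks))
            n_auto = int(np.clip(round((hi - lo + 2 * pad) / width), 50, 400))
        else:
            n_auto = 200
        grid = (lo - pad, hi + pad, n_auto)
    zmin, zmax, n_bins = grid
    if pooled.min() < zmin or pooled.max() > zmax:
        raise ValueError("grid does not cover all samples")
    edges = np.linspace(zmin, zmax, n_bins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])

    hist = _histograms(windows, edges)          # (n_win, n_bins)
    n_z = hist.sum(axis=0).astype(float)
    big_n = hist.sum(axis=1).astype(float)      # retained samples per window
    bias = np.stack([w.bias(z) for w in windows]) / kT  # (n_win, n_bins)

    if not _connected(hist):
        f = np.zeros(len(windows))
        prof = _profile_from_f(z, n_z, big_n, bias, f, kT, windows, 0, False)
        prof.diagnostics["error"] = (
            "window histograms do not overlap; windows cannot be combined"
        )
        return prof

    occupied = n_z > 0
    log_nz = np.full(n_bins, -np.inf)
    log_nz[occupied] = np.log(n_z[occupied])
    log_big_n = np.log(big_n)

    def sweep(f):
        """One self-consistent update f -> G(f); also returns log P(z)."""
        log_denom = logsumexp(log_big_n[:, None] + f[:, None] - bias, axis=0)
        log_p = log_nz - log_denom
        log_p -= logsumexp(log_p[occupied])
        f_new = -logsumexp(log_p[None, occupied] - bias[:, occupied], axis=1)
        return f_new - f_new[0], log_p

    # plain iteration converges linearly and slowly when adjacent windows
    # barely overlap; Aitken (Steffensen) extrapolation over sweep pairs
    # accelerates it without changing the fixed point or the stopping rule
    f = np.zeros(len(windows))  # window free energies, units of kT
    n_iter = 0
    delta = np.inf
    while n_iter < max_iter:
        f1, _ = sweep(f)
        f2, log_p = sweep(f1)
        n_iter += 2
        delta = np.max(np.abs(f2 - f1)) * kT
        if delta < tol:
            f = f2
            break
        d1, d2 = f1 - f, f2 - f1
        denom = d2 - d1
        safe = np.abs(denom) > 1e-300
        f_acc = np.where(safe, f2 - d2 ** 2 / np.where(safe, denom, 1.0), f2)
        # accept the extrapolation only if it reduces the sweep residual
        f3, _ = sweep(f_acc)
        n_iter += 1
        if np.max(np.abs(f3 - f_acc)) < np.max(np.abs(f2 - f1)):
            f = f_acc
        else:
            f = f2
    else:
        raise WHAMConvergenceError(
            f"WHAM did not converge in {max_iter} iterations; "
            f"final max |df_i| = {delta:.3e} kcal/mol"
        )
    return _profile_from_f(z, n_z, big_n, bias, f, kT, windows, n_iter, True,
                           log_p=log_p)


def _profile_from_f(z, n_z, big_n, bias, f, kT, windows, n_iter, converged,
                    log_p=None):
    occupied = n_z > 0
    if log_p is None:
        log_nz = np.where(occupied, np.log(np.where(occupied, n_z, 1.0)),
                          -np.inf)
        log_denom = logsumexp(np.log(big_n)[:, None] + f[:, None] - bias,
                              axis=0)
        log_p = log_nz - log_denom
    free = np.full_like(z, np.nan)
    free[occupied] = -kT * log_p[occupied]
    free -= np.nanmin(free)
    return PMFProfile(z=z, free_energy=free,
                      window_free_energies=f * kT, kT=kT,
                      n_iterations=n_iter, converged=converged,
                      counts=n_z)


def barrier_heights(profile: PMFProfile, well_windows) -> BarrierReport:
    """Forward/reverse barriers between two wells of a PMF.

    ``well_windows`` is a pair of z-intervals; each well is the minimum of
    F over the defined bins of its interval, the transition state the
    maximum of F strictly between the two well locations. Forward barrier
    is F(ts) - F(well1), reverse F(ts) - F(well2).
    """
    (a_lo, a_hi), (b_lo, b_hi) = well_windows
    z, F = profile.z, profile.free_energy

    def well(lo, hi):
        m = (z >= lo) & (z <= hi) & np.isfinite(F)
        if not m.any():
            raise ValueError(f"no defined PMF bins in well window [{lo}, {hi}]")
        idx = np.nonzero(m)[0]
        return idx[np.argmin(F[m])]

    i1, i2 = well(a_lo, a_hi), well(b_lo, b_hi)
    if i1 > i2:
        i1, i2 = i2, i1
    interior = np.arange(i1 + 1, i2)
    interior = interior[np.isfinite(F[interior])]
    if interior.size == 0:
        raise ValueError("no defined PMF bins between the two wells")
    its = interior[np.argmax(F[interior])]
    fwd = float(F[its] - F[well(a_lo, a_hi)])
    rev = float(F[its] - F[well(b_lo, b_hi)])
    return BarrierReport(forward=max(fwd, 0.0), reverse=max(rev, 0.0),
                         well1_z=float(z[well(a_lo, a_hi)]),
                         well2_z=float(z[well(b_lo, b_hi)]),
                         ts_z=float(z[its]))


def histogram_overlap(windows, grid, threshold: float = 0.05):
    """Adjacent-window overlap coefficients sum_z min(p_i, p_{i+1}).

    Windows are ordered by center. Returns (coefficients, flag); the flag is
    True iff every adjacent pair overlaps by at least ``threshold`` — the
    convergence criterion of monitoring histogram overlap.
    """
    windows = sorted(windows, key=lambda w: w.center)
    zmin, zmax, n_bins = grid
    edges = np.linspace(zmin, zmax, n_bins + 1)
    hist = _histograms(windows, edges).astype(float)
    p = hist / hist.sum(axis=1, keepdims=True)
    coeffs = np.array([np.minimum(p[i], p[i + 1]).sum()
                       for i in range(len(windows) - 1)])
    return coeffs, bool(np.all(coeffs >= threshold))


def pmf_error_bars(replicate_profiles, well_windows=None):
    """Aggregate replicate PMFs: per-bin mean/sd and barrier mean +/- sd.

    Replicates (independently chosen starting conformations in the original
    protocol; independently seeded windows here) must share a grid. Each
    profile is re-anchored to min 0 before aggregation, so constant offsets
    between replicates do not inflate the spread.
    """
    profiles = list(replicate_profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z0.shape or not np.allclose(p.z, z0):
            raise ValueError("replicate profiles are on mismatched grids")
    F = np.stack([p.free_energy - np.nanmin(p.free_energy) for p in profiles])
    n_def = np.isfinite(F).sum(axis=0)
    mean = np.full(z0.shape, np.nan)
    sd = np.full(z0.shape, np.nan)
    mean[n_def > 0] = np.nanmean(F[:, n_def > 0], axis=0)
    sd[n_def > 1] = np.nanstd(F[:, n_def > 1], axis=0, ddof=1)
    out = {
        "z": z0,
        "mean": mean,
        "sd": sd,
        "n_replicates": len(profiles),
    }
    if well_windows is not None:
        reports = [barrier_heights(p, well_windows) for p in profiles]
        tab = pd.DataFrame({
            "forward": [r.forward for r in reports],
            "reverse": [r.reverse for r in reports],
        })
        out["barriers"] = BarrierReport(
            forward=float(tab["forward"].mean()),
            reverse=float(tab["reverse"].mean()),
            well1_z=float(np.mean([r.well1_z for r in reports])),
            well2_z=float(np.mean([r.well2_z for r in reports])),
            ts_z=float(np.mean([r.ts_z for r in reports])),
            per_replicate=tab,
            forward_sd=float(tab["forward"].std(ddof=1)),
            reverse_sd=float(tab["reverse"].std(ddof=1)),
        )
    return out


def drift_check(series, threshold: float, n_equil: int = 0):
    """Flag monitored series that cross ``threshold`` after equilibration.

    Returns (passed, first_crossing_index) with the index referring to the
    full series. Used on the reaction coordinate or protein RMSD to detect
    umbrella-potential artifacts.
    """
    series = np.asarray(series, dtype=float).ravel()
    post = series[n_equil:]
    above = np.nonzero(post > threshold)[0]
    if above.size == 0:
        return True, None
    return False, int(above[0] + n_equil)
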