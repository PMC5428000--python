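"""Synthetic data with known ground truth for the full analysis pipeline.

Real K2P-channel MD datasets of the scale the analysis was designed for
(hundreds of microseconds) are not redistributable, so every stage of the
pipeline is exercised on generated inputs whose answers are known
analytically or by construction:

* :func:`gen_langevin_features` — overdamped Langevin (Euler–Maruyama)
  trajectories on multi-well potentials built as -kT log of a Gaussian
  mixture, so stationary well weights are exact mixture weights;
* :func:`gen_coupled_chain` — a three-layer discrete chain over
  (conformational macrostate, SF open/pinched state, 16-state ion occupancy)
  with macrostate-dependent rates, emulating the coupled
  conformation/filter/ion process;
* :func:`gen_umbrella_samples` — i.i.d. (or Metropolis) samples from
  harmonically biased analytic 1-D free-energy curves, the input to WHAM;
* :func:`gen_toy_channel_frames` — minimal coordinate frames (carbonyl
  layers, ions, waters, pore-diameter markers) that round-trip through the
  geometric featurizers.

All generators take an integer seed and are bit-reproducible for identical
(spec, seed); seeds are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve
from scipy.special import logsumexp

from .featurize import ALL_OCCUPANCY_STATES, OccupancyState
from .trajectory import FeatureTrajectory
from .wham import KT_300K, UmbrellaWindow

__all__ = [
    "Well",
    "PotentialSpec",
    "TiltedDoubleWell",
    "LangevinDivergenceError",
    "gen_langevin_features",
    "CoupledChainSpec",
    "CoupledChainTrajectory",
    "gen_coupled_chain",
    "default_coupled_chain_spec",
    "ion_hop_matrix",
    "ion_move_neighbors",
    "ToyChannelFrame",
    "gen_toy_channel_frames",
    "DEFAULT_LAYER_Z",
]


# ---------------------------------------------------------------------------
# Continuous potentials and Langevin sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Well:
    """One Gaussian basin: center (vector), depth (kcal/mol), width (nm)."""

    center: tuple
    depth: float
    width: float


@dataclass
class PotentialSpec:
    """Multi-well potential U(x) = -kT log sum_i a_i N(x; c_i, w_i^2 I).

    Because the Boltzmann density at temperature ``kT`` is then exactly the
    Gaussian mixture, the stationary weight of well i is the (normalized)
    mixture weight a_i = exp(depth_i / kT) — known analytically, which is
    what makes these potentials useful as ground truth. ``kT`` doubles as
    the sampling temperature for :func:`gen_langevin_features`; the
    zero-noise limit ``kT = 0`` is allowed (pure gradient descent), in which
    case the landscape is shaped with a reference kT of ``KT_300K``.
    """

    wells: list[Well]
    kT: float = KT_300K

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("at least one well is required")
        if any(w.width <= 0 for w in self.wells):
            raise ValueError("well widths must be positive")
        if self.kT < 0:
            raise ValueError("kT must be nonnegative")
        self._centers = np.atleast_2d(
            np.asarray([w.center for w in self.wells], dtype=float))
        self._widths = np.asarray([w.width for w in self.wells], dtype=float)
        self._depths = np.asarray([w.depth for w in self.wells], dtype=float)

    @property
    def dimensionality(self) -> int:
        return self._centers.shape[1]

    @property
    def _shape_kT(self) -> float:
        return self.kT if self.kT > 0 else KT_300K

    def well_weights(self) -> np.ndarray:
        """Exact stationary weight of each well at temperature kT."""
        a = self._depths / self._shape_kT
        return np.exp(a - logsumexp(a))

    def _log_mixture(self, x: np.ndarray):
        # log sum_i a_i N_i(x) and the responsibilities r_i(x)
        d = self.dimensionality
        diff = x[None, :] - self._centers            # (k, d)
        sq = (diff ** 2).sum(axis=1)
        log_comp = (self._depths / self._shape_kT
                    - 0.5 * sq / self._widths ** 2
                    - d * np.log(self._widths))
        lse = logsumexp(log_comp)
        return lse, np.exp(log_comp - lse), diff

    def potential(self, x) -> float:
        """U(x) in kcal/mol."""
        lse, _, _ = self._log_mixture(np.asarray(x, dtype=float).ravel())
        return -self._shape_kT * lse

    def gradient(self, x) -> np.ndarray:
        lse, resp, diff = self._log_mixture(np.asarray(x, dtype=float).ravel())
        return self._shape_kT * (resp[:, None] * diff
                                 / self._widths[:, None] ** 2).sum(axis=0)

    def assign_well(self, x) -> np.ndarray:
        """Nearest-center basin label for frames x (n, d) — ground truth."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d2 = ((x[:, None, :] - self._centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


class LangevinDivergenceError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(
            f"Langevin integration diverged at step {step}; "
            f"reduce the time step dt"
        )
        self.step = step


def gen_langevin_features(spec: PotentialSpec, n_steps: int, dt: float,
                          seed: int, friction: float = 1.0,
                          x0=None) -> FeatureTrajectory:
    """Overdamped Langevin trajectory on ``spec`` via Euler–Maruyama.

    x_{t+1} = x_t - (dt/friction) grad U(x_t) + sqrt(2 kT dt / friction) xi_t

    with standard-normal xi. Starts at the deepest well center unless ``x0``
    is given. Divergent coordinates (non-finite, or escaping far beyond the
    well region) raise :class:`LangevinDivergenceError` naming the step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    d = spec.dimensionality
    if x0 is None:
        x = spec._centers[int(np.argmax(spec._depths))].copy()
    else:
        x = np.asarray(x0, dtype=float).ravel().copy()
    scale = (np.abs(spec._centers).max() + spec._widths.max())
    bound = 50.0 * max(scale, 1.0)
    sigma = np.sqrt(2.0 * spec.kT * dt / friction)
    noise = rng.standard_normal((n_steps, d)) * sigma
    out = np.empty((n_steps, d))
    # gradient of the mixture potential, inlined for the hot loop
    centers = spec._centers
    inv_w2 = 1.0 / spec._widths ** 2
    log_a = spec._depths / spec._shape_kT - d * np.log(spec._widths)
    kT_shape = spec._shape_kT
    step = dt / friction
    for t in range(n_steps):
        diff = x[None, :] - centers
        logc = log_a - 0.5 * (diff * diff).sum(axis=1) * inv_w2
        r = np.exp(logc - logc.max())
        r /= r.sum()
        grad = kT_shape * ((r * inv_w2)[:, None] * diff).sum(axis=0)
        x = x - step * grad + noise[t]
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > bound):
            raise LangevinDivergenceError(t)
        out[t] = x
    labels = [f"x{i}" for i in range(d)]
    return FeatureTrajectory(out, dt=dt, labels=labels,
                             metadata={"generator": "langevin_overdamped",
                                       "seed": seed, "dt": dt,
                                       "friction": friction,
                                       "kT": spec.kT})


@dataclass
class TiltedDoubleWell:
    """Analytic 1-D free-energy curve U(z) = a((z/w)^2 - 1)^2 + b z/w.

    ``from_barriers`` solves (a, b) so that the forward barrier (left well
    to transition state) and reverse barrier (right well to transition
    state) take prescribed values in kcal/mol — the ground truth for the
    umbrella-sampling + WHAM pipeline. ``half_width`` w sets the well
    separation in nm: wells sit near z = -w and +w with the transition
    state near 0, so w = 0.1 nm reproduces the five-window layout with
    ~0.05 nm spacing (well, midpoint, transition state, midpoint, well).
    """

    a: float
    b: float
    half_width: float = 0.1

    def __call__(self, z):
        s = np.asarray(z, dtype=float) / self.half_width
        return self.a * (s ** 2 - 1.0) ** 2 + self.b * s

    def stationary_points(self) -> np.ndarray:
        """z of (left well, transition state, right well)."""
        roots = np.roots([4.0 * self.a, 0.0, -4.0 * self.a, self.b])
        real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
        if real.size != 3:
            raise ValueError("potential is not a double well for these a, b")
        return real * self.half_width

    def barriers(self) -> tuple[float, float]:
        zl, zt, zr = self.stationary_points()
        return (float(self(zt) - self(zl)), float(self(zt) - self(zr)))

    @classmethod
    def from_barriers(cls, forward: float, reverse: float,
                      half_width: float = 0.1) -> "TiltedDoubleWell":
        if forward <= 0 or reverse <= 0:
            raise ValueError("barriers must be positive")

        def residual(p):
            try:
                f, r = cls(p[0], p[1], half_width).barriers()
            except ValueError:
                return [1e3, 1e3]
            return [f - forward, r - reverse]

        a0 = 0.5 * (forward + reverse)
        b0 = 0.25 * (forward - reverse)
        sol = fsolve(residual, [a0, b0], full_output=False)
        well = cls(float(sol[0]), float(sol[1]), half_width)
        f, r = well.barriers()
        if abs(f - forward) > 1e-8 or abs(r - reverse) > 1e-8:
            raise ValueError("could not match the requested barriers")
        return well

    def default_window_centers(self) -> np.ndarray:
        """Five umbrella centers: wells, transition state, and midpoints."""
        zl, zt, zr = self.stationary_points()
        return np.array([zl, 0.5 * (zl + zt), zt, 0.5 * (zt + zr), zr])


# ---------------------------------------------------------------------------
# Coupled (macrostate, SF, ion) discrete chain
# ---------------------------------------------------------------------------


def _check_stochastic(mat, name):
    mat = np.asarray(mat, dtype=float)
    bad = []
    for i, row in enumerate(np.atleast_2d(mat.reshape(-1, mat.shape[-1]))):
        if np.any(row < 0) or np.any(row > 1) or abs(row.sum() - 1.0) > 1e-12:
            bad.append(i)
    if bad:
        raise ValueError(f"{name}: rows {bad} are not stochastic "
                         f"(entries in [0,1], sum 1 within 1e-12)")
    return mat


def ion_move_neighbors(code: int) -> list[int]:
    """Occupancy states reachable by one elementary ion move.

    Moves: entry at S1 or S4 into a vacant end site, exit from an occupied
    end site, and a hop between adjacent sites (occupied -> vacant). The
    neighbor relation is symmetric, so a constant proposal probability per
    candidate move gives a symmetric proposal kernel.
    """
    bits = [(code >> (3 - i)) & 1 for i in range(4)]  # S1..S4
    out = []
    for end in (0, 3):  # entry/exit at S1 and S4
        out.append(code ^ (1 << (3 - end)))
    for i in range(3):  # hops between adjacent sites
        if bits[i] != bits[i + 1]:
            out.append(code ^ (1 << (3 - i)) ^ (1 << (3 - (i + 1))))
    return sorted(set(out))


def ion_hop_matrix(energies: dict[int, float],
                   move_prob: float = 0.4) -> np.ndarray:
    """Reversible 16-state occupancy chain from per-state energies (kT).

    Metropolis dynamics over single-ion moves with a symmetric proposal
    (probability ``move_prob / 8`` per candidate move, 8 being the maximum
    move count), so the stationary distribution on the reachable set is
    Gibbs: pi(s) ∝ exp(-E_s). States absent from ``energies`` are
    unreachable (never proposed into, never left from).
    """
    if not 0 < move_prob <= 1:
        raise ValueError("move_prob must be in (0, 1]")
    q = move_prob / 8.0
    T = np.eye(16)
    for s in range(16):
        if s not in energies:
            continue
        for n in ion_move_neighbors(s):
            if n not in energies:
                continue
            p = q * min(1.0, np.exp(-(energies[n] - energies[s])))
            T[s, n] = p
        T[s, s] = 1.0 - (T[s].sum() - T[s, s])
    return T


@dataclass
class CoupledChainSpec:
    """Three-layer discrete chain: macrostate -> SF state -> ion occupancy.

    ``macro_T`` is the macrostate transition matrix (row-stochastic over
    ``macro_labels``); ``sf_flip[m] = (a, b)`` gives the per-step
    open->pinched (a) and pinched->open (b) probabilities inside macrostate
    m, so the within-macrostate stationary pinched:open odds are a/b;
    ``ion_T[m, s]`` is the 16x16 occupancy transition matrix conditioned on
    (macrostate m, SF state s). SF state 0 is open, 1 pinched.
    """

    macro_labels: tuple
    macro_T: np.ndarray
    sf_flip: np.ndarray          # (M, 2)
    ion_T: np.ndarray            # (M, 2, 16, 16)
    sf_labels: tuple = ("open", "pinched")

    def __post_init__(self) -> None:
        self.macro_T = _check_stochastic(self.macro_T, "macro_T")
        self.sf_flip = np.asarray(self.sf_flip, dtype=float)
        m = len(self.macro_labels)
        if self.macro_T.shape != (m, m):
            raise ValueError("macro_T shape must match macro_labels")
        if self.sf_flip.shape != (m, 2):
            raise ValueError("sf_flip must be (n_macro, 2)")
        if np.any(self.sf_flip < 0) or np.any(self.sf_flip > 1):
            raise ValueError("flip probabilities must be in [0, 1]")
        self.ion_T = np.asarray(self.ion_T, dtype=float)
        if self.ion_T.shape != (m, 2, 16, 16):
            raise ValueError("ion_T must be (n_macro, 2, 16, 16)")
        for i in range(m):
            for s in range(2):
                _check_stochastic(self.ion_T[i, s], f"ion_T[{i},{s}]")

    @property
    def n_macro(self) -> int:
        return len(self.macro_labels)

    def sf_T(self, macro: int) -> np.ndarray:
        a, b = self.sf_flip[macro]
        return np.array([[1 - a, a], [b, 1 - b]])

    # -- exact stationary quantities (oracles for estimator tests) ---------

    def joint_transition_matrix(self) -> np.ndarray:
        """Dense transition matrix of the (macro, sf, ion) product chain.

        Per-step sampling order is macro, then SF given the *new*
        macrostate, then ion given the new (macro, SF); the joint kernel is
        the corresponding product.
        """
        m = self.n_macro
        n = m * 2 * 16
        T = np.zeros((n, n))
        for ma in range(m):
            for sf in range(2):
                for ion in range(16):
                    i = (ma * 2 + sf) * 16 + ion
                    for ma2 in range(m):
                        p_m = self.macro_T[ma, ma2]
                        if p_m == 0:
                            continue
                        sfT = self.sf_T(ma2)
                        for sf2 in range(2):
                            p_s = sfT[sf, sf2]
                            if p_s == 0:
                                continue
                            row = self.ion_T[ma2, sf2, ion]
                            j0 = (ma2 * 2 + sf2) * 16
                            T[i, j0:j0 + 16] += p_m * p_s * row
        return T

    def joint_stationary(self) -> np.ndarray:
        T = self.joint_transition_matrix()
        w, v = np.linalg.eig(T.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def conditional_sf_odds(self, macro: int) -> float:
        """Exact stationary pinched:open odds conditioned on a macrostate."""
        pi = self.joint_stationary().reshape(self.n_macro, 2, 16)
        p = pi[macro].sum(axis=1)
        return float(p[1] / p[0])


@dataclass
class CoupledChainTrajectory:
    macro: np.ndarray
    sf: np.ndarray
    ion: np.ndarray
    macro_labels: tuple
    sf_labels: tuple
    seed: int

    def __len__(self) -> int:
        return len(self.macro)

    def ion_strings(self) -> list[str]:
        return [ALL_OCCUPANCY_STATES[c].string for c in self.ion]


def gen_coupled_chain(spec: CoupledChainSpec, n_steps: int,
                      seed: int, start=None) -> CoupledChainTrajectory:
    """Sample the coupled (macro, SF, ion) chain for ``n_steps`` steps.

    Each step draws the new macrostate, then the SF state conditioned on
    the new macrostate, then the ion state conditioned on the new
    (macrostate, SF). The start state defaults to a draw from the exact
    joint stationary distribution, so conditional statistics are unbiased
    from the first frame.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    m = spec.n_macro
    if start is None:
        pi = spec.joint_stationary()
        j = int(rng.choice(len(pi), p=pi))
        macro0, rest = divmod(j, 32)
        sf0, ion0 = divmod(rest, 16)
    else:
        macro0, sf0, ion0 = start

    macro_cum = np.cumsum(spec.macro_T, axis=1)
    sf_cum = np.stack([np.cumsum(spec.sf_T(i), axis=1) for i in range(m)])
    ion_cum = np.cumsum(spec.ion_T, axis=3)
    u = rng.random((n_steps, 3))

    macro = np.empty(n_steps, dtype=np.int64)
    sf = np.empty(n_steps, dtype=np.int64)
    ion = np.empty(n_steps, dtype=np.int64)
    ma, s, io = macro0, sf0, ion0
    for t in range(n_steps):
        ma = int(np.searchsorted(macro_cum[ma], u[t, 0], side="right"))
        s = int(np.searchsorted(sf_cum[ma, s], u[t, 1], side="right"))
        io = int(np.searchsorted(ion_cum[ma, s, io], u[t, 2], side="right"))
        macro[t], sf[t], ion[t] = ma, s, io
    return CoupledChainTrajectory(macro, sf, ion, spec.macro_labels,
                                  spec.sf_labels, seed)


# Study-condition defaults. Energies are in kT units; OXXO (code 6) is the
# resting minimum everywhere, mirroring its role as the dominant state. The
# compressed-conformation table allows all 16 occupancy codes (diffuse ion
# dynamics); the stretched conformation is restricted to the 7-state
# conduction-cycle neighborhood of OXXO.
_UP_ION_ENERGIES = {6: 0.0, 14: 1.2, 7: 1.2, 13: 2.2, 11: 2.2,
                    12: 2.8, 3: 2.8}
_DOWN_ION_ENERGIES = {6: 0.0, 14: 0.9, 7: 0.9, 13: 1.6, 11: 1.6,
                      12: 2.0, 3: 2.0, 2: 2.3, 4: 2.3, 1: 2.8, 8: 2.8,
                      15: 2.6, 10: 3.0, 5: 3.0, 9: 3.3, 0: 3.5}
_INTERMEDIATE_ION_ENERGIES = {**_UP_ION_ENERGIES, 2: 2.6, 4: 2.6}


def _pinched(energies: dict[int, float]) -> dict[int, float]:
    # pinched filter destabilizes everything but the resting state
    return {s: (e if s == 6 else e + 1.2) for s, e in energies.items()}


def default_coupled_chain_spec(down_odds: float = 75.0,
                               sf_rate: float = 0.6,
                               macro_stay: float = 0.99997,
                               move_prob: float = 0.4) -> CoupledChainSpec:
    """Coupled-chain study conditions.

    Macrostates (Up, Down, I1, I2) are slow (mean dwell ~1/(1 - macro_stay)
    steps) while SF flips relax within a few steps, giving the timescale
    separation under which the conditional pinched:open odds inside the Down
    macrostate equal the flip-probability ratio a/b = ``down_odds`` (75:1 by
    default). Up and I2 favor the open filter by the mirrored ratio, and I1
    never pinches. Ion tables are Metropolis chains over single-ion moves
    with OXXO the global minimum; the Down tables span all 16 codes while
    Up/I1/I2 are confined to the conduction-cycle states.
    """
    labels = ("Up", "Down", "I1", "I2")
    r = 1.0 - macro_stay
    macro_T = np.array([
        # Up       Down      I1        I2
        [0.0, 1 / 6, 1 / 3, 1 / 2],   # Up exchanges mostly via I2
        [1 / 6, 0.0, 1 / 6, 2 / 3],   # Down <-> I2 fast exchange
        [1 / 3, 1 / 6, 0.0, 1 / 2],   # I1 relaxes toward I2
        [1 / 3, 1 / 2, 1 / 6, 0.0],
    ]) * r
    np.fill_diagonal(macro_T, 0.0)
    np.fill_diagonal(macro_T, 1.0 - macro_T.sum(axis=1))
    # I1 relaxes a little faster than the rest
    macro_T[2] *= np.array([2.0, 2.0, 1.0, 2.0])
    macro_T[2, 2] = 0.0
    macro_T[2, 2] = 1.0 - macro_T[2].sum()

    a_down = sf_rate * down_odds / (1.0 + down_odds)
    b_down = sf_rate / (1.0 + down_odds)
    a_open_favor = sf_rate / (1.0 + down_odds)
    b_open_favor = sf_rate * down_odds / (1.0 + down_odds)
    sf_flip = np.array([
        [a_open_favor, b_open_favor],   # Up: open favored 75:1
        [a_down, b_down],               # Down: pinched favored 75:1
        [0.0, sf_rate],                 # I1: pinched never entered
        [a_open_favor, b_open_favor],   # I2: open favored
    ])

    tables = {
        "Up": _UP_ION_ENERGIES,
        "Down": _DOWN_ION_ENERGIES,
        "I1": _INTERMEDIATE_ION_ENERGIES,
        "I2": _INTERMEDIATE_ION_ENERGIES,
    }
    ion_T = np.empty((4, 2, 16, 16))
    for i, lab in enumerate(labels):
        ion_T[i, 0] = ion_hop_matrix(tables[lab], move_prob)
        ion_T[i, 1] = ion_hop_matrix(_pinched(tables[lab]), move_prob)
    return CoupledChainSpec(labels, macro_T, sf_flip, ion_T)


# ---------------------------------------------------------------------------
# Umbrella-sampling windows from analytic potentials
# ---------------------------------------------------------------------------


def gen_umbrella_samples(pmf, window_centers, k_spring: float,
                         n_samples: int, kT: float = KT_300K, seed: int = 0,
                         method: str = "rejection",
                         stride: int = 10) -> list[UmbrellaWindow]:
    """Draw umbrella-window samples from an analytic 1-D free energy.

    Per window i the target density is ∝ exp(-[U(z) + k/2 (z - z_i)^2]/kT).
    ``method="rejection"`` draws exact i.i.d. samples by proposing from the
    Gaussian the bias alone would give, N(z_i, kT/k), and accepting with
    exp(-(U(z) - U_min)/kT) (U_min taken over the proposal's 8-sigma range);
    ``method="metropolis"`` runs a random-walk chain thinned by ``stride``
    for tests that need autocorrelated input. The sampler and seed are
    recorded in each window's metadata.
    """
    if k_spring <= 0:
        raise ValueError("k_spring must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if method not in ("rejection", "metropolis"):
        raise ValueError(f"unknown sampler {method!r}")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(kT / k_spring)
    windows = []
    for center in np.asarray(window_centers, dtype=float):
        zgrid = np.linspace(center - 8 * sigma, center + 8 * sigma, 801)
        u_grid = np.asarray(pmf(zgrid), dtype=float)
        if not np.all(np.isfinite(u_grid)):
            raise ValueError(
                f"free-energy function is non-finite on the sampling range "
                f"of window at {center:.4f}"
            )
        u_min = u_grid.min()
        if method == "rejection":
            samples = np.empty(n_samples)
            filled = 0
            while filled < n_samples:
                n_prop = max(2 * (n_samples - filled), 64)
                z = rng.normal(center, sigma, size=n_prop)
                acc = rng.random(n_prop) < np.exp(
                    -(np.asarray(pmf(z), dtype=float) - u_min) / kT)
                z = z[acc][: n_samples - filled]
                samples[filled:filled + len(z)] = z
                filled += len(z)
        else:
            samples = np.empty(n_samples)
            z = center
            w_z = float(pmf(z)) + 0.5 * k_spring * (z - center) ** 2
            step = 1.5 * sigma
            prop = rng.normal(0.0, step, size=n_samples * stride)
            u = rng.random(n_samples * stride)
            j = 0
            for i in range(n_samples * stride):
                z_new = z + prop[i]
                w_new = (float(pmf(z_new))
                         + 0.5 * k_spring * (z_new - center) ** 2)
                if u[i] < np.exp(-(w_new - w_z) / kT):
                    z, w_z = z_new, w_new
                if (i + 1) % stride == 0:
                    samples[j] = z
                    j += 1
        windows.append(UmbrellaWindow(
            center=float(center), k_spring=k_spring, samples=samples,
            metadata={"sampler": method, "seed": seed, "kT": kT,
                      "stride": stride if method == "metropolis" else None}))
    return windows


# ---------------------------------------------------------------------------
# Toy channel frames
# ---------------------------------------------------------------------------

#: Default carbonyl-layer planes (nm), S1-top to S4-bottom; 0.3 nm sites.
DEFAULT_LAYER_Z = np.array([0.6, 0.3, 0.0, -0.3, -0.6])


@dataclass
class ToyChannelFrame:
    """Minimal channel geometry: carbonyl layers, ions, waters, markers.

    ``layer_z`` are the 5 carbonyl-oxygen plane heights (strictly
    decreasing); ``carbonyl_xyz`` carries 4 oxygens per layer on a ring so
    centroid-based boundary construction has something to average;
    ``marker_xyz`` are the two pore-diameter probe atoms at the
    extracellular mouth.
    """

    layer_z: np.ndarray
    ion_xyz: np.ndarray
    water_xyz: np.ndarray
    marker_xyz: np.ndarray
    carbonyl_xyz: np.ndarray

    def __post_init__(self) -> None:
        self.layer_z = np.asarray(self.layer_z, dtype=float)
        if not np.all(np.diff(self.layer_z) < 0):
            raise ValueError("layer planes must be strictly decreasing in z")

    def to_pdb(self, path) -> None:
        """Write the frame as a PDB for visual inspection."""
        import mdtraj as md

        top = md.Topology()
        xyz = []
        ch = top.add_chain()
        for i, pos in enumerate(self.carbonyl_xyz):
            res = top.add_residue("GLY", ch)
            top.add_atom("O", md.element.oxygen, res)
            xyz.append(pos)
        for pos in self.marker_xyz:
            res = top.add_residue("GLY", ch)
            top.add_atom("CA", md.element.carbon, res)
            xyz.append(pos)
        ch2 = top.add_chain()
        for pos in self.ion_xyz:
            res = top.add_residue("K", ch2)
            top.add_atom("K", md.element.potassium, res)
            xyz.append(pos)
        for pos in self.water_xyz:
            res = top.add_residue("HOH", ch2)
            top.add_atom("O", md.element.oxygen, res)
            xyz.append(pos)
        traj = md.Trajectory(np.asarray(xyz, dtype=float)[None], top)
        traj.save_pdb(str(path))


def gen_toy_channel_frames(occupancy_schedule, jitter: float = 0.0,
                           seed: int = 0, layer_z=DEFAULT_LAYER_Z,
                           pore_diameter_nm: float = 0.85,
                           n_cavity_waters: int = 0) -> list[ToyChannelFrame]:
    """Frames realizing a schedule of occupancy states exactly.

    Each frame places one ion on-axis at the midpoint of every occupied
    site, displaced along z by uniform jitter; vacant sites get no ion, so
    :func:`poremsm.featurize.assign_ion_sites` round-trips the schedule as
    long as ``jitter`` stays below half the smallest site height (larger
    values are refused). Optional cavity waters are placed below the S4
    plane. The pore-diameter markers sit ``pore_diameter_nm`` apart at the
    top plane (0.85 nm open-state default; build a 0.45 nm frame for the
    pinched-state analogue).
    """
    layer_z = np.asarray(layer_z, dtype=float)
    heights = -np.diff(layer_z)
    guard = heights.min() / 2.0
    if jitter >= guard:
        raise ValueError(
            f"jitter {jitter} would break the round-trip guarantee; it must "
            f"be below half the smallest site height ({guard:.4f} nm)"
        )
    rng = np.random.default_rng(seed)
    mids = 0.5 * (layer_z[:-1] + layer_z[1:])
    ring_r = 0.25
    angles = np.deg2rad([45.0, 135.0, 225.0, 315.0])
    carbonyls = np.array([[ring_r * np.cos(a), ring_r * np.sin(a), z]
                          for z in layer_z for a in angles])
    frames = []
    for entry in occupancy_schedule:
        state = entry if isinstance(entry, OccupancyState) \
            else OccupancyState(str(entry))
        ions = []
        for site in range(4):
            if state.occupied(site + 1):
                dz = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
                ions.append([0.0, 0.0, mids[site] + dz])
        waters = []
        for _ in range(n_cavity_waters):
            waters.append([rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2),
                           layer_z[-1] - rng.uniform(0.2, 0.6)])
        half = pore_diameter_nm / 2.0
        markers = np.array([[-half, 0.0, layer_z[0]],
                            [half, 0.0, layer_z[0]]])
        frames.append(ToyChannelFrame(
            layer_z=layer_z.copy(),
            ion_xyz=np.asarray(ions, dtype=float).reshape(-1, 3),
            water_xyz=np.asarray(waters, dtype=float).reshape(-1, 3),
            marker_xyz=markers,
            carbonyl_xyz=carbonyls))
    return frames
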