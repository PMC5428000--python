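"""Macrostate-conditioned Markov models of selectivity-filter ion occupancy.

Ion dynamics in the filter are modeled as a Markov chain over the 16
occupancy codes (four binding sites, occupied/vacant). Because ion kinetics
differ with channel conformation, transition pairs are first partitioned by
conformational macrostate — a pair at (t, t + lag) counts toward a
macrostate only if *every* frame in between carries that macrostate's
label; pairs spanning a conformational change are discarded rather than
attributed to either side. One reversible MSM is then fit per macrostate,
from which the dominant (stationary-argmax) occupancy state and the
stationary-flux transition network, with per-state sink scores, are read
off. In equilibrium data the resting state OXXO typically dominates and
acts as the network sink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurize import ALL_OCCUPANCY_STATES
from .msm import MarkovModel, largest_ergodic_set, mle_reversible_tmatrix

__all__ = [
    "ConditionedIonModel",
    "partition_by_macrostate",
    "fit_conditioned_models",
    "dominant_state",
    "transition_network",
]

N_ION_STATES = 16


@dataclass
class ConditionedIonModel:
    """Reversible occupancy-state MSM conditioned on one macrostate."""

    macrostate: object
    model: MarkovModel
    n_pairs: int
    n_discarded: int
    warnings: list = field(default_factory=list)

    def state_string(self, model_index: int) -> str:
        return ALL_OCCUPANCY_STATES[int(self.model.active_set[model_index])
                                    ].string


def partition_by_macrostate(ion_dtraj, macro_labels, lag_frames: int):
    """Split ion transition pairs by conformational macrostate.

    Returns (pairs_by_macro, n_discarded): for each macrostate label a
    (n, 2) array of (ion_t, ion_{t+lag}) code pairs whose whole frame span
    [t, t + lag] stays in that macrostate; all other eligible pairs are
    counted as discarded. Fails if no macrostate sustains a constant run of
    at least ``lag_frames`` frames, listing per-macrostate longest runs.
    """
    ion = np.asarray(ion_dtraj, dtype=np.int64)
    macro = np.asarray(macro_labels)
    if ion.shape != macro.shape:
        raise ValueError("ion and macrostate label sequences must be aligned")
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    n = len(ion)
    if n <= lag_frames:
        raise ValueError("sequence shorter than the lag")
    labels = np.unique(macro)
    # run_start[t] = index where the constant-macro run containing t began;
    # the pair (t, t+lag) stays within one macrostate iff the run containing
    # t+lag started at or before t
    idx = np.arange(n)
    is_start = np.concatenate([[True], macro[1:] != macro[:-1]])
    run_start = np.maximum.accumulate(np.where(is_start, idx, 0))
    t = idx[: n - lag_frames]
    valid = run_start[t + lag_frames] <= t
    discarded = int(np.sum(~valid))
    out = {}
    for m in labels:
        sel = t[valid & (macro[t] == m)]
        out[m] = np.column_stack([ion[sel], ion[sel + lag_frames]]) \
            if sel.size else np.empty((0, 2), dtype=np.int64)
    if all(p.shape[0] == 0 for p in out.values()):
        runs = {m: 0 for m in labels}
        t = 0
        while t < n:
            s = t
            while t + 1 < n and macro[t + 1] == macro[s]:
                t += 1
            runs[macro[s]] = max(runs[macro[s]], t - s + 1)
            t += 1
        if lag_frames > max(runs.values()):
            raise ValueError(
                f"lag {lag_frames} exceeds every constant-macrostate run; "
                f"longest runs: {runs}"
            )
    return out, discarded


def fit_conditioned_models(pairs_by_macro, n_discarded: int = 0,
                           lag_time: float = 1.0,
                           tol: float = 1e-12) -> dict:
    """Reversible occupancy MSM per macrostate from partitioned pairs.

    Counts live on the 16-state occupancy alphabet; each model is fit on
    the largest ergodic set of its own count graph, and a warning is
    recorded (not raised) when disconnected support forced a restriction.
    """
    out = {}
    for macro, pairs in pairs_by_macro.items():
        if pairs.shape[0] == 0:
            continue
        C = np.zeros((N_ION_STATES, N_ION_STATES), dtype=np.int64)
        np.add.at(C, (pairs[:, 0], pairs[:, 1]), 1)
        observed = np.nonzero(C.sum(axis=0) + C.sum(axis=1))[0]
        active = largest_ergodic_set(C)
        warnings = []
        if active.size < observed.size:
            dropped = np.setdiff1d(observed, active)
            warnings.append(
                f"disconnected occupancy support; dropped codes "
                f"{[ALL_OCCUPANCY_STATES[c].string for c in dropped]}"
            )
        sub = C[np.ix_(active, active)]
        model = mle_reversible_tmatrix(sub, tol=tol, lag_time=lag_time,
                                       active_set=active)
        out[macro] = ConditionedIonModel(
            macrostate=macro, model=model, n_pairs=int(pairs.shape[0]),
            n_discarded=int(n_discarded), warnings=warnings)
    return out


def dominant_state(conditioned: ConditionedIonModel) -> str:
    """Occupancy string with the largest stationary probability.

    Ties resolve to the lower occupancy code (active sets are sorted, and
    argmax takes the first maximum).
    """
    k = int(np.argmax(conditioned.model.stationary_distribution))
    return conditioned.state_string(k)


def transition_network(conditioned: ConditionedIonModel,
                       flux_threshold: float = 0.0):
    """Stationary-flux edge list and per-state sink scores.

    Edges i -> j (i != j) carry the stationary flux pi_i T_ij, the
    transition probability T_ij, and the rate per unit time (flux / lag);
    only edges with flux above ``flux_threshold`` are kept, sorted by
    descending flux. Node sink score = in-flux - out-flux over the listed
    edges, self-loops excluded; for a reversible model net edge fluxes
    vanish, but raw in-flux identifies the states transitions concentrate
    into (OXXO's sink role).
    """
    model = conditioned.model
    T = model.transition_matrix
    pi = model.stationary_distribution
    lag = model.lag_time
    rows = []
    n = model.n_states
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            flux = pi[i] * T[i, j]
            if flux > flux_threshold and T[i, j] > 0:
                rows.append({
                    "from": conditioned.state_string(i),
                    "to": conditioned.state_string(j),
                    "from_code": int(model.active_set[i]),
                    "to_code": int(model.active_set[j]),
                    "flux": flux,
                    "probability": T[i, j],
                    "rate": flux / lag,
                })
    edges = pd.DataFrame(rows).sort_values("flux", ascending=False,
                                           ignore_index=True) if rows else \
        pd.DataFrame(columns=["from", "to", "from_code", "to_code",
                              "flux", "probability", "rate"])
    nodes = []
    for i in range(n):
        s = conditioned.state_string(i)
        influx = edges.loc[edges["to"] == s, "flux"].sum() if len(edges) else 0.0
        outflux = edges.loc[edges["from"] == s, "flux"].sum() if len(edges) else 0.0
        nodes.append({"state": s, "code": int(model.active_set[i]),
                      "stationary": pi[i], "in_flux": influx,
                      "out_flux": outflux, "sink_score": influx - outflux,
                      "in_flux_rank": 0.0})
    nodes = pd.DataFrame(nodes)
    nodes["in_flux_rank"] = nodes["in_flux"].rank(ascending=False)
    return edges, nodes
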