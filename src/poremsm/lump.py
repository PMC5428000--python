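"""Macrostate lumping with PCCA+ and macrostate-level observables.

PCCA+ (Perron cluster cluster analysis) turns the leading right
eigenvectors of a reversible transition matrix into fuzzy memberships of
each microstate in n_macro metastable sets: the rows of the eigenvector
matrix live near the vertices of an (n_macro - 1)-simplex, and the
inner-simplex algorithm finds those vertices so memberships are the
barycentric coordinates. Crisp labels (argmax) recover, e.g., the
Up / Down / I1 / I2 conformational macrostates; downstream utilities give
macrostate populations, coarse-grained rates, the conditional
selectivity-filter state table (open vs pinched per macrostate, with the
pinched:open odds it implies), and representative-conformation selection
by dihedral PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .msm import MarkovModel, mfpt

__all__ = [
    "MacrostateAssignment",
    "ConditionalSFTable",
    "pcca_plus",
    "coarse_rates",
    "conditional_sf_table",
    "representative_conformation",
]


@dataclass
class MacrostateAssignment:
    """Fuzzy and crisp macrostate assignment of MSM microstates.

    ``memberships`` (chi) is microstates x macrostates, rows on the
    probability simplex; ``labels`` the argmax labels (ties to the lower
    macrostate index); ``populations`` the stationary mass of each
    macrostate, chi^T pi.
    """

    memberships: np.ndarray
    labels: np.ndarray
    populations: np.ndarray
    names: tuple | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_macro(self) -> int:
        return self.memberships.shape[1]

    def members(self, macro: int) -> np.ndarray:
        return np.nonzero(self.labels == macro)[0]


def _inner_simplex_vertices(psi: np.ndarray) -> np.ndarray:
    """Indices of rows of psi spanning the membership simplex.

    The standard index search: start from the row farthest from the origin,
    then repeatedly take the row farthest from the span of those already
    chosen (Gram-Schmidt deflation).
    """
    n, m = psi.shape
    ortho = psi.copy()
    idx = np.empty(m, dtype=int)
    idx[0] = int(np.argmax((ortho ** 2).sum(axis=1)))
    v = ortho[idx[0]] / np.linalg.norm(ortho[idx[0]])
    for j in range(1, m):
        ortho = ortho - np.outer(ortho @ v, v)
        idx[j] = int(np.argmax((ortho ** 2).sum(axis=1)))
        nrm = np.linalg.norm(ortho[idx[j]])
        if nrm == 0:
            raise ValueError("eigenvector rows do not span a simplex; "
                             "reduce n_macro")
        v = ortho[idx[j]] / nrm
    return idx


def pcca_plus(model: MarkovModel, n_macro: int,
              names=None) -> MacrostateAssignment:
    """PCCA+ memberships from the top-n_macro right eigenvectors.

    Requires a reversible model (real spectrum). Memberships are obtained
    by mapping the eigenvector rows through the inverse of the simplex
    vertices found by the inner-simplex search, then projected to
    feasibility (entries clipped to [0, 1], rows renormalized). With
    ``n_macro = 1`` the single all-ones membership column is returned.
    """
    if n_macro < 1:
        raise ValueError("n_macro must be >= 1")
    n = model.n_states
    if n_macro > n:
        raise ValueError("n_macro exceeds the number of microstates")
    pi = model.stationary_distribution
    if n_macro == 1:
        chi = np.ones((n, 1))
        return MacrostateAssignment(chi, np.zeros(n, dtype=int),
                                    np.array([1.0]), names=names)
    # reversibility guard: the symmetrized spectrum is only meaningful when
    # detailed balance holds; a non-reversible T can have complex pairs
    flux = pi[:, None] * model.transition_matrix
    if np.max(np.abs(flux - flux.T)) > 1e-6:
        w = np.linalg.eigvals(model.transition_matrix)
        w = w[np.argsort(-np.abs(w))][:n_macro]
        if np.any(np.abs(w.imag) > 1e-12):
            raise ValueError(
                "complex eigenvalues among the leading spectrum; use a "
                "reversible (detailed-balance) estimator before PCCA+"
            )
    w, psi = model.right_eigenvectors(n_macro)
    if w[n_macro - 1] <= 0:
        raise ValueError(
            f"only {int(np.sum(w > 0))} eigenvalues above the spectral cut; "
            f"cannot form {n_macro} macrostates"
        )
    psi[:, 0] = 1.0
    idx = _inner_simplex_vertices(psi)
    A = np.linalg.inv(psi[idx])
    chi = psi @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi /= chi.sum(axis=1, keepdims=True)
    labels = np.argmax(chi, axis=1)  # argmax takes the lower index on ties
    populations = chi.T @ pi
    populations /= populations.sum()
    return MacrostateAssignment(chi, labels, populations, names=names,
                                metadata={"vertex_states": idx,
                                          "eigenvalues": w})


def coarse_rates(model: MarkovModel, assignment: MacrostateAssignment):
    """Coarse-grained macrostate kinetics.

    Returns a dict with the coarse transition matrix
    T_mac = diag(chi^T pi)^-1 chi^T diag(pi) T chi (row-stochastic, with
    stationary distribution equal to the macrostate populations), and the
    matrix of macrostate-to-macrostate MFPTs over crisp label sets, in the
    model's physical time unit.
    """
    chi = assignment.memberships
    pi = model.stationary_distribution
    m = assignment.n_macro
    for a in range(m):
        if assignment.members(a).size == 0:
            raise ValueError(f"macrostate {a} has no crisp members")
    w = chi.T @ pi
    tmac = np.diag(1.0 / w) @ chi.T @ np.diag(pi) @ model.transition_matrix @ chi
    tmac /= tmac.sum(axis=1, keepdims=True)
    mfpts = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            mfpts[a, b] = mfpt(model, assignment.members(a),
                               assignment.members(b))
    return {"transition_matrix": tmac, "stationary": w / w.sum(),
            "mfpt": mfpts, "lag_time": model.lag_time}


@dataclass
class ConditionalSFTable:
    """Empirical P(SF state | macrostate) with backing counts."""

    probabilities: pd.DataFrame
    counts: pd.DataFrame

    def odds(self, macro, numerator, denominator) -> float:
        """e.g. odds("Down", "pinched", "open") — the pinched:open ratio."""
        row = self.probabilities.loc[macro]
        return float(row[numerator] / row[denominator])

    def to_tsv(self, path) -> None:
        merged = self.probabilities.copy()
        for c in self.counts.columns:
            merged[f"n_{c}"] = self.counts[c]
        merged.to_csv(path, sep="\t")


def conditional_sf_table(macro_labels, sf_labels, macro_names=None,
                         sf_names=None) -> ConditionalSFTable:
    """Per-macrostate SF-state probabilities from aligned label sequences.

    Rows for macrostates with zero frames are reported as NaN (undefined),
    not zero. The Down-row pinched:open odds is the headline conditional
    statistic of the coupled conformation/filter analysis.
    """
    macro_labels = np.asarray(macro_labels)
    sf_labels = np.asarray(sf_labels)
    if macro_labels.shape != sf_labels.shape:
        raise ValueError("macro and SF label sequences must be aligned")
    macros = (list(macro_names) if macro_names is not None
              else sorted(np.unique(macro_labels).tolist()))
    sfs = (list(sf_names) if sf_names is not None
           else sorted(np.unique(sf_labels).tolist()))
    counts = pd.DataFrame(0, index=pd.Index(macros, name="macrostate"),
                          columns=sfs, dtype=int)
    for m in macros:
        sel = sf_labels[macro_labels == m]
        for s in sfs:
            counts.loc[m, s] = int(np.sum(sel == s))
    totals = counts.sum(axis=1)
    probs = counts.div(totals.replace(0, np.nan), axis=0)
    return ConditionalSFTable(probabilities=probs, counts=counts)


def representative_conformation(dihedrals, n_components: int = 2) -> int:
    """Pick the conformation closest to the group mean in dihedral PC space.

    Dihedral angles (radians, conformations x angles) are embedded as
    (sin, cos) pairs to avoid angular wrap, reduced by PCA to the top
    ``n_components`` (2 by default), and the conformation nearest the mean
    in that subspace is returned; ties go to the lower index. With a single
    conformation it is returned directly.
    """
    dihedrals = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    n = dihedrals.shape[0]
    if n == 0:
        raise ValueError("need at least one conformation")
    if n == 1:
        return 0
    emb = np.concatenate([np.sin(dihedrals), np.cos(dihedrals)], axis=1)
    k = min(n_components, n - 1, emb.shape[1])
    pcs = PCA(n_components=k).fit_transform(emb)
    d2 = (pcs ** 2).sum(axis=1)  # PCA output is mean-centered
    return int(np.argmin(d2))
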