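"""Geometric featurization of channel trajectories.

Turns coordinate data into the quantities the kinetic analysis runs on:

* cross-chain residue-pair distances over the pore region (input to tICA on
  the whole-channel "up-down" motion),
* all-pairs distances among selectivity-filter (SF) atoms (input to the
  SF-focused tICA),
* the 16-letter ion-occupancy alphabet over binding sites S1..S4,
* the signed reaction coordinate dz for ion transitions (ion position relative
  to the SF centre of mass, projected on the pore axis),
* quality-control observables: pore diameter at the extracellular mouth,
  per-site water counts, and RMSD drift to a reference structure.

Units are nm throughout, except :func:`pore_diameter` which reports Angstrom
(the convention used when quoting pore-mouth constriction). Site positions are
indexed S1 (extracellular, largest z) to S4 (intracellular), with the pore
axis pointing extracellular.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .trajectory import FeatureTrajectory

__all__ = [
    "OccupancyState",
    "ALL_OCCUPANCY_STATES",
    "SiteBoundaries",
    "SiteAssignment",
    "pairwise_chain_distances",
    "sf_distances",
    "assign_ion_sites",
    "reaction_coordinate_dz",
    "pore_diameter",
    "count_site_waters",
    "rmsd_to_reference",
]

N_SITES = 4


@dataclass(frozen=True)
class OccupancyState:
    """Ion occupancy of the four SF binding sites, S1 -> S4.

    ``string`` is four characters over {O, X} (X = occupied), ordered S1 to
    S4; ``code`` is the integer with S1 as the most significant bit, so the
    16 states map bijectively onto 0..15 (e.g. ``"OXXO"`` <-> 6).
    """

    string: str

    def __post_init__(self) -> None:
        if len(self.string) != N_SITES or set(self.string) - {"O", "X"}:
            raise ValueError(
                f"occupancy string must be 4 characters over {{O,X}}, got "
                f"{self.string!r}"
            )

    @property
    def code(self) -> int:
        c = 0
        for ch in self.string:
            c = (c << 1) | (ch == "X")
        return c

    @classmethod
    def from_code(cls, code: int) -> "OccupancyState":
        if not 0 <= code <= 15:
            raise ValueError(f"occupancy code must be in 0..15, got {code}")
        return cls("".join("X" if code & (1 << (N_SITES - 1 - i)) else "O"
                           for i in range(N_SITES)))

    def occupied(self, site: int) -> bool:
        """1-based site index (1 = S1)."""
        return self.string[site - 1] == "X"

    def __str__(self) -> str:
        return self.string


#: All 16 occupancy states in code order 0..15.
ALL_OCCUPANCY_STATES: list[OccupancyState] = [
    OccupancyState.from_code(c) for c in range(16)
]


@dataclass
class SiteBoundaries:
    """Five monotone z-planes delimiting sites S1..S4 along the pore axis.

    Planes are ordered S1-top to S4-bottom, i.e. strictly decreasing z, so
    site i (1-based) spans ``(planes[i], planes[i-1])``. The default
    construction places the planes at the carbonyl-oxygen layer centroids
    that sandwich each site; explicit planes may be given instead.
    """

    planes: np.ndarray

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.shape != (N_SITES + 1,):
            raise ValueError("exactly 5 boundary planes are required")
        if not np.all(np.diff(self.planes) < 0):
            raise ValueError("boundary planes must be strictly decreasing in z")

    @classmethod
    def from_layer_centroids(cls, layer_z) -> "SiteBoundaries":
        """Boundaries from the mean z of each of the 5 carbonyl layers."""
        z = np.asarray([np.mean(l) for l in layer_z], dtype=float)
        return cls(z)

    def interval(self, site: int) -> tuple[float, float]:
        """(low, high) z-interval of 1-based site."""
        if not 1 <= site <= N_SITES:
            raise ValueError(f"site must be 1..4, got {site}")
        return float(self.planes[site]), float(self.planes[site - 1])

    @property
    def site_heights(self) -> np.ndarray:
        return -np.diff(self.planes)


@dataclass
class SiteAssignment:
    """Result of projecting the ions of one frame onto the site grid."""

    state: OccupancyState
    per_site_counts: np.ndarray
    outside_count: int
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        self.degenerate = bool(np.any(self.per_site_counts > 1))


def _unit(axis) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("pore axis must have nonzero length")
    return axis / n


def assign_ion_sites(ion_xyz, boundaries: SiteBoundaries,
                     axis=(0.0, 0.0, 1.0)) -> SiteAssignment:
    """Classify ions into SF binding sites by axial projection.

    A site is occupied (X) iff at least one ion projects into its z-interval;
    ions projecting outside all four intervals do not enter the string but
    are tallied in ``outside_count`` (e.g. cavity or bulk ions). Frames with
    two or more ions in a single site cannot be represented in the 16-state
    alphabet; the site is still marked X and the assignment is flagged
    ``degenerate`` so callers can count such frames rather than drop them
    silently.
    """
    u = _unit(axis)
    ion_xyz = np.asarray(ion_xyz, dtype=float).reshape(-1, 3)
    proj = ion_xyz @ u
    counts = np.zeros(N_SITES, dtype=int)
    outside = 0
    for z in proj:
        site_hit = False
        for s in range(1, N_SITES + 1):
            lo, hi = boundaries.interval(s)
            if lo <= z < hi:
                counts[s - 1] += 1
                site_hit = True
                break
        if not site_hit:
            outside += 1
    string = "".join("X" if c else "O" for c in counts)
    return SiteAssignment(OccupancyState(string), counts, outside)


def reaction_coordinate_dz(ion_xyz, sf_xyz, axis=(0.0, 0.0, 1.0),
                           masses=None) -> float:
    """Signed ion progress coordinate dz (nm).

    Projection of the vector from the SF centre of mass to the transitioning
    ion onto the (unit-normalized) pore axis; positive toward the
    extracellular side.
    """
    u = _unit(axis)
    sf_xyz = np.asarray(sf_xyz, dtype=float).reshape(-1, 3)
    if sf_xyz.shape[0] == 0:
        raise ValueError("SF selection is empty")
    w = (np.full(sf_xyz.shape[0], 1.0) if masses is None
         else np.asarray(masses, dtype=float))
    com = (w[:, None] * sf_xyz).sum(axis=0) / w.sum()
    return float((np.asarray(ion_xyz, dtype=float) - com) @ u)


def pore_diameter(xyz_a, xyz_b) -> float:
    """Distance between two marker atoms (nm in, Angstrom out).

    Used for the G176(A)-G176(B) probe at the extracellular mouth of the
    filter; reported in Angstrom to match how pore constriction is quoted.
    """
    a = np.asarray(xyz_a, dtype=float)
    b = np.asarray(xyz_b, dtype=float)
    return float(np.linalg.norm(a - b)) * 10.0


def count_site_waters(water_xyz, boundaries: SiteBoundaries,
                      radial_cutoff: float,
                      axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Per-site count of waters inside the filter.

    A water counts toward site i when its axial projection falls in the
    site's z-interval and its distance from the axis is below
    ``radial_cutoff`` (nm). The axis is taken through the origin.
    """
    u = _unit(axis)
    water_xyz = np.asarray(water_xyz, dtype=float).reshape(-1, 3)
    counts = np.zeros(N_SITES, dtype=int)
    if water_xyz.shape[0] == 0:
        return counts
    proj = water_xyz @ u
    radial = np.linalg.norm(water_xyz - proj[:, None] * u, axis=1)
    for s in range(1, N_SITES + 1):
        lo, hi = boundaries.interval(s)
        counts[s - 1] = int(np.sum((proj >= lo) & (proj < hi)
                                   & (radial < radial_cutoff)))
    return counts


# -- mdtraj-backed featurizers for real trajectories -----------------------


def _residue_atom(chain, resseq: int, atom_role: str, chain_name: str):
    for res in chain.residues:
        if res.resSeq == resseq:
            for atom in res.atoms:
                if atom.name == atom_role:
                    return atom
            raise ValueError(
                f"residue {resseq} on chain {chain_name} has no atom "
                f"{atom_role!r}"
            )
    raise ValueError(f"chain {chain_name} has no residue {resseq}")


def pairwise_chain_distances(traj, residue_ranges, atom_role: str = "CA",
                             chains=(0, 1)) -> FeatureTrajectory:
    """Corresponding-residue distances between the two channel chains.

    For every residue index in the inclusive ``residue_ranges`` (1-based, as
    in sequence numbering), measures the distance between that residue's
    ``atom_role`` atom on chain A and the *same residue index* on chain B —
    one feature per residue, pairing like with like across the symmetric
    dimer. The default pore-region ranges (1-24, 112-189, 230-256) yield
    129 features.

    Parameters
    ----------
    traj : mdtraj.Trajectory
    residue_ranges : list of (first, last) inclusive 1-based residue indices
    atom_role : atom name anchoring each residue (default alpha carbon)
    """
    import mdtraj  # noqa: F401  (traj must be an mdtraj.Trajectory)

    top = traj.topology
    chain_list = list(top.chains)
    if max(chains) >= len(chain_list):
        raise ValueError(
            f"topology has {len(chain_list)} chains, need indices {chains}"
        )
    ca, cb = chain_list[chains[0]], chain_list[chains[1]]
    pairs, labels = [], []
    for first, last in residue_ranges:
        for resseq in range(first, last + 1):
            a = _residue_atom(ca, resseq, atom_role, "A")
            b = _residue_atom(cb, resseq, atom_role, "B")
            pairs.append((a.index, b.index))
            labels.append(f"{atom_role}:{resseq}")
    import mdtraj as md

    d = md.compute_distances(traj, np.asarray(pairs), periodic=False)
    dt = float(traj.timestep) if traj.n_frames > 1 and traj.timestep > 0 else 1.0
    return FeatureTrajectory(d, dt=dt, labels=labels,
                             metadata={"featurizer": "pairwise_chain_distances",
                                       "atom_role": atom_role})


def sf_distances(traj, atom_indices) -> FeatureTrajectory:
    """All unordered pairwise distances among selectivity-filter atoms.

    n atoms give n(n-1)/2 features; used to learn the SF-focused tICA model
    that separates the open and pinched filter conformations.
    """
    import mdtraj as md

    atom_indices = list(atom_indices)
    if len(atom_indices) < 2:
        raise ValueError("need at least 2 SF atoms")
    pairs = list(itertools.combinations(atom_indices, 2))
    d = md.compute_distances(traj, np.asarray(pairs), periodic=False)
    labels = [f"d:{i}-{j}" for i, j in pairs]
    dt = float(traj.timestep) if traj.n_frames > 1 and traj.timestep > 0 else 1.0
    return FeatureTrajectory(d, dt=dt, labels=labels,
                             metadata={"featurizer": "sf_distances"})


def rmsd_to_reference(traj, reference, atom_indices=None) -> np.ndarray:
    """Per-frame least-squares-superposed RMSD (nm) to a reference frame.

    Monitored during umbrella sampling to catch bias-induced distortion of
    the protein conformation.
    """
    import mdtraj as md

    if atom_indices is not None:
        atom_indices = np.asarray(atom_indices)
        if traj.n_atoms < atom_indices.max() + 1:
            raise ValueError("atom selection exceeds trajectory atom count")
    elif traj.n_atoms != reference.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {traj.n_atoms}, "
            f"reference has {reference.n_atoms}"
        )
    return md.rmsd(traj, reference, atom_indices=atom_indices)
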