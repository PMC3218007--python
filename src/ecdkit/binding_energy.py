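"""Single-trajectory MM interaction energies and per-residue decomposition.

The gas-phase interaction between a receptor and a ligand group is the sum
over cross pairs of Coulomb and Lennard-Jones terms (Lorentz-Berthelot
combining, no distance cutoff).  In the single-trajectory scheme the
internal energies of each group are identical in complex and separated
states and cancel exactly, so only cross terms are computed.  A nonpolar
solvation term is estimated from the buried solvent-accessible surface
area (Shrake-Rupley); polar (Poisson-Boltzmann) solvation and solute
entropy are accepted as externally computed per-frame values — this
package does not solve the PB equation.

Energies are in kcal/mol, charges in elementary charge units, distances
in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory_io import AtomSelection, Topology, Trajectory

__all__ = [
    "EnergyModel",
    "EnergyDecomposition",
    "interaction_energy",
    "sasa",
    "delta_sasa",
    "binding_energy_series",
    "decompose_per_residue",
    "VDW_RADII",
]

#: AMBER electrostatic constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0637

#: Bondi-style van der Waals radii (A) used for SASA.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "MN": 1.39, "FE": 1.39,
    "CU": 1.40, "SE": 1.90,
}

_MIN_DISTANCE = 0.1  # A; closer cross pairs are treated as clashes


@dataclass
class EnergyModel:
    """Force-field style parameters for the MM + SASA estimate.

    ``gamma`` and ``b`` are the surface-tension coefficient and offset of
    the nonpolar solvation model G_np = gamma*SASA + b (common MM-PBSA
    defaults); ``b`` enters absolute single-structure estimates only — it
    cancels in binding differences.
    """

    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    gamma: float = 0.00542          # kcal/mol/A^2
    b: float = 0.92                 # kcal/mol
    probe_radius: float = 1.4       # A
    sasa_points: int = 960
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


def _require_parameters(topology: Topology, indices: np.ndarray) -> None:
    missing = []
    for attr in ("charge", "lj_sigma", "lj_epsilon"):
        arr = getattr(topology, attr)
        if arr is None:
            missing.append((attr, "all atoms"))
            continue
        bad = indices[~np.isfinite(arr[indices])]
        if len(bad):
            names = [f"{topology.chain_id[i]}:{topology.res_id[i]}:"
                     f"{topology.atom_name[i]}" for i in bad[:8]]
            missing.append((attr, names))
    if missing:
        raise ValueError(f"missing energy parameters: {missing}")


def _cross_pair_energies(
    frame: np.ndarray,
    topology: Topology,
    model: EnergyModel,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_a, n_b) electrostatic and van der Waals pair-energy matrices."""
    ra = frame[group_a]
    rb = frame[group_b]
    r = cdist(ra, rb)
    if r.min() < _MIN_DISTANCE:
        ia, ib = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"clash: atoms {group_a[ia]} and {group_b[ib]} are "
            f"{r.min():.3f} A apart"
        )
    q = topology.charge
    sig = topology.lj_sigma
    eps = topology.lj_epsilon
    e_ele = (model.coulomb_constant / model.dielectric) \
        * np.outer(q[group_a], q[group_b]) / r
    sigma_ij = 0.5 * (sig[group_a][:, None] + sig[group_b][None, :])
    eps_ij = np.sqrt(np.outer(eps[group_a], eps[group_b]))
    sr6 = (sigma_ij / r) ** 6
    e_vdw = 4.0 * eps_ij * (sr6 ** 2 - sr6)
    return e_ele, e_vdw


def interaction_energy(
    frame: np.ndarray,
    topology: Topology,
    model: EnergyModel,
    group_a: AtomSelection,
    group_b: AtomSelection,
) -> tuple[float, float]:
    """(E_ele, E_vdw) between two groups, all cross pairs, no cutoff."""
    a = group_a.indices
    b = group_b.indices
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if len(np.intersect1d(a, b)):
        raise ValueError("groups overlap")
    _require_parameters(topology, np.concatenate([a, b]))
    e_ele, e_vdw = _cross_pair_energies(
        np.asarray(frame, dtype=np.float64), topology, model, a, b)
    return float(e_ele.sum()), float(e_vdw.sum())


def sasa(
    coords: np.ndarray,
    topology: Topology,
    model: EnergyModel | None = None,
    subset: AtomSelection | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Uses a deterministic Fibonacci point set; the quadrature error on a
    single sphere is below 1% at the default point count.  When
    ``subset`` is given, only those atoms are present (the others are
    removed, not merely masked).
    """
    model = model or EnergyModel()
    import biotite.structure as struc

    idx = subset.indices if subset is not None else \
        np.arange(topology.n_atoms)
    arr = struc.AtomArray(len(idx))
    arr.coord = np.asarray(coords, dtype=np.float64)[idx].astype(np.float32)
    arr.element = topology.element[idx]
    arr.atom_name = topology.atom_name[idx]
    arr.res_id = topology.res_id[idx]
    arr.res_name = topology.res_name[idx]
    arr.chain_id = topology.chain_id[idx]
    try:
        radii = np.array([model.vdw_radii[el] for el in arr.element])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc}")
    # exactly coincident atoms: surface points lie ON (not inside) the
    # twin sphere and would be double counted; keep one copy, assign the
    # duplicate zero exposed area
    rounded = np.round(arr.coord.astype(np.float64), 6)
    _, inverse = np.unique(rounded, axis=0, return_inverse=True)
    keep = np.zeros(len(idx), dtype=bool)
    for g in range(inverse.max() + 1):
        members = np.flatnonzero(inverse == g)
        keep[members[np.argmax(radii[members])]] = True
    values = np.zeros(len(idx))
    computed = struc.sasa(
        arr[keep], probe_radius=model.probe_radius,
        point_number=model.sasa_points, vdw_radii=radii[keep],
        ignore_ions=False,
    )
    values[keep] = np.nan_to_num(computed.astype(np.float64))
    return values


def delta_sasa(
    frame: np.ndarray,
    topology: Topology,
    model: EnergyModel,
    receptor: AtomSelection,
    ligand: AtomSelection,
) -> tuple[float, np.ndarray]:
    """Buried area on complexation: SASA(complex) - SASA(parts).

    Returns the (negative) total change and the per-atom change over the
    complex atom order (receptor atoms then ligand atoms).
    """
    both = receptor | ligand
    complex_sasa = sasa(frame, topology, model, both)
    rec_sasa = sasa(frame, topology, model, receptor)
    lig_sasa = sasa(frame, topology, model, ligand)
    separate = np.empty(len(both))
    pos = {int(g): i for i, g in enumerate(both.indices)}
    for arr, sel in ((rec_sasa, receptor), (lig_sasa, ligand)):
        for value, g in zip(arr, sel.indices):
            separate[pos[int(g)]] = value
    per_atom = complex_sasa - separate
    return float(per_atom.sum()), per_atom


def binding_energy_series(
    traj: Trajectory,
    model: EnergyModel,
    receptor: AtomSelection,
    ligand: AtomSelection,
    external_polar: np.ndarray | None = None,
    external_entropy: float | None = None,
) -> dict:
    """Per-frame binding-energy estimate, averaged with its spread.

    Each frame contributes ``E_ele + E_vdw + gamma*dSASA`` plus the
    externally supplied polar-solvation value for that frame (0 if
    absent); the entropy term ``-T*dS`` is added to the mean only if
    supplied.  Returns a dict with the per-frame series and summary
    statistics.
    """
    if len(np.intersect1d(receptor.indices, ligand.indices)):
        raise ValueError("receptor and ligand selections overlap")
    if external_polar is not None:
        external_polar = np.asarray(external_polar, dtype=np.float64)
        if external_polar.shape != (traj.n_frames,):
            raise ValueError("external_polar must have one value per frame")
    _require_parameters(
        topology=traj.topology,
        indices=np.concatenate([receptor.indices, ligand.indices]))
    e_ele = np.empty(traj.n_frames)
    e_vdw = np.empty(traj.n_frames)
    e_np = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coordinates[t]
        ele, vdw = _cross_pair_energies(
            frame, traj.topology, model, receptor.indices, ligand.indices)
        e_ele[t] = ele.sum()
        e_vdw[t] = vdw.sum()
        dA, _ = delta_sasa(frame, traj.topology, model, receptor, ligand)
        e_np[t] = model.gamma * dA
    total = e_ele + e_vdw + e_np
    if external_polar is not None:
        total = total + external_polar
    mean = float(total.mean())
    if external_entropy is not None:
        mean += float(external_entropy)
    return {
        "per_frame": total,
        "E_ele": e_ele,
        "E_vdw": e_vdw,
        "E_nonpolar": e_np,
        "mean": mean,
        "sd": float(total.std(ddof=0)),
        "includes_polar": external_polar is not None,
        "includes_entropy": external_entropy is not None,
    }


@dataclass
class EnergyDecomposition:
    """Per-residue contributions to the binding energy.

    ``table`` has one row per residue on either side of the interface
    with electrostatic, van der Waals and nonpolar (buried-surface)
    contributions.  Every cross pair is attributed in full to the residue
    on each side, so the receptor-side rows and the ligand-side rows each
    sum to the total E_ele and E_vdw.  The nonpolar term is not pairwise:
    each residue carries the buried area of its own atoms, and the two
    sides together sum to gamma times the total buried area.
    """

    table: pd.DataFrame
    total_ele: float
    total_vdw: float
    total_nonpolar: float

    @property
    def total(self) -> float:
        return self.total_ele + self.total_vdw + self.total_nonpolar

    def side_sum(self, side: str, term: str = "total") -> float:
        sub = self.table[self.table["side"] == side]
        return float(sub[term].sum())

    def relative_to(self, reference: "EnergyDecomposition") -> pd.DataFrame:
        """Re-base contributions against a named reference condition."""
        merged = self.table.merge(
            reference.table, on=["side", "chain", "res_id", "res_name"],
            suffixes=("", "_ref"), how="left",
        )
        out = merged[["side", "chain", "res_id", "res_name"]].copy()
        for term in ("E_ele", "E_vdw", "E_nonpolar", "total"):
            out[term] = merged[term] - merged[f"{term}_ref"].fillna(0.0)
        return out

    def significant(self, threshold: float = 1.0) -> pd.DataFrame:
        """Rows with |total| >= threshold kcal/mol (reporting convention);
        the full table remains available."""
        return self.table[self.table["total"].abs() >= threshold]


def decompose_per_residue(
    traj: Trajectory,
    model: EnergyModel,
    receptor: AtomSelection,
    ligand: AtomSelection,
    include_sasa: bool = True,
) -> EnergyDecomposition:
    """Residue-level breakdown of the cross-interaction energy.

    Contributions are averaged over frames.  The nonpolar share of a
    residue is gamma times the buried area of its own atoms.
    """
    top = traj.topology
    a = receptor.indices
    b = ligand.indices
    if len(np.intersect1d(a, b)):
        raise ValueError("receptor and ligand selections overlap")
    _require_parameters(top, np.concatenate([a, b]))

    keys = {}
    for side, sel in (("receptor", a), ("ligand", b)):
        for g in sel:
            key = (side, str(top.chain_id[g]), int(top.res_id[g]))
            keys.setdefault(key, []).append(int(g))
    key_list = list(keys)
    acc = {key: np.zeros(3) for key in key_list}  # ele, vdw, np
    tot = np.zeros(3)

    both = receptor | ligand
    complex_pos = {int(g): i for i, g in enumerate(both.indices)}
    pos_a = {int(g): i for i, g in enumerate(a)}
    pos_b = {int(g): j for j, g in enumerate(b)}

    for t in range(traj.n_frames):
        frame = traj.coordinates[t]
        e_ele, e_vdw = _cross_pair_energies(frame, top, model, a, b)
        row_ele = e_ele.sum(axis=1)
        row_vdw = e_vdw.sum(axis=1)
        col_ele = e_ele.sum(axis=0)
        col_vdw = e_vdw.sum(axis=0)
        per_atom_np = None
        if include_sasa:
            _, per_atom = delta_sasa(frame, top, model, receptor, ligand)
            per_atom_np = model.gamma * per_atom
        for key, atoms in keys.items():
            side = key[0]
            ele = vdw = 0.0
            for g in atoms:
                if side == "receptor":
                    ele += row_ele[pos_a[g]]
                    vdw += row_vdw[pos_a[g]]
                else:
                    ele += col_ele[pos_b[g]]
                    vdw += col_vdw[pos_b[g]]
            np_term = 0.0
            if per_atom_np is not None:
                np_term = sum(per_atom_np[complex_pos[g]] for g in atoms)
            acc[key] += np.array([ele, vdw, np_term])
        tot += np.array([
            e_ele.sum(), e_vdw.sum(),
            float(per_atom_np.sum()) if per_atom_np is not None else 0.0,
        ])

    n = traj.n_frames
    rows = []
    for (side, chain, res_id), atoms in keys.items():
        ele, vdw, np_term = acc[(side, chain, res_id)] / n
        rows.append({
            "side": side, "chain": chain, "res_id": res_id,
            "res_name": top.res_name[atoms[0]],
            "E_ele": ele, "E_vdw": vdw, "E_nonpolar": np_term,
            "total": ele + vdw + np_term,
        })
    table = pd.DataFrame(rows).sort_values(
        ["side", "chain", "res_id"]).reset_index(drop=True)
    return EnergyDecomposition(
        table=table,
        total_ele=float(tot[0] / n),
        total_vdw=float(tot[1] / n),
        total_nonpolar=float(tot[2] / n),
    )
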