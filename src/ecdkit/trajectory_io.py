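"""Trajectory containers, readers/writers, superposition and RMSD.

Coordinates are in Angstrom throughout, times in picoseconds.  A
:class:`Trajectory` is a dense ``(n_frames, n_atoms, 3)`` array plus a
:class:`Topology`; multi-model PDB and frame-concatenated XYZ are the
on-disk formats, with an optional TSV sidecar carrying per-atom charges
and Lennard-Jones parameters that PDB cannot hold.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Topology",
    "AtomSelection",
    "Trajectory",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "read_topology_tsv",
    "write_topology_tsv",
    "superpose",
    "rmsd",
    "rmsd_series",
    "write_rmsd_series",
]

# Elements this package knows about; anything else triggers name inference.
KNOWN_ELEMENTS = frozenset(
    "H C N O P S F CL BR I NA K MG CA ZN MN FE CU SE".split()
)

WATER_RES_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})
DNA_RES_NAMES = frozenset(
    {"DA", "DT", "DG", "DC", "DA5", "DT5", "DG5", "DC5",
     "DA3", "DT3", "DG3", "DC3", "A", "T", "G", "C", "U", "DU"}
)
PROTEIN_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class TrajectoryParseError(ValueError):
    """Raised when a trajectory or topology file cannot be parsed."""


def _as_str_array(values: Sequence[str], n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object).astype(str)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got {arr.shape}")
    return arr


@dataclass
class Topology:
    """Per-atom metadata: names, elements, residue assignment, parameters.

    ``charge`` (e), ``lj_sigma`` (Angstrom) and ``lj_epsilon`` (kcal/mol)
    are optional and NaN where unknown.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    charge: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        self.atom_name = _as_str_array(self.atom_name, n, "atom_name")
        self.element = np.char.upper(_as_str_array(self.element, n, "element"))
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = _as_str_array(self.res_name, n, "res_name")
        self.chain_id = _as_str_array(self.chain_id, n, "chain_id")
        for attr in ("charge", "lj_sigma", "lj_epsilon"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val, dtype=np.float64)
                if val.shape != (n,):
                    raise ValueError(f"{attr} must have shape ({n},)")
                setattr(self, attr, val)
        unknown = set(self.element) - KNOWN_ELEMENTS
        if unknown:
            inferred = []
            for i, el in enumerate(self.element):
                if el not in KNOWN_ELEMENTS:
                    guess = _infer_element(self.atom_name[i])
                    self.element[i] = guess
                    inferred.append((self.atom_name[i], guess))
            warnings.warn(
                f"unknown element(s) {sorted(unknown)}; "
                f"inferred from atom names: {inferred[:5]}"
            )
        # residue ids must not decrease within a chain
        for chain in np.unique(self.chain_id):
            ids = self.res_id[self.chain_id == chain]
            if np.any(np.diff(ids) < 0):
                raise ValueError(
                    f"res_ids decrease within chain {chain!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def __len__(self) -> int:
        return self.n_atoms

    # ---- selection helpers -------------------------------------------------
    def select(
        self,
        *,
        atom_name: str | Iterable[str] | None = None,
        element: str | Iterable[str] | None = None,
        res_id: int | Iterable[int] | None = None,
        res_name: str | Iterable[str] | None = None,
        chain_id: str | Iterable[str] | None = None,
        mask: np.ndarray | None = None,
    ) -> "AtomSelection":
        """Combine equality filters (AND across fields, OR within a field)."""
        keep = np.ones(self.n_atoms, dtype=bool)

        def _match(values: np.ndarray, wanted) -> np.ndarray:
            if isinstance(wanted, (str, int, np.integer)):
                wanted = [wanted]
            return np.isin(values, np.asarray(list(wanted)))

        if atom_name is not None:
            keep &= _match(self.atom_name, atom_name)
        if element is not None:
            wanted = element if not isinstance(element, str) else [element]
            keep &= _match(self.element, [e.upper() for e in wanted])
        if res_id is not None:
            keep &= _match(self.res_id, res_id)
        if res_name is not None:
            keep &= _match(self.res_name, res_name)
        if chain_id is not None:
            keep &= _match(self.chain_id, chain_id)
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        return AtomSelection(np.flatnonzero(keep), self.n_atoms)

    def calpha(self) -> "AtomSelection":
        return self.select(atom_name="CA", element="C")

    def backbone(self) -> "AtomSelection":
        """Protein backbone heavy atoms (N, CA, C, O)."""
        keep = np.isin(self.atom_name, list(PROTEIN_BACKBONE_NAMES))
        keep &= ~np.isin(self.res_name, list(WATER_RES_NAMES))
        keep &= ~np.isin(self.res_name, list(DNA_RES_NAMES))
        return AtomSelection(np.flatnonzero(keep), self.n_atoms)

    def heavy(self) -> "AtomSelection":
        return AtomSelection(np.flatnonzero(self.element != "H"), self.n_atoms)

    def is_water(self) -> np.ndarray:
        return np.isin(self.res_name, list(WATER_RES_NAMES))

    def is_dna(self) -> np.ndarray:
        return np.isin(self.res_name, list(DNA_RES_NAMES))

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, res_id) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.res_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_atoms(self, chain: str, res: int) -> np.ndarray:
        return np.flatnonzero((self.chain_id == chain) & (self.res_id == res))


def _infer_element(atom_name: str) -> str:
    """Best-effort element from a PDB atom name."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        return "C"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "MN", "FE", "SE"}:
        return two
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomSelection:
    """An ordered set of atom indices into a :class:`Topology`."""

    indices: np.ndarray
    n_atoms_total: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        if len(idx) and (idx.min() < 0 or idx.max() >= self.n_atoms_total):
            raise ValueError("selection index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def __and__(self, other: "AtomSelection") -> "AtomSelection":
        common = np.intersect1d(self.indices, other.indices)
        return AtomSelection(common, self.n_atoms_total)

    def __or__(self, other: "AtomSelection") -> "AtomSelection":
        both = np.union1d(self.indices, other.indices)
        return AtomSelection(both, self.n_atoms_total)


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinate array with topology and optional times."""

    coordinates: np.ndarray
    topology: Topology
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} "
                f"!= topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=np.float64)
            if t.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal n_frames")
            if self.n_frames > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("frame_times must be strictly increasing")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        times = None
        if self.frame_times is not None:
            times = self.frame_times[start:stop]
        return Trajectory(self.coordinates[start:stop].copy(),
                          self.topology, times)


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------

def write_topology_tsv(topology: Topology, path: str | Path) -> None:
    n = topology.n_atoms
    df = pd.DataFrame(
        {
            "atom_index": np.arange(n),
            "atom_name": topology.atom_name,
            "element": topology.element,
            "res_id": topology.res_id,
            "res_name": topology.res_name,
            "chain": topology.chain_id,
            "charge": topology.charge if topology.charge is not None
            else np.full(n, np.nan),
            "lj_sigma": topology.lj_sigma if topology.lj_sigma is not None
            else np.full(n, np.nan),
            "lj_epsilon": topology.lj_epsilon
            if topology.lj_epsilon is not None else np.full(n, np.nan),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_topology_tsv(path: str | Path) -> Topology:
    df = pd.read_csv(path, sep="\t")
    required = {"atom_name", "element", "res_id", "res_name", "chain"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryParseError(
            f"topology TSV {path} missing columns {sorted(missing)}"
        )

    def _opt(col: str) -> np.ndarray | None:
        if col in df.columns and not df[col].isna().all():
            return df[col].to_numpy(dtype=np.float64)
        return None

    return Topology(
        atom_name=df["atom_name"].to_numpy(),
        element=df["element"].to_numpy(),
        res_id=df["res_id"].to_numpy(),
        res_name=df["res_name"].to_numpy(),
        chain_id=df["chain"].astype(str).to_numpy(),
        charge=_opt("charge"),
        lj_sigma=_opt("lj_sigma"),
        lj_epsilon=_opt("lj_epsilon"),
    )


def _to_biotite_stack(traj: Trajectory):
    import biotite.structure as struc

    top = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coordinates.astype(np.float32)
    chain = np.where(top.chain_id == "", "A", top.chain_id)
    stack.chain_id = chain.astype("U4")
    stack.res_id = top.res_id
    stack.res_name = top.res_name.astype("U5")
    stack.atom_name = top.atom_name.astype("U6")
    stack.element = top.element.astype("U2")
    stack.hetero = np.isin(top.res_name, list(WATER_RES_NAMES))
    return stack


def write_trajectory(traj: Trajectory, path: str | Path,
                     fmt: str | None = None,
                     topology_path: str | Path | None = None) -> None:
    """Write multi-model PDB or concatenated XYZ; optional topology sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(_to_biotite_stack(traj))
        f.write(str(path))
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for t in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"frame {t}\n")
                for el, (x, y, z) in zip(traj.topology.element,
                                         traj.coordinates[t]):
                    fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if topology_path is not None:
        write_topology_tsv(traj.topology, topology_path)


def _prescan_pdb_models(lines: list[str]) -> None:
    """Verify consistent atom counts across MODEL blocks, naming offenders."""
    counts: list[tuple[int, int]] = []  # (model index, atom count)
    current: int | None = None
    n = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            current = len(counts) + 1
            n = 0
        elif rec in ("ATOM  ", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise TrajectoryParseError(
                    f"truncated ATOM record at line {lineno}"
                )
            n += 1
        elif rec.startswith("ENDMDL"):
            counts.append((current if current is not None else 1, n))
            n = 0
    if current is not None and n > 0:
        counts.append((current, n))
    if not counts and n > 0:
        counts.append((1, n))
    if counts:
        first = counts[0][1]
        for model, cnt in counts:
            if cnt != first:
                raise TrajectoryParseError(
                    f"model {model} has {cnt} atoms, expected {first}"
                )


def read_trajectory(path: str | Path, fmt: str | None = None,
                    topology_path: str | Path | None = None) -> Trajectory:
    """Read a multi-model PDB or frame-concatenated XYZ file.

    MODEL/ENDMDL blocks become frames.  If a topology TSV sidecar is given
    it overrides/augments metadata parsed from the file (and is required
    for XYZ, which carries only elements).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    sidecar = read_topology_tsv(topology_path) if topology_path else None

    if fmt == "pdb":
        text = path.read_text()
        _prescan_pdb_models(text.splitlines())
        from biotite.structure.io.pdb import PDBFile

        try:
            pdb = PDBFile.read(io.StringIO(text))
            stack = pdb.get_structure(model=None)
        except Exception as exc:  # biotite raises various types
            raise TrajectoryParseError(f"cannot parse {path}: {exc}") from exc
        import biotite.structure as struc

        if isinstance(stack, struc.AtomArray):
            coords = stack.coord[np.newaxis].astype(np.float64)
            arr = stack
        else:
            coords = stack.coord.astype(np.float64)
            arr = stack[0]
        element = np.char.upper(np.asarray(arr.element, dtype=str))
        blank = element == ""
        if blank.any():
            warnings.warn("blank element fields; inferring from atom names")
            names = np.asarray(arr.atom_name, dtype=str)
            element = element.copy()
            element[blank] = [_infer_element(nm) for nm in names[blank]]
        chain = np.asarray(arr.chain_id, dtype=str)
        chain = np.where(chain == "", "A", chain)
        top = Topology(
            atom_name=np.asarray(arr.atom_name, dtype=str),
            element=element,
            res_id=np.asarray(arr.res_id, dtype=np.int64),
            res_name=np.asarray(arr.res_name, dtype=str),
            chain_id=chain,
        )
    elif fmt == "xyz":
        coords_list = []
        elements: list[str] | None = None
        lines = path.read_text().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"{path}: expected atom count at line {i + 1}"
                ) from exc
            if i + 1 + n >= len(lines) + 1 and len(lines) < i + 2 + n:
                raise TrajectoryParseError(
                    f"{path}: truncated frame starting at line {i + 1}"
                )
            frame = np.empty((n, 3))
            frame_elements = []
            for j in range(n):
                parts = lines[i + 2 + j].split()
                if len(parts) < 4:
                    raise TrajectoryParseError(
                        f"{path}: malformed atom at line {i + 3 + j}"
                    )
                frame_elements.append(parts[0].upper())
                frame[j] = [float(p) for p in parts[1:4]]
            if elements is None:
                elements = frame_elements
            elif len(frame_elements) != len(elements):
                raise TrajectoryParseError(
                    f"{path}: inconsistent atom count in frame "
                    f"{len(coords_list) + 1}"
                )
            coords_list.append(frame)
            i += 2 + n
        if not coords_list:
            raise TrajectoryParseError(f"{path}: no frames found")
        coords = np.stack(coords_list)
        assert elements is not None
        n = len(elements)
        top = Topology(
            atom_name=np.array([f"{el}{k+1}" for k, el in enumerate(elements)]),
            element=np.array(elements),
            res_id=np.arange(1, n + 1),
            res_name=np.array(["UNK"] * n),
            chain_id=np.array(["A"] * n),
        )
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    if sidecar is not None:
        if sidecar.n_atoms != coords.shape[1]:
            raise TrajectoryParseError(
                f"topology sidecar has {sidecar.n_atoms} atoms, "
                f"file has {coords.shape[1]}"
            )
        top = sidecar
    return Trajectory(coords, top)


# --------------------------------------------------------------------------
# Superposition and RMSD
# --------------------------------------------------------------------------

def _check_fit_selection(ref_sel: np.ndarray) -> None:
    if ref_sel.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; rotation ill-defined")


def superpose(traj: Trajectory, reference_frame: np.ndarray,
              selection: AtomSelection) -> Trajectory:
    """Least-squares (Kabsch) fit of every frame onto a reference.

    The rotation/translation is determined on ``selection`` only but
    applied to all atoms.  Unweighted: every selected atom counts equally.
    """
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection")
    ref = np.asarray(reference_frame, dtype=np.float64)
    ref_sel = ref[idx]
    _check_fit_selection(ref_sel)
    ref_centroid = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_centroid

    out = np.empty_like(traj.coordinates)
    for t in range(traj.n_frames):
        frame = traj.coordinates[t]
        mob = frame[idx]
        mob_centroid = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob - mob_centroid)
        out[t] = rot.apply(frame - mob_centroid) + ref_centroid
    return Trajectory(out, traj.topology, traj.frame_times)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between two (n, 3) arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must share a shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference_frame: np.ndarray,
                selection: AtomSelection) -> np.ndarray:
    """Per-frame RMSD (Angstrom) on ``selection`` after fitting on it."""
    fitted = superpose(traj, reference_frame, selection)
    idx = selection.indices
    ref = np.asarray(reference_frame, dtype=np.float64)[idx]
    diff = fitted.coordinates[:, idx, :] - ref
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


def write_rmsd_series(times_ps: np.ndarray, values: np.ndarray,
                      path: str | Path) -> None:
    pd.DataFrame({"time_ps": times_ps, "rmsd_A": values}).to_csv(
        path, sep="\t", index=False
    )
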