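"""Geometric hydrogen-bond and water-bridge detection on structures.

A hydrogen bond is a donor/acceptor N or O pair within a cutoff distance
(default 3.5 A) whose D-H...A arrangement deviates from linearity by less
than an angular cutoff (default 50 deg); the angle vertex is the hydrogen,
so the criterion is angle(D-H-A) > 130 deg.  A water bridge is a single
water simultaneously hydrogen-bonded to two distinct non-water residues.
Detection is intended for representative (centroid) structures, not for
occupancy statistics over trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_io import Topology, WATER_RES_NAMES, DNA_RES_NAMES

__all__ = [
    "HBond",
    "WaterBridge",
    "detect_hbonds",
    "detect_water_bridges",
    "classify_dna_contact",
    "contact_set",
    "build_network",
    "compare_networks",
    "hbonds_to_frame",
]

ResidueKey = tuple[str, int]

_COVALENT_H_CUTOFF = 1.25  # A: an H this close to N/O is bonded to it


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    deviation_deg: float
    donor_res: ResidueKey
    acceptor_res: ResidueKey
    category: str  # protein-dna | protein-protein | dna-dna | water


@dataclass(frozen=True)
class WaterBridge:
    res_a: ResidueKey
    water: ResidueKey
    res_b: ResidueKey
    leg_a: HBond
    leg_b: HBond


def _residue_kind(res_name: str, element: str) -> str:
    if res_name in WATER_RES_NAMES:
        return "water"
    if res_name in DNA_RES_NAMES:
        return "dna"
    if element in {"NA", "K", "CL", "MG", "ZN", "CA", "MN", "FE"} \
            and res_name not in {"GLY", "SER", "ALA"}:
        return "ion"
    return "protein"


def _category(kind_a: str, kind_b: str) -> str:
    if "water" in (kind_a, kind_b):
        return "water"
    return "-".join(sorted((kind_a, kind_b)))


def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    cutoff: float = 3.5,
    max_deviation: float = 50.0,
    include_sulfur: bool = False,
) -> list[HBond]:
    """All donor-acceptor pairs meeting the distance/linearity criterion.

    Donors are N/O atoms carrying at least one covalent hydrogen (H within
    1.25 A); acceptors are all N/O atoms.  Pairs within the same residue
    are excluded.  Requires an all-hydrogen structure.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] != topology.n_atoms:
        raise ValueError("coords must be a single (n_atoms, 3) frame")
    el = topology.element
    h_idx = np.flatnonzero(el == "H")
    if len(h_idx) == 0:
        raise ValueError(
            "structure contains no hydrogens; hydrogen-bond detection "
            "requires a protonated (all-hydrogen) input"
        )
    polar = {"N", "O"} | ({"S"} if include_sulfur else set())
    heavy_idx = np.flatnonzero(np.isin(el, list(polar)))
    if len(heavy_idx) == 0:
        return []

    # assign each hydrogen to its covalent heavy partner (nearest N/O)
    heavy_tree = cKDTree(coords[heavy_idx])
    dists, nearest = heavy_tree.query(coords[h_idx],
                                      distance_upper_bound=_COVALENT_H_CUTOFF)
    donor_hydrogens: dict[int, list[int]] = {}
    for h, d, j in zip(h_idx, dists, nearest):
        if np.isfinite(d):
            donor_hydrogens.setdefault(int(heavy_idx[j]), []).append(int(h))

    res_key = [(str(c), int(r))
               for c, r in zip(topology.chain_id, topology.res_id)]
    kinds = [_residue_kind(rn, e)
             for rn, e in zip(topology.res_name, topology.element)]

    pairs = cKDTree(coords[heavy_idx]).query_pairs(cutoff, output_type="ndarray")
    bonds: list[HBond] = []
    min_angle = 180.0 - max_deviation
    for ia, ib in pairs:
        a, c = int(heavy_idx[ia]), int(heavy_idx[ib])
        if res_key[a] == res_key[c]:
            continue
        for donor, acceptor in ((a, c), (c, a)):
            hydrogens = donor_hydrogens.get(donor)
            if not hydrogens:
                continue
            dist = float(np.linalg.norm(coords[donor] - coords[acceptor]))
            best: tuple[float, int] | None = None
            for h in hydrogens:
                v1 = coords[donor] - coords[h]
                v2 = coords[acceptor] - coords[h]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if ang > min_angle and (best is None or ang > best[0]):
                    best = (ang, h)
            if best is None:
                continue
            bonds.append(HBond(
                donor=donor, hydrogen=best[1], acceptor=acceptor,
                distance=dist, deviation_deg=180.0 - best[0],
                donor_res=res_key[donor], acceptor_res=res_key[acceptor],
                category=_category(kinds[donor], kinds[acceptor]),
            ))
    bonds.sort(key=lambda hb: (hb.donor, hb.acceptor))
    return bonds


def detect_water_bridges(topology: Topology,
                         hbonds: list[HBond]) -> list[WaterBridge]:
    """Single-water bridges: one water H-bonded to two non-water residues.

    Multi-water chains are not traversed; a water bonded to two atoms of
    the same residue does not form a bridge.
    """
    water_mask = topology.is_water()
    water_links: dict[ResidueKey, list[tuple[ResidueKey, HBond]]] = {}
    for hb in hbonds:
        d_water = bool(water_mask[hb.donor])
        a_water = bool(water_mask[hb.acceptor])
        if d_water == a_water:  # water-water or solute-solute
            continue
        if d_water:
            water_links.setdefault(hb.donor_res, []).append(
                (hb.acceptor_res, hb))
        else:
            water_links.setdefault(hb.acceptor_res, []).append(
                (hb.donor_res, hb))
    bridges: list[WaterBridge] = []
    for water, links in sorted(water_links.items()):
        partners = sorted({res for res, _ in links})
        for i in range(len(partners)):
            for j in range(i + 1, len(partners)):
                ra, rb = partners[i], partners[j]
                leg_a = next(hb for res, hb in links if res == ra)
                leg_b = next(hb for res, hb in links if res == rb)
                bridges.append(WaterBridge(ra, water, rb, leg_a, leg_b))
    return bridges


# --------------------------------------------------------------------------
# DNA groove classification
# --------------------------------------------------------------------------

_PHOSPHATE_ATOMS = {"P", "OP1", "O1P", "OP2", "O2P", "O3'", "O5'"}
_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}

# Base-edge tables per base type.  Watson-Crick edge atoms that face
# neither groove squarely are assigned by convention: purine N1 with the
# minor-groove C2 side, pyrimidine N3 with the major-groove C4 side.
_PURINE_MAJOR = {"N7", "O6", "N6", "C5", "C6", "C8", "H8", "H61", "H62"}
_PURINE_MINOR = {"N3", "N2", "C2", "C4", "N9", "N1", "H2", "H21", "H22",
                 "H1"}
_PYRIMIDINE_MAJOR = {"O4", "N4", "C4", "C5", "C6", "C7", "C5M", "N3",
                     "H41", "H42", "H5", "H6", "H3", "H71", "H72", "H73"}
_PYRIMIDINE_MINOR = {"O2", "C2", "N1"}

_PURINES = {"DA", "DG", "A", "G", "DA5", "DG5", "DA3", "DG3"}
_PYRIMIDINES = {"DT", "DC", "T", "C", "U", "DU", "DT5", "DC5", "DT3", "DC3"}


def classify_dna_contact(atom_name: str, res_name: str) -> str:
    """major_groove | minor_groove | phosphate | unclassified."""
    if atom_name in _PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in _SUGAR_ATOMS:
        return "minor_groove"  # sugar face lines the minor groove
    if res_name in _PURINES:
        if atom_name in _PURINE_MAJOR:
            return "major_groove"
        if atom_name in _PURINE_MINOR:
            return "minor_groove"
    elif res_name in _PYRIMIDINES:
        if atom_name in _PYRIMIDINE_MAJOR:
            return "major_groove"
        if atom_name in _PYRIMIDINE_MINOR:
            return "minor_groove"
    warnings.warn(
        f"cannot classify DNA atom {atom_name!r} of {res_name!r}"
    )
    return "unclassified"


# --------------------------------------------------------------------------
# Networks and comparison
# --------------------------------------------------------------------------

def contact_set(topology: Topology, hbonds: list[HBond],
                bridges: list[WaterBridge]) -> set:
    """Canonical residue-level edge set for exact round-trip comparison.

    Direct solute-solute bonds become ``("direct", {resA, resB})``;
    bridges become ``("water", {resA, resB}, water_res)``.  Bridge legs
    (bonds touching water) are not counted as direct edges.
    """
    out: set = set()
    for hb in hbonds:
        if hb.category == "water":
            continue
        out.add(("direct", frozenset({hb.donor_res, hb.acceptor_res})))
    for br in bridges:
        out.add(("water", frozenset({br.res_a, br.res_b}), br.water))
    return out


def build_network(topology: Topology, hbonds: list[HBond],
                  bridges: list[WaterBridge]):
    """networkx MultiGraph: residue nodes, typed direct/water edges.

    DNA-touching edges carry a ``groove_class`` attribute derived from the
    DNA-side contact atom.
    """
    import networkx as nx

    g = nx.MultiGraph()
    dna_mask = topology.is_dna()

    def _label(key: ResidueKey) -> str:
        idx = topology.residue_atoms(*key)
        rn = topology.res_name[idx[0]] if len(idx) else "?"
        return f"{key[0]}:{rn}{key[1]}"

    for hb in hbonds:
        if hb.category == "water":
            continue
        groove = None
        for atom in (hb.donor, hb.acceptor):
            if dna_mask[atom]:
                groove = classify_dna_contact(
                    topology.atom_name[atom], topology.res_name[atom])
        g.add_edge(
            _label(hb.donor_res), _label(hb.acceptor_res), type="direct",
            distance=hb.distance, deviation_deg=hb.deviation_deg,
            groove_class=groove,
        )
    for br in bridges:
        grooves = []
        for leg in (br.leg_a, br.leg_b):
            for atom in (leg.donor, leg.acceptor):
                if dna_mask[atom]:
                    grooves.append(classify_dna_contact(
                        topology.atom_name[atom], topology.res_name[atom]))
        g.add_edge(
            _label(br.res_a), _label(br.res_b), type="water",
            water=_label(br.water),
            groove_class=grooves[0] if grooves else None,
        )
    return g


def compare_networks(topology_a: Topology, contacts_a: set,
                     topology_b: Topology, contacts_b: set) -> dict:
    """Edge diff between two contact sets sharing residue numbering.

    Water-bridge edges are compared by residue pair (the bridging water's
    identity is incidental).  Residue pairs whose link changes between
    direct and water-mediated are flagged as transitions -- the signature
    change the 248 contact undergoes with temperature.
    """

    def _by_pair(contacts: set) -> dict[frozenset, set[str]]:
        out: dict[frozenset, set[str]] = {}
        for edge in contacts:
            kind, pair = edge[0], edge[1]
            out.setdefault(pair, set()).add(kind)
        return out

    a, b = _by_pair(contacts_a), _by_pair(contacts_b)
    gained = [(pair, sorted(b[pair])) for pair in b if pair not in a]
    lost = [(pair, sorted(a[pair])) for pair in a if pair not in b]
    retained = [pair for pair in a if pair in b]
    transitions = [
        (pair, sorted(a[pair]), sorted(b[pair]))
        for pair in retained if a[pair] != b[pair]
    ]
    return {
        "gained": sorted(gained, key=str),
        "lost": sorted(lost, key=str),
        "retained": sorted(retained, key=str),
        "transitions": sorted(transitions, key=str),
    }


def hbonds_to_frame(topology: Topology, hbonds: list[HBond],
                    bridges: list[WaterBridge]) -> pd.DataFrame:
    """Edge-list table (TSV-ready) for direct bonds and bridges."""
    dna_mask = topology.is_dna()
    rows = []
    for hb in hbonds:
        if hb.category == "water":
            continue
        groove = ""
        for atom in (hb.donor, hb.acceptor):
            if dna_mask[atom]:
                groove = classify_dna_contact(
                    topology.atom_name[atom], topology.res_name[atom])
        rows.append({
            "res_a": f"{hb.donor_res[0]}:{hb.donor_res[1]}",
            "res_b": f"{hb.acceptor_res[0]}:{hb.acceptor_res[1]}",
            "type": "direct", "water_id": "",
            "distance_A": round(hb.distance, 3),
            "deviation_deg": round(hb.deviation_deg, 2),
            "groove_class": groove,
        })
    for br in bridges:
        grooves = [
            classify_dna_contact(topology.atom_name[atom],
                                 topology.res_name[atom])
            for leg in (br.leg_a, br.leg_b)
            for atom in (leg.donor, leg.acceptor) if dna_mask[atom]
        ]
        rows.append({
            "res_a": f"{br.res_a[0]}:{br.res_a[1]}",
            "res_b": f"{br.res_b[0]}:{br.res_b[1]}",
            "type": "water",
            "water_id": f"{br.water[0]}:{br.water[1]}",
            "distance_A": round(max(br.leg_a.distance,
                                    br.leg_b.distance), 3),
            "deviation_deg": round(max(br.leg_a.deviation_deg,
                                       br.leg_b.deviation_deg), 2),
            "groove_class": grooves[0] if grooves else "",
        })
    return pd.DataFrame(
        rows, columns=["res_a", "res_b", "type", "water_id", "distance_A",
                       "deviation_deg", "groove_class"])
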