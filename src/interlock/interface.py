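"""Cross-chain interface characterisation.

Distance-threshold analyses of a two-chain complex: interface residues,
hydrogen bonds and their ensemble occupancy, per-frame minimum-distance
series, additive pseudoenergies (hydrogen-bond, electrostatic, van der
Waals terms counted at distance thresholds), and hotspot residues.

The pseudoenergy constants are calibrated stand-ins, not physics: each
interaction type contributes a fixed increment per counted pair, so totals
scale with interface size and the per-residue normalized energy is
comparable across complexes.  Every constant is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Ensemble, Residue, ResidueKey, Snapshot

__all__ = [
    "HBondCriteria",
    "EnergyParams",
    "EnergyBreakdown",
    "OccupancyRecord",
    "HBond",
    "interface_residues",
    "detect_hbonds",
    "hbond_occupancy",
    "min_distance_series",
    "interface_energies",
    "energy_time_series",
    "hotspots",
]


class InterfaceError(ValueError):
    pass


# donor/acceptor heavy atoms by residue type; backbone N donates (except
# proline) and backbone O accepts for every residue type
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}
SIDECHAIN_ACCEPTORS = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

# formal charges: carboxylates -1, Lys/Arg terminal amines +1, His neutral
CHARGED_GROUPS = {
    "ASP": (("OD1", "OD2"), -1),
    "GLU": (("OE1", "OE2"), -1),
    "LYS": (("NZ",), +1),
    "ARG": (("NH1", "NH2", "NE"), +1),
}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    Donor-acceptor heavy-atom distance <= ``da_cutoff`` Å; when explicit
    hydrogens are present, additionally require a hydrogen-donor-acceptor
    angle <= ``angle_cutoff`` degrees for some hydrogen bound to the donor.
    """

    da_cutoff: float = 3.5
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise InterfaceError("H-bond cutoffs must be positive")


@dataclass(frozen=True)
class EnergyParams:
    """Distance thresholds and per-interaction pseudoenergy increments."""

    e_hb: float = -1.5  # kcal/mol per cross-chain H-bond
    e_elec: float = 1.0  # kcal/mol magnitude per charged-group pair
    elec_cutoff: float = 6.0  # Å between charged-group centroids
    e_vdw: float = -0.2  # kcal/mol per heavy-atom contact pair
    vdw_lo: float = 3.0  # Å
    vdw_hi: float = 5.0  # Å
    interface_cutoff: float = 5.0  # Å heavy-atom interface definition
    hotspot_threshold: float = -2.0  # kcal/mol per-residue energy
    hbond: HBondCriteria = field(default_factory=HBondCriteria)


@dataclass
class EnergyBreakdown:
    hbond_energy: float
    electrostatic_energy: float
    vdw_energy: float
    total_stabilizing: float
    n_interface_residues: int
    normalized_per_residue: float  # nan when the interface is empty
    per_residue: dict[ResidueKey, float] = field(default_factory=dict)


@dataclass(frozen=True)
class HBond:
    donor_residue: ResidueKey
    acceptor_residue: ResidueKey
    donor_atom: str
    acceptor_atom: str
    distance: float


@dataclass
class OccupancyRecord:
    donor_residue: ResidueKey
    acceptor_residue: ResidueKey
    occupancy: float  # fraction of frames with the bond present
    stable: bool  # strictly > 0.5


def _chain_heavy(snapshot: Snapshot, chain_id: str):
    residues = snapshot.chain(chain_id)
    coords, owner = [], []
    for res in residues:
        hc = res.heavy_coords()
        coords.append(hc)
        owner.extend([res.key] * len(hc))
    return residues, np.concatenate(coords), owner


def interface_residues(
    snapshot: Snapshot,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
) -> list[ResidueKey]:
    """Residues of either chain with a heavy atom within ``cutoff`` of the
    other chain.  Symmetric in the chain arguments; sorted by residue key."""
    _, xa, oa = _chain_heavy(snapshot, chain_a)
    _, xb, ob = _chain_heavy(snapshot, chain_b)
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), cutoff)
    out: set[ResidueKey] = set()
    for ia, hits in enumerate(pairs):
        if hits:
            out.add(oa[ia])
            out.update(ob[ib] for ib in hits)
    return sorted(out)


def _donor_acceptor_atoms(res: Residue):
    donors, acceptors = [], []
    for atom in res.heavy_atoms():
        if atom.name == "N" and res.name != "PRO":
            donors.append(atom)
        elif atom.name == "O" or atom.name == "OXT":
            acceptors.append(atom)
        elif atom.name in SIDECHAIN_DONORS.get(res.name, ()):
            donors.append(atom)
        if atom.name in SIDECHAIN_ACCEPTORS.get(res.name, ()):
            acceptors.append(atom)
    return donors, acceptors


def _donor_hydrogens(res: Residue, donor_pos: np.ndarray) -> list[np.ndarray]:
    out = []
    for atom in res.atoms:
        if atom.element == "H" and np.linalg.norm(atom.position - donor_pos) <= 1.25:
            out.append(atom.position)
    return out


def detect_hbonds(
    snapshot: Snapshot,
    criteria: Optional[HBondCriteria] = None,
    cross_chain_only: bool = True,
) -> list[HBond]:
    """Hydrogen bonds by donor-acceptor geometry.

    Donor/acceptor roles come from standard per-residue N/O typing.  The
    angle criterion applies only when the donor carries explicit hydrogens;
    protein-only heavy-atom ensembles are judged on distance alone.
    """
    criteria = criteria or HBondCriteria()
    donors: list[tuple[Residue, np.ndarray, str]] = []
    acceptors: list[tuple[Residue, np.ndarray, str]] = []
    for res in snapshot:
        d, a = _donor_acceptor_atoms(res)
        donors.extend((res, atom.position, atom.name) for atom in d)
        acceptors.extend((res, atom.position, atom.name) for atom in a)
    if not donors or not acceptors:
        return []
    tree = cKDTree(np.array([p for _, p, _ in acceptors]))
    bonds: list[HBond] = []
    for res_d, pos_d, name_d in donors:
        for ia in tree.query_ball_point(pos_d, criteria.da_cutoff):
            res_a, pos_a, name_a = acceptors[ia]
            if res_a.key == res_d.key:
                continue
            if cross_chain_only and res_a.chain_id == res_d.chain_id:
                continue
            hydrogens = _donor_hydrogens(res_d, pos_d)
            if hydrogens:
                ok = False
                for h in hydrogens:
                    v1 = h - pos_d
                    v2 = pos_a - pos_d
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= criteria.angle_cutoff:
                        ok = True
                        break
                if not ok:
                    continue
            bonds.append(
                HBond(
                    donor_residue=res_d.key,
                    acceptor_residue=res_a.key,
                    donor_atom=name_d,
                    acceptor_atom=name_a,
                    distance=float(np.linalg.norm(pos_a - pos_d)),
                )
            )
    return bonds


def hbond_occupancy(
    ensemble: Ensemble,
    criteria: Optional[HBondCriteria] = None,
    cross_chain_only: bool = True,
) -> list[OccupancyRecord]:
    """Per residue pair, the fraction of frames in which it is H-bonded.

    A pair is 'stable' when its occupancy is strictly greater than 0.5.
    Pairs never bonded in any frame are not reported.
    """
    criteria = criteria or HBondCriteria()
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for snap in ensemble:
        seen = set()
        for bond in detect_hbonds(snap, criteria, cross_chain_only):
            seen.add((bond.donor_residue, bond.acceptor_residue))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(ensemble)
    return [
        OccupancyRecord(
            donor_residue=d, acceptor_residue=a, occupancy=c / n, stable=c / n > 0.5
        )
        for (d, a), c in sorted(counts.items())
    ]


def min_distance_series(
    ensemble: Ensemble, pair: tuple[ResidueKey, ResidueKey]
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between two residues, Å."""
    key_a, key_b = tuple(pair[0]), tuple(pair[1])
    out = []
    for snap in ensemble:
        xa = snap.residue(key_a).heavy_coords()
        xb = snap.residue(key_b).heavy_coords()
        d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
        out.append(float(np.sqrt(d2.min())))
    return np.asarray(out)


def _charged_groups(residues: Sequence[Residue]):
    groups = []
    for res in residues:
        entry = CHARGED_GROUPS.get(res.name)
        if entry is None:
            continue
        names, charge = entry
        pos = [a.position for a in res.atoms if a.name in names]
        if pos:
            groups.append((res.key, np.mean(pos, axis=0), charge))
    return groups


def interface_energies(
    snapshot: Snapshot,
    chain_a: str,
    chain_b: str,
    params: Optional[EnergyParams] = None,
) -> EnergyBreakdown:
    """Additive distance-threshold pseudoenergies of the cross-chain interface.

    hbond: count of cross-chain hydrogen bonds x e_hb.
    electrostatic: charged-group centroid pairs within elec_cutoff; opposite
    formal charges contribute -e_elec (attractive), like charges +e_elec.
    vdw: cross-chain heavy-atom pairs within [vdw_lo, vdw_hi] x e_vdw.
    Every pairwise term is attributed half to each participating residue, so
    the per-residue energies sum exactly to the total.
    """
    params = params or EnergyParams()
    iface = interface_residues(snapshot, chain_a, chain_b, params.interface_cutoff)
    per_res: dict[ResidueKey, float] = {k: 0.0 for k in iface}

    def credit(key: ResidueKey, amount: float) -> None:
        per_res[key] = per_res.get(key, 0.0) + amount

    # hydrogen bonds
    hb_energy = 0.0
    for bond in detect_hbonds(snapshot, params.hbond, cross_chain_only=True):
        da, db = bond.donor_residue, bond.acceptor_residue
        if {da[0], db[0]} != {chain_a, chain_b}:
            continue
        hb_energy += params.e_hb
        credit(da, params.e_hb / 2)
        credit(db, params.e_hb / 2)

    # electrostatics between formal-charge groups
    ga = _charged_groups(snapshot.chain(chain_a))
    gb = _charged_groups(snapshot.chain(chain_b))
    elec_energy = 0.0
    for key_a, pos_a, qa in ga:
        for key_b, pos_b, qb in gb:
            if np.linalg.norm(pos_a - pos_b) <= params.elec_cutoff:
                term = params.e_elec if qa * qb > 0 else -params.e_elec
                elec_energy += term
                credit(key_a, term / 2)
                credit(key_b, term / 2)

    # van der Waals contact count
    res_a, xa, oa = _chain_heavy(snapshot, chain_a)
    res_b, xb, ob = _chain_heavy(snapshot, chain_b)
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), params.vdw_hi)
    vdw_energy = 0.0
    for ia, hits in enumerate(pairs):
        for ib in hits:
            d = np.linalg.norm(xa[ia] - xb[ib])
            if params.vdw_lo <= d <= params.vdw_hi:
                vdw_energy += params.e_vdw
                credit(oa[ia], params.e_vdw / 2)
                credit(ob[ib], params.e_vdw / 2)

    total = hb_energy + elec_energy + vdw_energy
    n_iface = len(iface)
    return EnergyBreakdown(
        hbond_energy=hb_energy,
        electrostatic_energy=elec_energy,
        vdw_energy=vdw_energy,
        total_stabilizing=total,
        n_interface_residues=n_iface,
        normalized_per_residue=(total / n_iface) if n_iface else float("nan"),
        per_residue=per_res,
    )


def energy_time_series(
    ensemble: Ensemble,
    chain_a: str,
    chain_b: str,
    params: Optional[EnergyParams] = None,
    stride: int = 1,
) -> list[tuple[int, EnergyBreakdown]]:
    """interface_energies on every ``stride``-th frame; (frame_index, breakdown)."""
    if stride < 1:
        raise InterfaceError("stride must be >= 1")
    params = params or EnergyParams()
    return [
        (k, interface_energies(ensemble[k], chain_a, chain_b, params))
        for k in range(0, len(ensemble), stride)
    ]


def hotspots(
    snapshot: Snapshot,
    chain_a: str,
    chain_b: str,
    params: Optional[EnergyParams] = None,
) -> list[ResidueKey]:
    """Interface residues whose attributed stabilizing energy is at or below
    the hotspot threshold (more negative = stronger contributor)."""
    params = params or EnergyParams()
    breakdown = interface_energies(snapshot, chain_a, chain_b, params)
    return sorted(
        k for k, e in breakdown.per_residue.items() if e <= params.hotspot_threshold
    )
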