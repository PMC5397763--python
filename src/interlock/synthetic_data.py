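"""Synthetic inputs with known ground truth.

Two generators drive the test pipeline end to end without any downloads:

* :func:`generate_coupled_msa` builds a pair of per-domain alignments whose
  columns are i.i.d. draws from per-column profiles, except for planted
  column pairs where the letter at one column determines (with a tunable
  probability) the letter at the other through a fixed bijection.  The
  planted pairs are the ground truth a co-evolution analysis should find.

* :func:`generate_toy_complex` lays out a two-chain Cα-trace complex with
  simplified side-chain pseudo-atoms in which designated cross-chain
  residue pairs are in contact (optionally with donor/acceptor geometry)
  and a designated intra-chain residue chain forms consecutive contacts —
  the ground-truth communication path.  :func:`generate_ensemble` perturbs
  the complex into a frame ensemble with Gaussian noise and an optional
  contiguous block of frames with the interface deliberately separated.

Pseudo-residues carry a Cα plus one to three side-chain pseudo-atoms: that
is sufficient for every distance-threshold analysis here, while full
rotamer realism is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .coevolution import AMINO_ACIDS
from .structio import Ensemble, Msa, Residue, Snapshot, make_atom

__all__ = [
    "CouplingSpec",
    "MsaGroundTruth",
    "ToyComplexSpec",
    "GeometryError",
    "generate_coupled_msa",
    "generate_toy_complex",
    "generate_ensemble",
    "write_ground_truth",
]

CA_STEP = 3.8  # consecutive Cα spacing, Å
CONTACT_GAP = 4.0  # tip-to-tip distance of a planted cross-chain contact, Å
HBOND_GAP = 3.0  # donor-acceptor distance of a planted hydrogen bond, Å
CHAIN_SEPARATION = 12.0  # Cα-plane separation of the two chains, Å
PATH_STEP = 4.2  # Cα spacing of consecutive planted path anchors, Å
BROKEN_SHIFT = 20.0  # rigid displacement of the separated-interface frames, Å


class GeometryError(ValueError):
    """The requested toy-complex geometry could not be realised."""


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coupled MSA


def _default_bijection() -> dict[str, str]:
    """Fixed cyclic shift of the amino-acid alphabet."""
    return {a: AMINO_ACIDS[(k + 7) % len(AMINO_ACIDS)] for k, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class CouplingSpec:
    """A planted dependency between two concatenated-alignment columns.

    With probability ``strength`` a row's letter at column ``j`` is
    ``bijection[letter at column i]``; otherwise it is an independent draw
    from column j's profile.  Columns are 1-based over the concatenated
    (domain A then domain B) range.
    """

    column_pair: tuple[int, int]
    strength: float = 1.0
    bijection: dict[str, str] = field(default_factory=_default_bijection)

    def __post_init__(self) -> None:
        i, j = self.column_pair
        if i == j:
            raise SyntheticError("coupled columns must differ")
        if not 0.0 <= self.strength <= 1.0:
            raise SyntheticError("coupling strength must be in [0, 1]")
        if sorted(self.bijection) != sorted(set(self.bijection.values())):
            raise SyntheticError("bijection must be a permutation of the alphabet")


@dataclass
class MsaGroundTruth:
    couplings: list[CouplingSpec]
    length_a: int
    length_b: int
    gap_fraction: float
    seed: int
    profiles: np.ndarray  # (length_a + length_b, 20)


def generate_coupled_msa(
    n_seqs: int,
    length_a: int,
    length_b: int,
    couplings: Sequence[CouplingSpec] = (),
    gap_fraction: float = 0.0,
    seed: int = 0,
    concentration: float = 1.0,
    profile_overrides: Optional[dict[int, Sequence[float]]] = None,
) -> tuple[Msa, Msa, MsaGroundTruth]:
    """Two per-domain alignments with planted column couplings.

    Column profiles are drawn once per column from a symmetric Dirichlet
    with the given concentration; rows are i.i.d. draws from the profiles;
    couplings then overwrite the dependent column; finally gaps are placed
    i.i.d. at ``gap_fraction`` per cell.  ``profile_overrides`` pins chosen
    columns (1-based, concatenated) to explicit profiles.  Both alignments
    share the same ordered ids and everything is reproducible from ``seed``.
    """
    if n_seqs < 2:
        raise SyntheticError("need at least 2 sequences")
    if not 0.0 <= gap_fraction < 1.0:
        raise SyntheticError("gap_fraction must be in [0, 1)")
    n_cols = length_a + length_b
    for c in couplings:
        for col in c.column_pair:
            if not 1 <= col <= n_cols:
                raise SyntheticError(f"coupled column {col} outside 1..{n_cols}")
    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    profiles = rng.dirichlet(np.full(n_aa, concentration), size=n_cols)
    if profile_overrides:
        for col, prof in profile_overrides.items():
            p = np.asarray(prof, dtype=float)
            if p.shape != (n_aa,) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise SyntheticError(f"profile override for column {col} must sum to 1")
            profiles[col - 1] = p
    # i.i.d. draws per column
    codes = np.empty((n_seqs, n_cols), dtype=np.int64)
    for c in range(n_cols):
        codes[:, c] = rng.choice(n_aa, size=n_seqs, p=profiles[c])
    # planted couplings: j follows bijection(i) with prob = strength
    aa_index = {a: k for k, a in enumerate(AMINO_ACIDS)}
    for spec in couplings:
        i, j = spec.column_pair
        perm = np.array([aa_index[spec.bijection[a]] for a in AMINO_ACIDS])
        follow = rng.random(n_seqs) < spec.strength
        codes[follow, j - 1] = perm[codes[follow, i - 1]]
    letters = np.array(list(AMINO_ACIDS))
    rows = letters[codes]
    if gap_fraction > 0:
        gaps = rng.random((n_seqs, n_cols)) < gap_fraction
        rows[gaps] = "-"
    ids = [f"seq{k + 1:04d}" for k in range(n_seqs)]
    rows_joined = ["".join(r) for r in rows]
    msa_a = Msa(ids=ids, rows=[r[:length_a] for r in rows_joined])
    msa_b = Msa(ids=list(ids), rows=[r[length_a:] for r in rows_joined])
    truth = MsaGroundTruth(
        couplings=list(couplings),
        length_a=length_a,
        length_b=length_b,
        gap_fraction=gap_fraction,
        seed=seed,
        profiles=profiles,
    )
    return msa_a, msa_b, truth


def write_ground_truth(truth: MsaGroundTruth, path: str | Path) -> None:
    """Plain TSV sidecar listing the planted couplings."""
    lines = ["column_i\tcolumn_j\tstrength"]
    for c in truth.couplings:
        lines.append(f"{c.column_pair[0]}\t{c.column_pair[1]}\t{c.strength}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# toy two-chain complex


@dataclass
class ToyComplexSpec:
    """Blueprint of a two-chain complex with known contacts and path.

    ``contact_pairs`` are (residue in chain A, residue in chain B) pairs to
    be placed within interface distance; ``hbond_pairs`` (a subset) get
    donor/acceptor geometry; ``path_chain`` is an ordered residue list of
    chain A placed as a chain of mutual contacts (the planted communication
    path).  Feasibility constraints: contact residues must be separated by
    at least 3 in sequence within each chain (non-contact cross-chain pairs
    must stay at least 8 Å apart), path residues must be strictly
    increasing with gaps of at least 3 (closer pairs would be discarded as
    covalent neighbours by the network stage), and path residues must not
    double as contact residues.
    """

    n_res_a: int
    n_res_b: int
    contact_pairs: list[tuple[int, int]] = field(default_factory=list)
    hbond_pairs: list[tuple[int, int]] = field(default_factory=list)
    path_chain: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.contact_pairs:
            if not (1 <= a <= self.n_res_a and 1 <= b <= self.n_res_b):
                raise SyntheticError(f"contact pair ({a},{b}) outside chain ranges")
        if not set(map(tuple, self.hbond_pairs)) <= set(map(tuple, self.contact_pairs)):
            raise SyntheticError("hbond_pairs must be a subset of contact_pairs")
        by_b = sorted(self.contact_pairs, key=lambda p: p[1])
        a_order = [p[0] for p in by_b]
        if a_order != sorted(a_order):
            raise SyntheticError("contact pairs must not cross (a and b orders must agree)")
        for (a0, b0), (a1, b1) in zip(by_b, by_b[1:]):
            if a1 - a0 < 3 or b1 - b0 < 3:
                raise SyntheticError("contact residues must be >= 3 apart in sequence")
        if self.path_chain:
            for p in self.path_chain:
                if not 1 <= p <= self.n_res_a:
                    raise SyntheticError(f"path residue {p} outside chain A")
            if any(q - p < 3 for p, q in zip(self.path_chain, self.path_chain[1:])):
                raise SyntheticError("path residues must increase with gaps >= 3")
            contacts_a = {a for a, _ in self.contact_pairs}
            if contacts_a & set(self.path_chain):
                raise SyntheticError("path residues cannot double as contact residues")


def _arc_points(p: np.ndarray, q: np.ndarray, n_seg: int, step: float, bulge: np.ndarray) -> list[np.ndarray]:
    """``n_seg - 1`` intermediate points from p to q in ``n_seg`` equal
    chords of length ``step``, on a circular arc bulging toward ``bulge``."""
    d = float(np.linalg.norm(q - p))
    if n_seg * step < d - 1e-9:
        raise GeometryError(f"cannot span {d:.2f} Å with {n_seg} steps of {step} Å")
    u = (q - p) / d
    w = bulge - (bulge @ u) * u
    wn = float(np.linalg.norm(w))
    if wn < 1e-9:
        raise GeometryError("bulge direction parallel to the chord")
    w = w / wn
    if abs(n_seg * step - d) < 1e-9:  # collinear
        return [p + u * step * t for t in range(1, n_seg)]

    def gap(phi: float) -> float:
        return step * math.sin(n_seg * phi / 2.0) / math.sin(phi / 2.0) - d

    hi = 2.0 * math.pi / n_seg - 1e-9
    phi = brentq(gap, 1e-9, hi)
    radius = step / (2.0 * math.sin(phi / 2.0))
    total = n_seg * phi
    # local frame: p at origin, q at (d, 0); search centre sign / direction
    # giving the requested sweep with the apex on the bulge (+w) side
    half = math.sqrt(max(radius**2 - (d / 2.0) ** 2, 0.0))
    for yc in (-half, half):
        centre = np.array([d / 2.0, yc])
        ang_p = math.atan2(-yc, -d / 2.0)
        ang_q = math.atan2(-yc, d / 2.0)
        for direction in (1.0, -1.0):
            sweep = (direction * (ang_q - ang_p)) % (2.0 * math.pi)
            if abs(sweep - total) > 1e-6:
                continue
            mid = centre + radius * np.array(
                [
                    math.cos(ang_p + direction * total / 2.0),
                    math.sin(ang_p + direction * total / 2.0),
                ]
            )
            if mid[1] <= 0:  # apex must be on the bulge side
                continue
            pts = []
            for t in range(1, n_seg):
                a = ang_p + direction * phi * t
                local = centre + radius * np.array([math.cos(a), math.sin(a)])
                pts.append(p + u * local[0] + w * local[1])
            return pts
    raise GeometryError("no arc orientation matches the required sweep")


def _route_chain(
    n_res: int,
    anchors: dict[int, np.ndarray],
    head_dir: np.ndarray,
    tail_dir: np.ndarray,
    bulges: Sequence[np.ndarray],
) -> np.ndarray:
    """Cα positions for residues 1..n with 3.8 Å steps through the anchors."""
    pos = np.zeros((n_res, 3))
    if not anchors:
        for k in range(n_res):
            pos[k] = (k * CA_STEP, 0.0, 0.0)
        return pos
    items = sorted(anchors.items())
    for idx, (res, p) in enumerate(items):
        pos[res - 1] = p
    first_res, first_p = items[0]
    for m in range(1, first_res):
        pos[first_res - 1 - m] = first_p + head_dir * CA_STEP * m
    for t, ((r0, p0), (r1, p1)) in enumerate(zip(items, items[1:])):
        n_seg = r1 - r0
        bulge = bulges[t % len(bulges)]
        for k, point in enumerate(_arc_points(p0, p1, n_seg, CA_STEP, bulge)):
            pos[r0 + k] = point
    last_res, last_p = items[-1]
    for m in range(1, n_res - last_res + 1):
        pos[last_res - 1 + m] = last_p + tail_dir * CA_STEP * m
    return pos


def _make_residue(chain_id: str, number: int, kind: str, ca: np.ndarray, up: float) -> Residue:
    """Pseudo-residue at Cα position ``ca``; ``up``=+1 extends side chains
    toward +z (chain A interface side), -1 toward -z (chain B)."""
    z = np.array([0.0, 0.0, 1.0])

    def at(offset: float):
        return ca + z * (up * offset)

    if kind == "plain":
        atoms = [make_atom("CA", "C", ca), make_atom("CB", "C", at(-1.5))]
        name = "ALA"
    elif kind == "contact":
        atoms = [
            make_atom("CA", "C", ca),
            make_atom("CB", "C", at(1.5)),
            make_atom("CG", "C", at(2.75)),
            make_atom("CD1", "C", at(CHAIN_SEPARATION / 2 - CONTACT_GAP / 2)),
        ]
        name = "LEU"
    elif kind == "donor":
        atoms = [
            make_atom("CA", "C", ca),
            make_atom("CB", "C", at(1.5)),
            make_atom("CG", "C", at(3.0)),
            make_atom("NE2", "N", at(CHAIN_SEPARATION / 2 - HBOND_GAP / 2)),
        ]
        name = "GLN"
    elif kind == "acceptor":
        atoms = [
            make_atom("CA", "C", ca),
            make_atom("CB", "C", at(1.5)),
            make_atom("CG", "C", at(3.0)),
            make_atom("OE1", "O", at(CHAIN_SEPARATION / 2 - HBOND_GAP / 2)),
        ]
        name = "GLN"
    else:  # pragma: no cover
        raise ValueError(kind)
    return Residue(chain_id=chain_id, number=number, name=name, atoms=atoms)


def _verify_geometry(snapshot: Snapshot, spec: ToyComplexSpec) -> None:
    """Brute-force check of every guarantee the generator makes."""
    res_a = snapshot.chain("A")
    res_b = snapshot.chain("B")
    contact = {(a, b) for a, b in spec.contact_pairs}
    hbond = {(a, b) for a, b in spec.hbond_pairs}

    def min_dist(r1: Residue, r2: Residue) -> float:
        x1, x2 = r1.heavy_coords(), r2.heavy_coords()
        return float(np.sqrt(((x1[:, None] - x2[None]) ** 2).sum(-1).min()))

    for chain in (res_a, res_b):
        for r1, r2 in zip(chain, chain[1:]):
            step = np.linalg.norm(r1.atom("CA").position - r2.atom("CA").position)
            if abs(step - CA_STEP) > 1e-6:
                raise GeometryError(f"broken trace at {r1.label}: step {step:.3f}")
    for a, b in contact:
        d = min_dist(res_a[a - 1], res_b[b - 1])
        if d > 4.5:
            raise GeometryError(f"contact pair ({a},{b}) at {d:.2f} Å > 4.5")
    for a, b in hbond:
        donor = res_a[a - 1].atom("NE2")
        acceptor = res_b[b - 1].atom("OE1")
        if donor is None or acceptor is None:
            raise GeometryError(f"missing donor/acceptor atoms on pair ({a},{b})")
        if np.linalg.norm(donor.position - acceptor.position) > 3.2:
            raise GeometryError(f"H-bond pair ({a},{b}) exceeds 3.2 Å")
    for ra in res_a:
        for rb in res_b:
            if (ra.number, rb.number) in contact:
                continue
            if min_dist(ra, rb) < 8.0:
                raise GeometryError(
                    f"non-contact cross-chain pair ({ra.number},{rb.number}) "
                    f"closer than 8 Å"
                )
    path_edges = {
        tuple(sorted(e)) for e in zip(spec.path_chain, spec.path_chain[1:])
    }
    for chain in (res_a, res_b):
        for i, r1 in enumerate(chain):
            for r2 in chain[i + 1 :]:
                sep = r2.number - r1.number
                if sep <= 2:
                    if np.linalg.norm(r1.atom("CA").position - r2.atom("CA").position) < 2.0:
                        raise GeometryError("self-intersecting trace")
                    continue
                key = tuple(sorted((r1.number, r2.number)))
                is_path_edge = chain is res_a and key in path_edges
                d = min_dist(r1, r2)
                if is_path_edge and d > 4.5:
                    raise GeometryError(f"planted path edge {key} at {d:.2f} Å > 4.5")
                if not is_path_edge and d <= 4.5:
                    raise GeometryError(
                        f"unplanned intra-chain contact {key} at {d:.2f} Å"
                    )


def generate_toy_complex(spec: ToyComplexSpec, seed: int = 0) -> Snapshot:
    """Lay out the two-chain complex described by ``spec``.

    Chain A runs near the z = 0 plane with its interface side facing +z;
    chain B runs near z = 12 with contact residues reaching down.  The
    planted path residues of chain A are placed 4.2 Å apart in a row with
    the intervening residues routed over non-interacting arcs.  Every
    guarantee (contacts <= 4.5 Å, H-bonds <= 3.2 Å, non-contact cross-chain
    pairs >= 8 Å, no unplanned intra-chain contacts) is verified by a
    brute-force scan; a handful of alternative arc orientations are tried
    before giving up with :class:`GeometryError`.
    """
    rng = np.random.default_rng(seed)
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    contacts_by_b = sorted(spec.contact_pairs, key=lambda p: p[1])
    hbond = {tuple(p) for p in spec.hbond_pairs}
    last_err: Optional[Exception] = None
    for attempt in range(8):
        tilt = math.radians(attempt * 9.0) * (1 if attempt % 2 == 0 else -1)
        try:
            # chain A: path anchors (if any) in a 4.2 Å row along x at z=0
            anchors_a = {
                p: np.array([PATH_STEP * t, 0.0, 0.0])
                for t, p in enumerate(spec.path_chain)
            }
            bulge_up = np.array([math.sin(tilt), math.cos(tilt), 0.0])
            pos_a = _route_chain(
                spec.n_res_a,
                anchors_a,
                head_dir=np.array([-0.5, -math.sqrt(3) / 2, 0.0]),
                tail_dir=np.array(
                    [0.5, math.sqrt(3) / 2 * (-1 if len(anchors_a) % 2 == 0 else 1), 0.0]
                ),
                bulges=[bulge_up, -bulge_up],
            )
            # chain B: anchors above chain A's contact residues
            anchors_b = {
                b: pos_a[a - 1] + z * CHAIN_SEPARATION for a, b in contacts_by_b
            }
            bulge_b = np.array([0.0, math.sin(tilt), math.cos(tilt)])
            pos_b = _route_chain(
                spec.n_res_b,
                anchors_b,
                head_dir=np.array([-0.5, 0.0, math.sqrt(3) / 2]),
                tail_dir=np.array([0.5, 0.0, math.sqrt(3) / 2]),
                bulges=[bulge_b, np.array([0.0, -math.sin(tilt), math.cos(tilt)])],
            )
            if not anchors_b:  # keep the chains apart when nothing touches
                pos_b = pos_b + z * CHAIN_SEPARATION
            contacts_a = {a for a, _ in spec.contact_pairs}
            contacts_b = {b for _, b in spec.contact_pairs}
            donors_a = {a for a, _ in hbond}
            acceptors_b = {b for _, b in hbond}
            residues = []
            for k in range(spec.n_res_a):
                n = k + 1
                kind = (
                    "donor" if n in donors_a
                    else "contact" if n in contacts_a
                    else "plain"
                )
                residues.append(_make_residue("A", n, kind, pos_a[k], up=+1.0))
            for k in range(spec.n_res_b):
                n = k + 1
                kind = (
                    "acceptor" if n in acceptors_b
                    else "contact" if n in contacts_b
                    else "plain"
                )
                residues.append(_make_residue("B", n, kind, pos_b[k], up=-1.0))
            snapshot = Snapshot(residues)
            _verify_geometry(snapshot, spec)
            return snapshot
        except GeometryError as exc:
            last_err = exc
            # deterministic retry with a different arc tilt; the rng only
            # breaks symmetry if the fixed patterns are exhausted
            _ = rng.random()
            continue
    raise GeometryError(f"no feasible layout for spec after retries: {last_err}")


def generate_two_cluster_snapshot(n_per_cluster: int = 5) -> Snapshot:
    """Two dense residue clusters joined by a single weak bridge contact.

    Each cluster is a ring of glycine-like 2-atom pseudo-residues whose
    mutual interaction strengths are several percent; the last residue of
    the first cluster and the first residue of the second carry one extra
    atom each, meeting in exactly one heavy-atom contact — an interaction
    strength of 100/47.31 ≈ 2.1%.  Raising I_min past that value splits the
    largest cluster in half, which is the transition an I_min scan should
    select.  Analyse with ``exclude_neighbors=0`` (the clusters are
    sequence-consecutive by construction).
    """
    residues = []
    number = 0
    for c, centre_x in enumerate((0.0, 12.0)):
        for k in range(n_per_cluster):
            number += 1
            angle = 2.0 * math.pi * k / n_per_cluster
            ca = np.array(
                [centre_x + 1.5 * math.cos(angle), 1.5 * math.sin(angle), 0.0]
            )
            atoms = [make_atom("CA", "C", ca), make_atom("CB", "C", ca + [0, 0, 1.0])]
            bridges_right = c == 0 and k == 0  # residue at angle 0 faces +x
            bridges_left = c == 1 and k == (n_per_cluster + 1) // 2
            if bridges_right:
                atoms.append(make_atom("CG", "C", [4.0, 0.0, 0.0]))
            if bridges_left:
                atoms.append(make_atom("CG", "C", [8.0, 0.0, 0.0]))
            residues.append(Residue("A", number, "GLY", atoms))
    return Snapshot(residues)


def generate_ensemble(
    base: Snapshot,
    n_frames: int,
    noise_sd: float = 0.0,
    broken_fraction: float = 0.0,
    seed: int = 0,
    scattered: bool = False,
    frame_spacing: float = 1000.0,
) -> Ensemble:
    """Perturb a snapshot into an ``n_frames`` ensemble.

    Every frame is the base plus i.i.d. isotropic Gaussian displacement of
    each atom (sd ``noise_sd`` Å).  ``round(broken_fraction * n_frames)``
    frames additionally have every chain other than the first rigidly
    translated 20 Å along the interface normal, breaking all cross-chain
    contacts; these frames form a contiguous block at the end of the
    trajectory unless ``scattered`` is set.  Bit-reproducible from ``seed``.
    """
    if n_frames < 1:
        raise SyntheticError("n_frames must be >= 1")
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be non-negative")
    if not 0.0 <= broken_fraction <= 1.0:
        raise SyntheticError("broken_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    coords = base.coordinates()
    chain_of_atom = np.array(
        [r.chain_id for r in base for _ in r.atoms]
    )
    first_chain = base.residues[0].chain_id
    partner = chain_of_atom != first_chain
    if partner.any():
        normal = coords[partner].mean(axis=0) - coords[~partner].mean(axis=0)
        normal = normal / np.linalg.norm(normal)
    else:
        normal = np.array([0.0, 0.0, 1.0])
    n_broken = int(round(broken_fraction * n_frames))
    if scattered:
        broken_idx = set(rng.choice(n_frames, size=n_broken, replace=False).tolist())
    else:
        broken_idx = set(range(n_frames - n_broken, n_frames))
    snapshots = []
    for k in range(n_frames):
        frame = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        if k in broken_idx:
            frame = frame + np.where(partner[:, None], normal * BROKEN_SHIFT, 0.0)
        snap = base.with_coordinates(frame)
        snap.model_index = k + 1
        snap.time = k * frame_spacing
        snapshots.append(snap)
    return Ensemble(snapshots, frame_spacing=frame_spacing)
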