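"""Mutual-information co-evolution analysis on a concatenated two-domain MSA.

The pipeline mirrors the classic correlated-mutation recipe for small
alignments: drop columns with more than 30% gaps, concatenate the two
per-domain alignments row-wise, estimate a pseudocount-regularised joint
distribution for every column pair, compute mutual information in nats,
apply the average-product correction (APC), and rank pairs, labelling each
as intra-domain or inter-domain.

The pseudocount blends the observed pair distribution with the product of
the two column profiles,

    P_PP(x_i, y_j) = (1 - tau) P_obs(x_i, y_j) + tau q(x_i) q(y_j),

with a weight that decays with the effective number of sequences aligned
at both positions,

    tau = (1 + b) / (exp(a * Neff(i, j)) + b).

Marginals are taken as row/column sums of the pseudocounted joint, so MI is
computed on a proper distribution.  The APC term MI(i,.)MI(.,j)/MI(.,.)
removes the shared background (phylogenetic and sampling) signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structio import Msa

__all__ = [
    "AMINO_ACIDS",
    "PseudocountParams",
    "DomainPartition",
    "JointDistribution",
    "PairScore",
    "CoevolutionResult",
    "remove_gappy_columns",
    "concatenate_alignments",
    "sequence_weights",
    "effective_sequences",
    "pseudocount_weight",
    "joint_probability",
    "mutual_information",
    "mi_matrix",
    "apc_correction",
    "predict_coevolving_pairs",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}
N_AA = 20


class CoevolutionError(ValueError):
    pass


@dataclass(frozen=True)
class PseudocountParams:
    """Constants of the pseudocount weight tau = (1+b)/(e^{a*Neff}+b).

    Defaults give tau ~ 1 for a handful of sequences and tau < 0.1 by
    Neff ~ 90, i.e. strong regularisation only when data are scarce.
    """

    a: float = 0.05
    b: float = 10.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise CoevolutionError("pseudocount constants a, b must be positive")


@dataclass(frozen=True)
class DomainPartition:
    """Split of a concatenated alignment into domain A and domain B columns."""

    boundary: int  # last column (1-based) of domain A
    label_a: str = "A"
    label_b: str = "B"

    def classify(self, i: int, j: int) -> str:
        a = i <= self.boundary
        b = j <= self.boundary
        if a and b:
            return f"intra_{self.label_a}"
        if not a and not b:
            return f"intra_{self.label_b}"
        return "inter"


@dataclass
class JointDistribution:
    counts_based: np.ndarray  # P_obs, 20x20
    pseudocounted: np.ndarray  # P_PP, 20x20
    marginal_x: np.ndarray  # P(x_i) = sum_y P_PP
    marginal_y: np.ndarray  # P(y_j) = sum_x P_PP
    neff: float
    tau: float


@dataclass(frozen=True)
class PairScore:
    i: int  # original concatenated column, 1-based
    j: int
    mi: float
    mip: float
    rank: int
    pair_class: str


@dataclass
class CoevolutionResult:
    pairs: list[PairScore]
    column_map: list[int]  # filtered column k (0-based) -> original column (1-based)
    partition: DomainPartition


def _encode(msa: Msa) -> np.ndarray:
    """Rows as int codes: 0..19 amino acids, -1 gap (gap and 'X' alike)."""
    arr = np.frombuffer("".join(msa.rows).encode(), dtype="S1").reshape(msa.n_seqs, msa.n_cols)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for aa, k in _AA_INDEX.items():
        out[arr == aa.encode()] = k
    return out


# ---------------------------------------------------------------------------
# alignment preparation

def remove_gappy_columns(
    msa: Msa, max_gap_fraction: float = 0.30
) -> tuple[Msa, list[int]]:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    Returns the filtered alignment and a map from kept-column index
    (0-based) to the original 1-based column number.  'X' counts as a gap.
    A column with exactly the threshold fraction (e.g. 3 gaps in 10 rows at
    0.30) is retained.
    """
    codes = _encode(msa)
    gap_frac = (codes < 0).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction + 1e-12)
    if keep.size == 0:
        raise CoevolutionError("all columns exceed the gap threshold")
    rows = ["".join(row[k] for k in keep) for row in msa.rows]
    return Msa(ids=list(msa.ids), rows=rows), [int(k) + 1 for k in keep]


def concatenate_alignments(msa_a: Msa, msa_b: Msa) -> tuple[Msa, DomainPartition]:
    """Row-wise concatenation of two alignments sharing ordered ids."""
    if msa_a.ids != msa_b.ids:
        raise CoevolutionError(
            "alignments cannot be paired: sequence ids differ or are ordered differently"
        )
    rows = [ra + rb for ra, rb in zip(msa_a.rows, msa_b.rows)]
    return Msa(ids=list(msa_a.ids), rows=rows), DomainPartition(boundary=msa_a.n_cols)


def sequence_weights(msa: Msa, identity_threshold: float = 0.8) -> np.ndarray:
    """Per-row weights 1/cluster-size at the given fractional identity.

    A row's cluster size is the number of rows (including itself) with
    pairwise identity >= threshold over non-doubly-gapped columns.
    """
    codes = _encode(msa)
    n = msa.n_seqs
    weights = np.ones(n)
    for s in range(n):
        both = (codes[s] >= 0) & (codes >= 0)
        matches = ((codes[s] == codes) & both).sum(axis=1)
        lengths = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(lengths > 0, matches / np.maximum(lengths, 1), 0.0)
        weights[s] = 1.0 / max(int((ident >= identity_threshold).sum()), 1)
    return weights


def effective_sequences(
    msa: Msa, i: int, j: int, weights: Optional[np.ndarray] = None
) -> float:
    """Effective number of sequences aligned (ungapped) at both columns.

    Unweighted (default): the plain count of rows ungapped at both ``i``
    and ``j`` (1-based columns).  With ``weights`` (see
    :func:`sequence_weights`), the sum of those rows' weights.
    """
    codes = _encode(msa)
    mask = (codes[:, i - 1] >= 0) & (codes[:, j - 1] >= 0)
    if weights is None:
        return float(mask.sum())
    return float(np.asarray(weights)[mask].sum())


def pseudocount_weight(neff: float, params: PseudocountParams = PseudocountParams()) -> float:
    """tau = (1 + b) / (exp(a * Neff) + b); 1 at Neff=0, -> 0 as Neff grows."""
    if neff < 0:
        raise CoevolutionError("neff must be non-negative")
    exponent = params.a * neff
    if exponent > 700:  # exp would overflow; tau underflows to 0
        return 0.0
    return (1.0 + params.b) / (math.exp(exponent) + params.b)


def _column_profile(codes: np.ndarray, col0: int) -> np.ndarray:
    col = codes[:, col0]
    col = col[col >= 0]
    if col.size == 0:
        return np.full(N_AA, 1.0 / N_AA)
    return np.bincount(col, minlength=N_AA) / col.size


def joint_probability(
    msa: Msa,
    i: int,
    j: int,
    params: PseudocountParams = PseudocountParams(),
    weights: Optional[np.ndarray] = None,
    tau: Optional[float] = None,
) -> JointDistribution:
    """Pseudocounted joint distribution of columns ``i`` and ``j`` (1-based).

    P_obs comes from rows ungapped at both columns; the column profiles q
    come from each column's ungapped rows; tau from Neff(i, j) unless pinned
    explicitly (tau=0 reproduces P_obs, tau=1 the product of profiles).
    """
    codes = _encode(msa)
    ci, cj = codes[:, i - 1], codes[:, j - 1]
    mask = (ci >= 0) & (cj >= 0)
    if mask.sum() < 2:
        raise CoevolutionError(
            f"columns {i},{j}: fewer than 2 rows ungapped at both positions"
        )
    w = np.ones(msa.n_seqs) if weights is None else np.asarray(weights, dtype=float)
    counts = np.zeros((N_AA, N_AA))
    np.add.at(counts, (ci[mask], cj[mask]), w[mask])
    p_obs = counts / counts.sum()
    neff = float(w[mask].sum())
    if tau is None:
        tau = pseudocount_weight(neff, params)
    elif not 0.0 <= tau <= 1.0:
        raise CoevolutionError("explicit tau must be in [0, 1]")
    qi = _column_profile(codes, i - 1)
    qj = _column_profile(codes, j - 1)
    p_pp = (1.0 - tau) * p_obs + tau * np.outer(qi, qj)
    return JointDistribution(
        counts_based=p_obs,
        pseudocounted=p_pp,
        marginal_x=p_pp.sum(axis=1),
        marginal_y=p_pp.sum(axis=0),
        neff=neff,
        tau=tau,
    )


def mutual_information(joint: JointDistribution) -> float:
    """MI(i,j) = sum_xy P(x,y) log(P(x,y) / (P(x) P(y))), in nats.

    Terms with P(x,y) = 0 contribute zero.
    """
    p = joint.pseudocounted
    px, py = joint.marginal_x, joint.marginal_y
    denom = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0) / denom), 0.0)
    return float(max(terms.sum(), 0.0))


def mi_matrix(
    msa: Msa,
    params: PseudocountParams = PseudocountParams(),
    weights: Optional[np.ndarray] = None,
    block: int = 32,
) -> np.ndarray:
    """Symmetric MI matrix over all column pairs (vectorised, blocked).

    Equivalent to calling :func:`joint_probability` +
    :func:`mutual_information` per pair; pairs with fewer than two usable
    rows score 0.  Diagonal is 0 by convention.
    """
    codes = _encode(msa)
    n_seqs, n_cols = codes.shape
    w = np.ones(n_seqs) if weights is None else np.asarray(weights, dtype=float)
    # one-hot with gaps as all-zero; weighted rows
    onehot = np.zeros((n_seqs, n_cols, N_AA))
    s_idx, c_idx = np.nonzero(codes >= 0)
    onehot[s_idx, c_idx, codes[s_idx, c_idx]] = 1.0
    wh = onehot * w[:, None, None]
    profiles = np.stack([_column_profile(codes, c) for c in range(n_cols)])
    mi = np.zeros((n_cols, n_cols))
    for lo in range(0, n_cols, block):
        hi = min(lo + block, n_cols)
        # counts[b, j, x, y] = sum_s w_s [row s has x at col lo+b and y at col j]
        counts = np.einsum("sia,sjb->ijab", wh[:, lo:hi], onehot, optimize=True)
        neff = counts.sum(axis=(2, 3))
        tau = (1.0 + params.b) / (np.exp(params.a * neff) + params.b)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_obs = counts / np.maximum(neff[..., None, None], 1e-300)
        prod = np.einsum("ia,jb->ijab", profiles[lo:hi], profiles)
        p_pp = (1.0 - tau[..., None, None]) * p_obs + tau[..., None, None] * prod
        px = p_pp.sum(axis=3)
        py = p_pp.sum(axis=2)
        denom = px[:, :, :, None] * py[:, :, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                p_pp > 0, p_pp * np.log(np.where(p_pp > 0, p_pp, 1.0) / denom), 0.0
            )
        block_mi = terms.sum(axis=(2, 3))
        block_mi[neff < 2] = 0.0
        mi[lo:hi] = block_mi
    np.fill_diagonal(mi, 0.0)
    return np.maximum((mi + mi.T) / 2.0, 0.0)  # enforce exact symmetry


def apc_correction(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: MIp = MI - MI(i,.) MI(.,j) / MI(.,.).

    Averages run over off-diagonal entries.  If the overall average is zero
    no correction is possible and MI is returned unchanged.  The diagonal of
    the output is zero.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if mi.shape != (n, n) or not np.allclose(mi, mi.T, atol=1e-8):
        raise CoevolutionError("apc_correction expects a symmetric square matrix")
    if n < 2:
        return np.zeros_like(mi)
    off = mi.copy()
    np.fill_diagonal(off, 0.0)
    row_mean = off.sum(axis=1) / (n - 1)  # MI(i, .)
    overall = off.sum() / (n * (n - 1))  # MI(., .)
    if overall == 0:
        out = mi.copy()
    else:
        out = mi - np.outer(row_mean, row_mean) / overall
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


def predict_coevolving_pairs(
    msa_a: Msa,
    msa_b: Msa,
    params: PseudocountParams = PseudocountParams(),
    top_n: int = 24,
    max_gap_fraction: float = 0.30,
    min_separation: int = 5,
    weighted: bool = False,
    identity_threshold: float = 0.8,
    rank_by: str = "mip",
) -> CoevolutionResult:
    """Full co-evolution pipeline on two per-domain alignments.

    Filters gappy columns per alignment, concatenates, computes MI and MIp
    over all remaining column pairs, excludes intra-domain pairs closer than
    ``min_separation`` in original column numbering (trivial chain-neighbour
    signal), ranks descending by MIp (ties: MI descending, then i, then j)
    and returns the ``top_n`` pairs with original 1-based concatenated
    column numbers and intra/inter-domain labels.
    """
    if rank_by not in ("mip", "mi"):
        raise CoevolutionError("rank_by must be 'mip' or 'mi'")
    filt_a, map_a = remove_gappy_columns(msa_a, max_gap_fraction)
    filt_b, map_b = remove_gappy_columns(msa_b, max_gap_fraction)
    concat, partition = concatenate_alignments(filt_a, filt_b)
    # original concatenated numbering: domain B columns offset by full A width
    column_map = map_a + [msa_a.n_cols + c for c in map_b]
    weights = sequence_weights(concat, identity_threshold) if weighted else None
    mi = mi_matrix(concat, params, weights=weights)
    mip = apc_correction(mi)
    orig_partition = DomainPartition(
        boundary=msa_a.n_cols, label_a=partition.label_a, label_b=partition.label_b
    )

    candidates = []
    n = concat.n_cols
    for i in range(n):
        for j in range(i + 1, n):
            oi, oj = column_map[i], column_map[j]
            cls = orig_partition.classify(oi, oj)
            if cls != "inter" and abs(oj - oi) < min_separation:
                continue
            candidates.append((oi, oj, float(mi[i, j]), float(mip[i, j]), cls))
    key = (lambda c: (-c[3], -c[2], c[0], c[1])) if rank_by == "mip" else (
        lambda c: (-c[2], -c[3], c[0], c[1])
    )
    candidates.sort(key=key)
    pairs = [
        PairScore(i=oi, j=oj, mi=mi_v, mip=mip_v, rank=r + 1, pair_class=cls)
        for r, (oi, oj, mi_v, mip_v, cls) in enumerate(candidates[:top_n])
    ]
    return CoevolutionResult(pairs=pairs, column_map=column_map, partition=orig_partition)
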