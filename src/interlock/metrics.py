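"""Conformational ensemble metrics: RMSD, radius of gyration, RMSF."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structio import Ensemble, ResidueKey, Snapshot

__all__ = [
    "MetricSeries",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "rmsf",
]

BACKBONE = ("N", "CA", "C", "O")


class MetricsError(ValueError):
    pass


@dataclass
class MetricSeries:
    name: str
    values: np.ndarray  # per frame (RMSD, Rg) or per residue (RMSF), Å
    reference: str
    labels: Optional[list] = None  # residue keys for per-residue series


def _selection_coords(snapshot: Snapshot, selection: str) -> np.ndarray:
    if selection == "backbone":
        names: Sequence[str] = BACKBONE
    elif selection == "ca":
        names = ("CA",)
    elif selection == "all":
        return snapshot.coordinates()
    else:
        raise MetricsError(f"unknown selection {selection!r}")
    coords = [
        a.position for r in snapshot for a in r.atoms if a.name in names
    ]
    if not coords:
        raise MetricsError(f"no atoms match selection {selection!r}")
    return np.asarray(coords)


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centred ``mobile`` onto centred ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return u @ diag @ vt


def kabsch_superpose(
    mobile: Snapshot, reference: Snapshot, selection: str = "backbone"
) -> tuple[Snapshot, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The optimal rigid transform is fitted on the selected atoms (default
    backbone N, CA, C, O) and applied to all atoms of the mobile snapshot.
    Returns the transformed snapshot and the RMSD over the selection.
    """
    xm = _selection_coords(mobile, selection)
    xr = _selection_coords(reference, selection)
    if xm.shape != xr.shape:
        raise MetricsError(
            f"selection size mismatch: {xm.shape[0]} vs {xr.shape[0]} atoms"
        )
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    rot = _kabsch_rotation(xm - cm, xr - cr)
    fitted = (xm - cm) @ rot + cr
    rmsd = float(np.sqrt(((fitted - xr) ** 2).sum(axis=1).mean()))
    all_coords = mobile.coordinates()
    transformed = (all_coords - cm) @ rot + cr
    return mobile.with_coordinates(transformed), rmsd


def rmsd_series(
    ensemble: Ensemble, reference: Snapshot, selection: str = "backbone"
) -> MetricSeries:
    """Per-frame RMSD to a reference after optimal superposition."""
    values = np.array(
        [kabsch_superpose(s, reference, selection)[1] for s in ensemble]
    )
    return MetricSeries(
        name=f"rmsd_{selection}", values=values, reference="superposed reference"
    )


def radius_of_gyration(snapshot: Snapshot, mass_weighted: bool = True) -> float:
    """Rg = sqrt(sum m_k |r_k - r_com|^2 / sum m_k), over all atoms, Å."""
    coords = snapshot.coordinates()
    masses = np.array([a.mass for r in snapshot for a in r.atoms])
    w = masses if mass_weighted else np.ones_like(masses)
    com = (coords * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - com) ** 2).sum(axis=1)).sum() / w.sum()))


def rg_series(ensemble: Ensemble, mass_weighted: bool = True) -> MetricSeries:
    values = np.array([radius_of_gyration(s, mass_weighted) for s in ensemble])
    return MetricSeries(name="rg", values=values, reference="centre of mass")


def _window_frames(n_frames: int, window) -> list[int]:
    if isinstance(window, float):
        if not 0 < window <= 1:
            raise MetricsError("trailing window fraction must be in (0, 1]")
        start = n_frames - max(int(round(window * n_frames)), 1)
        return list(range(start, n_frames))
    start, end = window
    return list(range(start, end))


def rmsf(ensemble: Ensemble, window: float | tuple[int, int] = 0.2) -> MetricSeries:
    """Per-residue Cα root-mean-square fluctuation over a trailing window.

    ``window`` is either a trailing fraction of frames (e.g. 0.2 = last 20%)
    or an explicit (start, end) frame range.  Frames are superposed (on Cα)
    to an iteratively refined mean structure (two refinement passes), then
    RMSF_r = sqrt(mean_t |r_t - r_mean|^2).
    """
    frames = _window_frames(len(ensemble), window)
    if len(frames) < 2:
        raise MetricsError("RMSF window must contain at least 2 frames")
    coords = np.stack([_selection_coords(ensemble[k], "ca") for k in frames])
    keys = [r.key for r in ensemble[0] if r.atom("CA") is not None]
    if coords.shape[1] != len(keys):
        raise MetricsError("Cα selection does not match residue list")
    mean = coords[0]
    for _ in range(2):  # superpose to the running mean, then recompute it
        fitted = []
        mc = mean - mean.mean(axis=0)
        for x in coords:
            c = x.mean(axis=0)
            rot = _kabsch_rotation(x - c, mc)
            fitted.append((x - c) @ rot + mean.mean(axis=0))
        coords = np.stack(fitted)
        mean = coords.mean(axis=0)
    values = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return MetricSeries(
        name="rmsf_ca",
        values=values,
        reference=f"mean structure of frames {frames[0]}..{frames[-1]}",
        labels=keys,
    )
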