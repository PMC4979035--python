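"""Superposition-based trajectory stability metrics: RMSD and RMSF.

The optimal rigid superposition (Kabsch) is delegated to
``scipy.spatial.transform.Rotation.align_vectors``; this module adds the
weighted-RMSD bookkeeping, time series over trajectories, histograms of the
RMSD distribution, and per-atom / per-residue-Calpha RMSF about an iterated
mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_io import Selection, SelectionError, Trajectory

__all__ = ["MetricSeries", "GeometryError", "kabsch_superpose",
           "rmsd_series", "rmsd_distribution", "rmsf", "pearson"]


class GeometryError(ValueError):
    """Degenerate geometry (too few or collinear points)."""


@dataclass
class MetricSeries:
    """A per-frame metric (A) with provenance of selection and reference."""

    frame_index: np.ndarray
    values: np.ndarray
    selection: str = ""
    reference: str = ""

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, int)
        self.values = np.asarray(self.values, float)
        if len(self.frame_index) != len(self.values):
            raise ValueError("frame_index and values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("metric values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame_index, "value": self.values})


def _check_points(x):
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise GeometryError("expected an N x 3 coordinate array")
    if len(x) < 3:
        raise GeometryError("superposition needs at least 3 points")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("points are collinear or coincident")
    return x


def kabsch_superpose(mobile, reference, weights=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` and
    ``rmsd = sqrt(sum_i w_i |x_i - y_i|^2 / sum_i w_i)`` after the transform.
    The rotation is proper (det = +1).
    """
    mobile = _check_points(mobile)
    reference = _check_points(reference)
    if mobile.shape != reference.shape:
        raise GeometryError("mobile/reference shape mismatch")
    n = len(mobile)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise GeometryError("weights must be non-negative with positive sum")

    mc = (w[:, None] * mobile).sum(0) / w.sum()
    rc = (w[:, None] * reference).sum(0) / w.sum()
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mobile @ R.T + t
    d2 = ((moved - reference) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((w * d2).sum() / w.sum()))
    return R, t, rmsd


def rmsd_series(traj: Trajectory, reference, selection: Selection,
                weights=None) -> MetricSeries:
    """RMSD of a selection versus a reference frame, per trajectory frame.

    ``reference`` is either a 0-based frame position into ``traj`` or an
    explicit full-topology coordinate array.
    """
    if len(selection) == 0:
        raise SelectionError("rmsd_series: empty selection")
    idx = selection.index_array
    if np.isscalar(reference):
        ref = traj.coords[int(reference), idx]
        ref_label = f"frame {int(reference)}"
    else:
        ref = np.asarray(reference, float)[idx]
        ref_label = "external"
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, vals[f] = kabsch_superpose(traj.coords[f, idx], ref, weights)
    return MetricSeries(traj.frame_index, vals,
                        selection=selection.provenance, reference=ref_label)


def rmsd_distribution(series: MetricSeries, bin_width: float):
    """Histogram of an RMSD series as (bin centers, normalized density)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(series.values) == 0:
        raise ValueError("empty series")
    lo = np.floor(series.values.min() / bin_width) * bin_width
    hi = np.ceil(series.values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(series.values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def _superpose_frames(coords, ref, weights):
    out = np.empty_like(coords)
    for f in range(len(coords)):
        R, t, _ = kabsch_superpose(coords[f], ref, weights)
        out[f] = coords[f] @ R.T + t
    return out


def rmsf(traj: Trajectory, selection: Selection, weights=None,
         mass_weighted=False, passes: int = 2):
    """Per-atom RMSF about the iterated mean structure of a selection.

    Frames are superposed onto the running mean (``passes`` refinement
    passes, default 2), then ``RMSF_i = sqrt(<|x_i - <x_i>|^2>)``.  With
    ``mass_weighted`` the superposition weights are the atomic masses.
    Returns an array of length ``len(selection)``.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    if len(selection) == 0:
        raise SelectionError("rmsf: empty selection")
    idx = selection.index_array
    coords = traj.coords[:, idx]
    if weights is None and mass_weighted:
        weights = traj.topology.masses[idx]
    ref = coords[0]
    for _ in range(passes):
        sup = _superpose_frames(coords, ref, weights)
        ref = sup.mean(axis=0)
    sup = _superpose_frames(coords, ref, weights)
    mean = sup.mean(axis=0)
    return np.sqrt(((sup - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_per_residue_calpha(traj: Trajectory, weights=None):
    """Calpha RMSF aggregated per protein residue.

    Returns a DataFrame (residue_name, residue_index, rmsf).  Superposition
    is on the Calpha selection itself.
    """
    from .model_io import select
    sel = select(traj.topology, "calpha")
    vals = rmsf(traj, sel, weights=weights)
    top = traj.topology
    rows = [(top.atoms[a].residue_name, top.atoms[a].residue_index, v)
            for a, v in zip(sel.indices, vals)]
    return pd.DataFrame(rows, columns=["residue_name", "residue_index", "rmsf"])


def pearson(x, y) -> float:
    """Pearson correlation coefficient (utility for comparing RMSF profiles)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors, n >= 2")
    return float(np.corrcoef(x, y)[0, 1])
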