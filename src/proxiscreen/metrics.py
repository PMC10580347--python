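"""Post-simulation trajectory analytics.

Implements the standard descriptive statistics used to judge the stability
and dynamics of a simulated protein–ligand complex:

* optimal rigid-body superposition (Kabsch),
* RMSD time series against the first frame,
* per-residue RMSF about the mean structure,
* dynamic cross-correlation matrix (DCCM) of residue displacements,
* principal component analysis of the coordinate covariance,
* 2D free-energy landscapes over (PC1, PC2), F = -kB*T*ln(P/Pmax),
* the trailing convergence window (by default the last 20% of frames)
  used upstream of energy aggregation and landscapes.

All metrics superpose frames first, so they are invariant under global
rigid motion of the input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "FreeEnergyLandscape",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "dccm",
    "pca",
    "free_energy_landscape",
    "convergence_window",
]

#: Boltzmann constant in kcal/mol/K
KB_KCAL_PER_MOL_K = 0.0019872

MaskLike = Union[str, Sequence[bool], np.ndarray, None]


def _check_superposable(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise ValueError("superposition needs at least 3 masked atoms")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("masked atoms are collinear; superposition is degenerate")


def _fit_transform(mobile_pts: np.ndarray, ref_pts: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal proper rotation + centroids aligning mobile points onto reference."""
    _check_superposable(mobile_pts)
    _check_superposable(ref_pts)
    mob_c = mobile_pts.mean(axis=0)
    ref_c = ref_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_pts - ref_c, mobile_pts - mob_c)
    return rot, mob_c, ref_c


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Superpose one frame onto another and report the minimized RMSD.

    Parameters
    ----------
    mobile, reference : ndarray, shape (n_atoms, 3)
        Coordinate frames with identical atom ordering.
    mask : boolean ndarray, optional
        Atoms used for the fit and the reported RMSD; the whole frame is
        transformed.  Defaults to all atoms.

    Returns
    -------
    (moved, rmsd)
        The rigidly moved mobile frame and the masked RMSD (Å) after the
        optimal translation + proper rotation (reflections are excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n_atoms, 3)")
    if mask is None:
        mask = np.ones(mobile.shape[0], dtype=bool)
    rot, mob_c, ref_c = _fit_transform(mobile[mask], reference[mask])
    moved = rot.apply(mobile - mob_c) + ref_c
    return moved, _rmsd(moved[mask], reference[mask])


def _superpose_stack(coords: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        out[i], _ = kabsch_superpose(coords[i], reference, mask)
    return out


def superpose_to_mean(traj: Trajectory, mask: MaskLike = None,
                      fit_mask: MaskLike = None) -> np.ndarray:
    """Frames superposed on the mean structure.

    One refinement pass: align everything to frame 0, take the mean, then
    re-align the original frames to that mean.  ``fit_mask`` selects the
    atoms used for the rigid fit (GROMACS-style fit group); it defaults to
    ``mask``.
    """
    m = traj.mask(fit_mask if fit_mask is not None else mask)
    first = _superpose_stack(traj.coords, traj.coords[0], m)
    mean = first.mean(axis=0)
    return _superpose_stack(traj.coords, mean, m)


def rmsd_series(traj: Trajectory, mask: MaskLike = None) -> np.ndarray:
    """Per-frame RMSD (Å) against frame 0 after masked superposition."""
    m = traj.mask(mask)
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    out[0] = 0.0
    for i in range(1, traj.n_frames):
        _, out[i] = kabsch_superpose(traj.coords[i], ref, m)
    return out


def rmsf_per_residue(traj: Trajectory, mask: MaskLike = None,
                     fit_mask: MaskLike = None) -> pd.Series:
    """Per-residue RMSF (Å) about the mean structure.

    Per-atom fluctuations sqrt(<|r_i - <r_i>|^2>) are aggregated within each
    residue by root-mean-square over that residue's masked atoms.  Residues
    with no masked atom are omitted.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    m = traj.mask(mask)
    aligned = superpose_to_mean(traj, m, fit_mask)
    mean = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # (n_atoms,)
    resids = []
    values = []
    for resid in traj.residue_ids:
        idx = np.array([lab.resid == resid for lab in traj.atom_labels]) & m
        if not idx.any():
            continue
        resids.append(resid)
        values.append(math.sqrt(float(np.mean(msf_atom[idx]))))
    return pd.Series(values, index=pd.Index(resids, name="resid"), name="rmsf")


def _residue_representatives(traj: Trajectory, aligned: np.ndarray, mask: np.ndarray):
    """Unweighted centroid of each residue's masked atoms, per frame."""
    resids = []
    reps = []
    for resid in traj.residue_ids:
        idx = np.array([lab.resid == resid for lab in traj.atom_labels]) & mask
        if not idx.any():
            continue
        resids.append(resid)
        reps.append(aligned[:, idx, :].mean(axis=1))
    return resids, np.stack(reps, axis=1)  # (n_frames, n_res, 3)


def dccm(traj: Trajectory, mask: MaskLike = None,
         fit_mask: MaskLike = None) -> tuple[np.ndarray, list[int]]:
    """Dynamic cross-correlation matrix of residue displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) on frames superposed
    to the mean structure, with one representative point per residue (the
    unweighted centroid of its masked atoms).  Symmetric with unit diagonal;
    zero-variance residues get zero off-diagonal entries and are flagged in
    the log.

    Returns
    -------
    (C, residue_ids)
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    m = traj.mask(mask)
    aligned = superpose_to_mean(traj, m, fit_mask)
    resids, reps = _residue_representatives(traj, aligned, m)
    delta = reps - reps.mean(axis=0)  # (n_frames, n_res, 3)
    cov = np.einsum("fik,fjk->ij", delta, delta) / traj.n_frames
    var = np.diag(cov).copy()
    dead = var < 1e-12
    if dead.any():
        logger.warning("DCCM: %d zero-variance residue(s): %s",
                       dead.sum(), [resids[i] for i in np.where(dead)[0]])
    denom = np.sqrt(np.outer(np.where(dead, 1.0, var), np.where(dead, 1.0, var)))
    C = cov / denom
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C, resids


def pca(traj: Trajectory, mask: MaskLike = None,
        fit_mask: MaskLike = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the superposed coordinate covariance.

    Equivalent to the eigendecomposition of the 3N x 3N covariance matrix of
    the masked, superposed coordinates (computed by SVD for stability; rank
    deficiency is handled naturally).

    Returns
    -------
    (projections, variance_fractions)
        Centered frame projections, shape (n_frames, k), and the fraction of
        total variance per component, non-increasing and summing to 1.
    """
    m = traj.mask(mask)
    aligned = superpose_to_mean(traj, m, fit_mask)
    X = aligned[:, m, :].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-9):
        raise ValueError("all-zero coordinate covariance; PCA undefined")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    fractions = s**2 / total
    projections = U * s
    return projections, fractions


@dataclass
class FreeEnergyLandscape:
    """2D free-energy surface over two reaction coordinates.

    ``energy`` is in kcal/mol, exactly 0 at the most populated bin and NaN
    on empty bins; ``probability`` sums to 1 over occupied bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    energy: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.probability > 0


def free_energy_landscape(
    pc1: np.ndarray,
    pc2: np.ndarray,
    temperature_K: float = 310.0,
    bins: int = 50,
) -> FreeEnergyLandscape:
    """Boltzmann-invert a 2D histogram of reaction coordinates.

    F(bin) = -kB * T * ln(P(bin) / P_max) in kcal/mol, so the most populated
    bin sits at exactly zero and every other occupied bin is positive.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if pc1.shape != pc2.shape or pc1.ndim != 1 or pc1.size < 1:
        raise ValueError("pc1 and pc2 must be equal-length 1D series")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, x_edges, y_edges = np.histogram2d(pc1, pc2, bins=bins)
    prob = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = -KB_KCAL_PER_MOL_K * temperature_K * np.log(counts / counts.max())
    energy[counts == 0] = np.nan
    return FreeEnergyLandscape(x_edges, y_edges, prob, energy, temperature_K)


def convergence_window(traj: Trajectory, fraction: float = 0.2) -> Trajectory:
    """The trailing ``fraction`` of frames (count rounded up).

    With the default 0.2 and a 100-frame run this keeps frames 80–99, the
    converged tail used for energy aggregation and landscapes.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * traj.n_frames)
    return traj.slice_frames(traj.n_frames - n_keep)
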