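"""Size and anisotropy of assemblies and the nucleoid.

Principal axes come from the eigenvectors of the coordinate covariance of
foreground voxel centers (for masks) or arc-resampled polyline points (for
filament sets); axis *lengths* are reported as projection extents
(max - min along each axis), matching the intuitive long/short-axis reading
of fluorescence spot measurements, not eigenvalue multiples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VoxelMask
from .synthetic import resample_polyline

__all__ = ["ShapeMetrics", "principal_shape", "nucleoid_width"]


@dataclass
class ShapeMetrics:
    centroid: np.ndarray
    axes: np.ndarray  # rows: axis of L, M, S
    extents: tuple  # (L, M, S), nm, L >= M >= S
    source: str  # "mask" or "filaments"
    degenerate: bool = False

    @property
    def elongation(self) -> float:
        L, _, S = self.extents
        return L / S if S > 0 else float("inf")


def _entity_coords(entity, spacing: float = 2.0):
    if isinstance(entity, VoxelMask):
        if entity.n_foreground == 0:
            raise ValueError("mask is empty")
        return entity.voxel_centers(), "mask"
    if not entity:
        raise ValueError("need at least one filament")
    return np.vstack([resample_polyline(f.points, spacing) for f in entity]), "filaments"


def principal_shape(entity, projection_2d: bool = False) -> ShapeMetrics:
    """Principal axes and projection extents (L >= M >= S) of an entity.

    ``projection_2d`` drops the z coordinate first (SIM-style in-plane
    long/short axes); the third extent is then 0 and flagged degenerate.
    """
    coords, source = _entity_coords(entity)
    if projection_2d:
        coords = np.column_stack([coords[:, 0], coords[:, 1], np.zeros(len(coords))])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = (centered.T @ centered) / max(len(coords) - 1, 1)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1]  # descending eigenvalue order
    extents = np.ptp(centered @ axes.T, axis=0)
    order = np.argsort(extents)[::-1]
    axes, extents = axes[order], extents[order]
    degenerate = (
        len(coords) < 4
        or np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3
    )
    return ShapeMetrics(
        centroid=centroid,
        axes=axes,
        extents=tuple(float(e) for e in extents),
        source=source,
        degenerate=bool(degenerate),
    )


def nucleoid_width(mask: VoxelMask, cell_axis=None) -> float:
    """Median over axial slices of the slice-wise maximal transverse extent.

    Slices are one voxel pitch thick along ``cell_axis`` (default: the
    mask's own longest principal axis); each slice's width is the extent of
    its voxel centers along the slice's in-plane principal direction.
    """
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    coords = mask.voxel_centers()
    if cell_axis is None:
        cell_axis = principal_shape(mask).axes[0]
    axis = np.asarray(cell_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = coords @ axis
    perp = coords - np.outer(t, axis)
    slice_idx = np.floor((t - t.min()) / mask.voxel_size).astype(int)
    widths = []
    for i in np.unique(slice_idx):
        q = perp[slice_idx == i]
        if len(q) < 2:
            continue
        qc = q - q.mean(axis=0)
        cov = (qc.T @ qc) / max(len(q) - 1, 1)
        _, vecs = np.linalg.eigh(cov)
        proj = qc @ vecs[:, -1]
        widths.append(np.ptp(proj))
    if not widths:
        raise ValueError("no slice has enough voxels to measure a width")
    return float(np.median(widths))
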