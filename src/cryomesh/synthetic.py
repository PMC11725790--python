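"""Synthetic segmented cryo-ET scenes with known ground truth.

Emulates the geometry the analysis assumes: a spheroidal porous meshwork of
bent, intertwined filaments (the wild-type condensate), straighter/elongated
variants for the deletion genotypes, an adjacent bundle of aligned nucleoid
filaments, a hard-core ribosome point process that is (or is not) excluded
from the condensate, a cell-envelope membrane shell, and an 80-120 nm
lamella slab.  Every generator is reproducible given a seed.

Filaments are discrete worm-like chains: fixed step length ``ds`` and
successive tangents drawn from a von Mises-Fisher distribution about the
previous tangent with concentration kappa = Lp/ds, which gives the
tangent-correlation law <t(s) . t(s+d)> ~ exp(-d/Lp).  Chains are confined
by specular reflection at the boundary (the bounce point is inserted as a
polyline vertex, so step length is conserved exactly).

All preset numbers here (filament counts, lengths, radii, gaps, ribosome
intensity) are artifact choices tuned to reproduce qualitative contrasts;
they are not measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import (
    Compartment,
    Filament,
    Genotype,
    MaskLabel,
    PointSet,
    Scene,
    SceneMeta,
    VoxelMask,
)

__all__ = [
    "WLCParams",
    "AssemblyPreset",
    "PointProcessParams",
    "Sphere",
    "Ellipsoid",
    "EllipticCylinder",
    "generate_wlc_filament",
    "generate_assembly",
    "generate_nucleoid",
    "generate_points",
    "generate_scene",
    "slab_crop",
    "sample_isotropic_axes",
    "vmf_directions",
    "estimate_persistence_length",
    "rasterize_filaments",
    "GENOTYPE_PRESETS",
    "DEFAULT_VOXEL_SIZE",
]

DEFAULT_VOXEL_SIZE = 4.0  # nm; resolves the ~5 nm filament scale
DEFAULT_DS = 5.0  # nm; WLC step length


# ---------------------------------------------------------------------------
# direction sampling


def sample_isotropic_axes(n: int, rng) -> np.ndarray:
    """n unit vectors uniform on the sphere (axially they are isotropic)."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _orthonormal_basis(mu: np.ndarray):
    """Two unit vectors completing mu to a right-handed frame."""
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return e1, e2


def vmf_directions(mu, kappa: float, n: int, rng) -> np.ndarray:
    """Sample n unit vectors from a von Mises-Fisher distribution about mu.

    Uses the inverse-CDF of the cosine for dimension 3:
    w = 1 + log(u + (1-u) e^(-2k)) / k.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if kappa > 1e12:  # rigid limit: exactly parallel
        return np.tile(mu, (n, 1))
    u = rng.random(n)
    if kappa < 1e-12:
        w = 2.0 * u - 1.0
    else:
        # exp(-2k) underflows harmlessly to 0 for large kappa
        w = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * min(kappa, 745.0))) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    e1, e2 = _orthonormal_basis(mu)
    s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    v = (
        w[:, None] * mu
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _vmf_step(mu: np.ndarray, kappa: float, rng) -> np.ndarray:
    return vmf_directions(mu, kappa, 1, rng)[0]


# ---------------------------------------------------------------------------
# confinement geometries (specular reflection)


class Ellipsoid:
    """Axis-aligned ellipsoid confinement."""

    def __init__(self, center, semi_axes):
        self.center = np.asarray(center, dtype=float)
        self.semi = np.asarray(semi_axes, dtype=float)
        if np.any(self.semi <= 0):
            raise ValueError("semi-axes must be > 0")

    def contains(self, p) -> bool:
        u = (np.asarray(p) - self.center) / self.semi
        return float(u @ u) <= 1.0

    def bounds(self):
        return self.center - self.semi, self.center + self.semi

    def sample_point(self, rng) -> np.ndarray:
        lo, hi = self.bounds()
        for _ in range(10000):
            p = rng.uniform(lo, hi)
            if self.contains(p):
                return p
        raise RuntimeError("degenerate confinement: could not seed a point")

    def _first_hit(self, p0, d):
        """Smallest t in (0, 1] where p0 + t d crosses the surface, with normal."""
        u0 = (p0 - self.center) / self.semi
        du = d / self.semi
        a = du @ du
        if a == 0.0:
            return None
        b = 2.0 * (u0 @ du)
        c = u0 @ u0 - 1.0
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return None
        t = (-b + math.sqrt(disc)) / (2.0 * a)
        if not (0.0 < t <= 1.0):
            return None
        h = p0 + t * d
        n = (h - self.center) / (self.semi**2)
        n /= np.linalg.norm(n)
        return t, h, n


class Sphere(Ellipsoid):
    def __init__(self, center, radius):
        super().__init__(center, (radius, radius, radius))
        self.radius = float(radius)


class EllipticCylinder:
    """Finite cylinder with elliptical cross-section and flat caps.

    ``axis`` is the long direction; ``half_length`` the axial half-extent and
    ``(r1, r2)`` the cross-section semi-axes along two perpendicular basis
    vectors.
    """

    def __init__(self, center, axis, half_length, r1, r2):
        self.center = np.asarray(center, dtype=float)
        axis = np.asarray(axis, dtype=float)
        self.axis = axis / np.linalg.norm(axis)
        self.half_length = float(half_length)
        self.r1, self.r2 = float(r1), float(r2)
        if min(self.half_length, self.r1, self.r2) <= 0:
            raise ValueError("cylinder dimensions must be > 0")
        self.e1, self.e2 = _orthonormal_basis(self.axis)

    def _local(self, p):
        q = np.asarray(p) - self.center
        return q @ self.axis, q @ self.e1, q @ self.e2

    def contains(self, p) -> bool:
        x, y1, y2 = self._local(p)
        return abs(x) <= self.half_length and (y1 / self.r1) ** 2 + (y2 / self.r2) ** 2 <= 1.0

    def bounds(self):
        ext = (
            np.abs(self.axis) * self.half_length
            + np.abs(self.e1) * self.r1
            + np.abs(self.e2) * self.r2
        )
        return self.center - ext, self.center + ext

    def sample_point(self, rng) -> np.ndarray:
        lo, hi = self.bounds()
        for _ in range(10000):
            p = rng.uniform(lo, hi)
            if self.contains(p):
                return p
        raise RuntimeError("degenerate confinement: could not seed a point")

    def _first_hit(self, p0, d):
        x0, a0, b0 = self._local(p0)
        dx, da, db = d @ self.axis, d @ self.e1, d @ self.e2
        hits = []
        # flat caps
        for sign in (+1.0, -1.0):
            if dx * sign > 1e-15:
                t = (sign * self.half_length - x0) / dx
                if 0.0 < t <= 1.0:
                    a, b = a0 + t * da, b0 + t * db
                    if (a / self.r1) ** 2 + (b / self.r2) ** 2 <= 1.0 + 1e-12:
                        hits.append((t, -sign * self.axis))
        # elliptical wall: ((a0+t da)/r1)^2 + ((b0+t db)/r2)^2 = 1
        qa = (da / self.r1) ** 2 + (db / self.r2) ** 2
        qb = 2.0 * (a0 * da / self.r1**2 + b0 * db / self.r2**2)
        qc = (a0 / self.r1) ** 2 + (b0 / self.r2) ** 2 - 1.0
        if qa > 0.0:
            disc = qb * qb - 4.0 * qa * qc
            if disc >= 0.0:
                t = (-qb + math.sqrt(disc)) / (2.0 * qa)
                if 0.0 < t <= 1.0:
                    x = x0 + t * dx
                    if abs(x) <= self.half_length + 1e-9:
                        a, b = a0 + t * da, b0 + t * db
                        n = -(a / self.r1**2) * self.e1 - (b / self.r2**2) * self.e2
                        n /= np.linalg.norm(n)
                        hits.append((t, n))
        if not hits:
            return None
        t, n = min(hits, key=lambda h: h[0])
        return t, p0 + t * d, n


def _reflected_step(confinement, p0, step, max_bounce: int = 16):
    """Advance p0 by `step` with specular reflection; returns (vertices, tangent).

    `vertices` are the polyline points added (bounce points plus the final
    point); `tangent` is the direction of the final leg.
    """
    verts = []
    d = np.asarray(step, dtype=float)
    p = np.asarray(p0, dtype=float)
    for _ in range(max_bounce):
        q = p + d
        if confinement.contains(q):
            verts.append(q)
            nrm = np.linalg.norm(d)
            return verts, d / nrm if nrm > 0 else d
        hit = confinement._first_hit(p, d)
        if hit is None:
            # numerical corner case: pull back toward the seed center
            q = p + 0.5 * d
            verts.append(q)
            return verts, d / np.linalg.norm(d)
        t, h, n = hit
        # nudge the bounce point slightly inward so the next leg starts inside
        h_in = h + 1e-9 * n
        rem = (1.0 - t) * d
        rem = rem - 2.0 * (rem @ n) * n
        if np.linalg.norm(h_in - p) > 1e-12:
            verts.append(h_in)
        p, d = h_in, rem
    verts.append(p)
    return verts, d / max(np.linalg.norm(d), 1e-300)


# ---------------------------------------------------------------------------
# worm-like chains


@dataclass
class WLCParams:
    """Discrete worm-like chain parameters (Kratky-Porod discretization)."""

    segment_length: float = DEFAULT_DS  # ds, nm
    persistence_length: float = 100.0  # Lp, nm
    n_segments: int = 100
    start: tuple = (0.0, 0.0, 0.0)
    initial_direction: object = "isotropic"  # unit vector or "isotropic"

    def __post_init__(self):
        if not (self.segment_length > 0):
            raise ValueError("segment_length must be > 0")
        if not (self.persistence_length > 0):
            raise ValueError("persistence_length must be > 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def _wlc_chain(rng, start, t0, ds, lp, n_segments, confinement=None):
    kappa = lp / ds
    pts = [np.asarray(start, dtype=float)]
    t = np.asarray(t0, dtype=float)
    t = t / np.linalg.norm(t)
    for _ in range(n_segments):
        t = _vmf_step(t, kappa, rng)
        if confinement is None:
            pts.append(pts[-1] + ds * t)
        else:
            verts, t = _reflected_step(confinement, pts[-1], ds * t)
            pts.extend(verts)
    return np.array(pts)


def generate_wlc_filament(params: WLCParams, rng_seed: int, fid: str = "wlc",
                          compartment=Compartment.assembly) -> Filament:
    """One free (unconfined) worm-like chain, reproducible given the seed."""
    rng = np.random.default_rng(rng_seed)
    if isinstance(params.initial_direction, str):
        if params.initial_direction != "isotropic":
            raise ValueError(f"unknown initial_direction {params.initial_direction!r}")
        t0 = sample_isotropic_axes(1, rng)[0]
    else:
        t0 = np.asarray(params.initial_direction, dtype=float)
    pts = _wlc_chain(
        rng, params.start, t0, params.segment_length,
        params.persistence_length, params.n_segments,
    )
    return Filament(fid, pts, compartment)


def estimate_persistence_length(filaments, ds: float, corr_floor: float = 0.2) -> float:
    """Recover Lp from the tangent autocorrelation decay of a set of chains.

    Chains are resampled at arc spacing ``ds``; the mean tangent correlation
    C(k) over all chains and positions is fit as log C = -k ds / Lp (through
    the origin) over lags where C exceeds ``corr_floor``.
    """
    max_n = 0
    sums = None
    counts = None
    for f in filaments:
        pts = resample_polyline(f.points, ds)
        t = np.diff(pts, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n = len(t)
        if n < 2:
            continue
        # FFT autocorrelation, summed over the three tangent components
        m = 1 << int(np.ceil(np.log2(2 * n)))
        F = np.fft.rfft(t, n=m, axis=0)
        ac = np.fft.irfft((F * F.conj()).real.sum(axis=1), n=m)[:n]
        if sums is None or n > max_n:
            new_sums = np.zeros(n)
            new_counts = np.zeros(n)
            if sums is not None:
                new_sums[:max_n] = sums
                new_counts[:max_n] = counts
            sums, counts, max_n = new_sums, new_counts, n
        sums[:n] += ac
        counts[:n] += n - np.arange(n)
    if sums is None:
        raise ValueError("need chains with at least two segments")
    corr = (sums / counts)[1:]
    lags = np.arange(1, max_n, dtype=float)
    use = corr > corr_floor
    use &= np.cumsum(~use) == 0  # contiguous leading run only
    if use.sum() < 2:
        use = np.zeros_like(use)
        use[: max(2, len(use) // 10)] = True
    x = lags[use] * ds
    y = np.log(corr[use])
    slope = float((x @ y) / (x @ x))
    return -1.0 / slope


# ---------------------------------------------------------------------------
# polyline resampling / rasterization


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at fixed arc spacing (final vertex kept)."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1].copy()
    si = np.arange(0.0, total, spacing)
    si = np.append(si, total)
    out = np.column_stack([np.interp(si, s, pts[:, i]) for i in range(3)])
    return out


def _ball_dilate(grid, r, voxel):
    if r <= 0:
        return grid.copy()
    dt = ndimage.distance_transform_edt(~grid, sampling=voxel)
    return dt <= r + 1e-9


def _ball_erode(grid, r, voxel):
    if r <= 0:
        return grid.copy()
    dt = ndimage.distance_transform_edt(grid, sampling=voxel)
    return dt > r


def _ball_close(grid, r, voxel):
    return _ball_erode(_ball_dilate(grid, r, voxel), r, voxel)


def _cropped(grid, margin_vox, fn):
    """Apply a morphology fn inside the foreground bounding box + margin."""
    idx = np.argwhere(grid)
    if len(idx) == 0:
        return grid.copy()
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 1, grid.shape)
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out = np.zeros_like(grid)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = fn(sub)
    return out


@dataclass(frozen=True)
class GridSpec:
    shape: tuple
    voxel_size: float
    origin: tuple

    @classmethod
    def around(cls, lo, hi, voxel):
        lo = np.floor(np.asarray(lo) / voxel) * voxel
        n = np.ceil((np.asarray(hi) - lo) / voxel).astype(int) + 1
        return cls(tuple(int(x) for x in n), float(voxel), tuple(float(x) for x in lo))

    def empty(self, label) -> VoxelMask:
        return VoxelMask(label, np.zeros(self.shape, dtype=bool), self.voxel_size,
                         np.asarray(self.origin))


def rasterize_filaments(filaments, grid: GridSpec, radius: float = 0.0,
                        label=MaskLabel.condensate) -> VoxelMask:
    """Mark voxels whose centers lie on (or within `radius` of) any filament."""
    voxel = grid.voxel_size
    arr = np.zeros(grid.shape, dtype=bool)
    origin = np.asarray(grid.origin)
    shape = np.array(grid.shape)
    for f in filaments:
        pts = resample_polyline(f.points, voxel / 2.0)
        idx = np.rint((pts - origin) / voxel).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        ii = idx[ok]
        arr[ii[:, 0], ii[:, 1], ii[:, 2]] = True
    if radius > 0:
        m = int(np.ceil(radius / voxel)) + 2
        arr = _cropped(arr, m, lambda g: _ball_dilate(g, radius, voxel))
    return VoxelMask(label, arr, voxel, origin)


# ---------------------------------------------------------------------------
# assemblies, nucleoid, points


@dataclass
class AssemblyPreset:
    """Recipe for one filament meshwork and its condensate mask."""

    genotype: Genotype = Genotype.WT
    n_filaments: int = 60
    filament_length: float = 900.0  # nm per chain
    lp_mean: float = 60.0  # nm
    lp_sd: float = 0.0
    confinement: object = field(default_factory=lambda: Sphere((0, 0, 0), 110.0))
    alignment_sigma_deg: float | None = None  # None = isotropic initial axes
    alignment_axis: tuple = (1.0, 0.0, 0.0)
    condensate_dilation_radius: float = 12.0  # nm
    ribosome_exclusion: bool = True
    ds: float = DEFAULT_DS
    filament_radius: float = 2.5  # nm, ~5 nm filament width
    close_radius: float = 16.0  # nm, bridges meshwork pores

    def __post_init__(self):
        self.genotype = Genotype(self.genotype)
        if self.alignment_sigma_deg is not None and not (
            0.0 <= self.alignment_sigma_deg <= 90.0
        ):
            raise ValueError("alignment sigma must be in [0, 90] degrees")
        for name in ("filament_length", "lp_mean", "condensate_dilation_radius", "ds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _initial_directions(n, sigma_deg, axis, rng):
    if sigma_deg is None:
        return sample_isotropic_axes(n, rng)
    if sigma_deg == 0.0:
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        return np.tile(ax, (n, 1))
    kappa = 1.0 / math.radians(sigma_deg) ** 2
    return vmf_directions(axis, kappa, n, rng)


def _generate_bundle(preset: AssemblyPreset, rng, grid: GridSpec | None,
                     compartment, mask_label):
    conf = preset.confinement
    if grid is None:
        lo, hi = conf.bounds()
        pad = preset.close_radius + preset.condensate_dilation_radius + 8.0
        grid = GridSpec.around(lo - pad, hi + pad, DEFAULT_VOXEL_SIZE)
    dirs = _initial_directions(
        preset.n_filaments, preset.alignment_sigma_deg, preset.alignment_axis, rng
    )
    n_seg = max(1, int(round(preset.filament_length / preset.ds)))
    filaments = []
    for i in range(preset.n_filaments):
        lp = preset.lp_mean
        if preset.lp_sd > 0:
            lp = max(2.0 * preset.ds, rng.normal(preset.lp_mean, preset.lp_sd))
        start = conf.sample_point(rng)
        pts = _wlc_chain(rng, start, dirs[i], preset.ds, lp, n_seg, conf)
        filaments.append(Filament(f"{compartment.value}_{i:03d}", pts, compartment))
    raw = rasterize_filaments(filaments, grid, radius=preset.filament_radius,
                              label=mask_label)
    margin = int(np.ceil(
        (preset.close_radius + preset.condensate_dilation_radius) / grid.voxel_size
    )) + 2
    voxel = grid.voxel_size

    def pipeline(g):
        g = _ball_close(g, preset.close_radius, voxel)
        return _ball_dilate(g, preset.condensate_dilation_radius, voxel)

    mask = VoxelMask(mask_label, _cropped(raw.grid, margin, pipeline), voxel,
                     np.asarray(grid.origin))
    return filaments, mask


def generate_assembly(preset: AssemblyPreset, rng_seed: int,
                      grid: GridSpec | None = None):
    """Filament meshwork + condensate mask (raster -> closing -> dilation)."""
    rng = np.random.default_rng(rng_seed)
    return _generate_bundle(preset, rng, grid, Compartment.assembly,
                            MaskLabel.condensate)


def generate_nucleoid(axis, dimensions, sigma_deg: float = 10.0, lp: float = 20000.0,
                      n_filaments: int = 40, rng_seed: int = 0,
                      grid: GridSpec | None = None, center=(0.0, 0.0, 0.0),
                      filament_length: float | None = None):
    """Bundle of near-parallel stiff filaments in an elongated elliptic cylinder.

    ``dimensions`` are full extents (length-along-axis, width1, width2) in nm.
    The default persistence length is far above the confinement width, so
    alignment is maintained along the whole bundle (Odijk deflection regime)
    and the fragment-angle distribution stays narrow.
    """
    length, w1, w2 = dimensions
    conf = EllipticCylinder(center, axis, length / 2.0, w1 / 2.0, w2 / 2.0)
    preset = AssemblyPreset(
        genotype=Genotype.WT,
        n_filaments=n_filaments,
        filament_length=filament_length if filament_length else 4.0 * length / 3.0,
        lp_mean=lp,
        confinement=conf,
        alignment_sigma_deg=sigma_deg,
        alignment_axis=tuple(np.asarray(axis, dtype=float)),
        condensate_dilation_radius=2.5,
        close_radius=16.0,
    )
    rng = np.random.default_rng(rng_seed)
    return _generate_bundle(preset, rng, grid, Compartment.nucleoid,
                            MaskLabel.nucleoid)


@dataclass
class PointProcessParams:
    """Hard-core (RSA) point process on a voxel domain with exclusion zones."""

    intensity: float = 1.8e-5  # points / nm^3
    hard_core_distance: float = 25.0  # nm, ~ribosome diameter
    domain: VoxelMask = None
    exclusion: list = field(default_factory=list)
    label: str = "ribosome"
    max_attempt_factor: int = 100

    def __post_init__(self):
        if self.intensity < 0 or self.hard_core_distance < 0:
            raise ValueError("intensity and hard-core distance must be >= 0")


def generate_points(params: PointProcessParams, rng_seed: int) -> PointSet:
    """Random sequential adsorption inside the domain mask.

    Candidates are uniform over domain voxels (jittered within the voxel),
    rejected when inside an exclusion mask or within the hard-core distance
    of an accepted point.  Stops at ceil(intensity * V_domain) or when the
    attempt budget is exhausted (then returns fewer, with a warning).
    """
    if params.domain is None or params.domain.n_foreground == 0:
        raise ValueError("point process domain mask is empty")
    rng = np.random.default_rng(rng_seed)
    allowed = params.domain.grid.copy()
    for ex in params.exclusion:
        if not params.domain.same_grid(ex):
            raise ValueError("exclusion masks must share the domain grid")
        allowed &= ~ex.grid
    voxel = params.domain.voxel_size
    target = int(np.ceil(params.intensity * params.domain.n_foreground * voxel**3))
    if target == 0:
        return PointSet(params.label, np.empty((0, 3)))
    cand_idx = np.argwhere(allowed)
    if len(cand_idx) == 0:
        warnings.warn("no domain voxels outside exclusion zones; 0 points placed")
        return PointSet(params.label, np.empty((0, 3)))
    origin = params.domain.origin
    d_hc = params.hard_core_distance
    cell = d_hc if d_hc > 0 else voxel
    grid_hash: dict[tuple, list] = {}
    accepted = []
    budget = params.max_attempt_factor * target
    attempts = 0
    d2 = d_hc * d_hc
    while len(accepted) < target and attempts < budget:
        batch = min(4096, budget - attempts)
        picks = cand_idx[rng.integers(0, len(cand_idx), batch)]
        jitter = rng.uniform(-0.5, 0.5, (batch, 3)) * voxel
        pts = origin + voxel * picks + jitter
        for p in pts:
            attempts += 1
            if len(accepted) >= target or attempts > budget:
                break
            key = (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))
            ok = True
            if d_hc > 0:
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            for q in grid_hash.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                                dd = p - q
                                if dd @ dd < d2:
                                    ok = False
                                    break
                            if not ok:
                                break
                        if not ok:
                            break
                    if not ok:
                        break
            if ok:
                accepted.append(p)
                grid_hash.setdefault(key, []).append(p)
    if len(accepted) < target:
        warnings.warn(
            f"RSA under-filled: {len(accepted)}/{target} points after {attempts} attempts"
        )
    return PointSet(params.label, np.array(accepted) if accepted else np.empty((0, 3)))


# ---------------------------------------------------------------------------
# slab cropping (lamella geometry)


def _clip_polyline_z(points, z0, z1):
    """Split a polyline at the slab faces; exact plane intersections."""
    pieces = []
    current = []

    def flush():
        nonlocal current
        if len(current) >= 2:
            pieces.append(np.array(current))
        current = []

    for a, b in zip(points[:-1], points[1:]):
        dz = b[2] - a[2]
        ta, tb = 0.0, 1.0
        # Liang-Barsky on the z interval
        if dz != 0.0:
            t_lo = (z0 - a[2]) / dz
            t_hi = (z1 - a[2]) / dz
            t_enter, t_exit = min(t_lo, t_hi), max(t_lo, t_hi)
            ta, tb = max(ta, t_enter), min(tb, t_exit)
        elif not (z0 <= a[2] <= z1):
            flush()
            continue
        if ta >= tb:
            flush()
            continue
        pa = a + ta * (b - a)
        pb = a + tb * (b - a)
        if ta > 0.0:
            flush()
        if not current:
            current.append(pa)
        if np.linalg.norm(pb - current[-1]) > 1e-12:
            current.append(pb)
        if tb < 1.0:
            flush()
    flush()
    return pieces


def slab_crop(scene: Scene, z0: float, thickness: float) -> Scene:
    """Restrict a scene to the lamella slab z in [z0, z0 + thickness]."""
    if thickness <= 0:
        raise ValueError("slab thickness must be > 0")
    z1 = z0 + thickness
    filaments = []
    for f in scene.filaments:
        pieces = _clip_polyline_z(f.points, z0, z1)
        for j, pts in enumerate(pieces):
            fid = f.id if len(pieces) == 1 else f"{f.id}_{j}"
            filaments.append(Filament(fid, pts, f.compartment))
    points = []
    for ps in scene.points:
        keep = (ps.coords[:, 2] >= z0) & (ps.coords[:, 2] <= z1)
        points.append(PointSet(ps.label, ps.coords[keep]))
    masks = []
    for m in scene.masks:
        zc = m.origin[2] + m.voxel_size * np.arange(m.grid.shape[2])
        keep = (zc >= z0) & (zc <= z1)
        g = m.grid & keep[None, None, :]
        masks.append(VoxelMask(m.label, g, m.voxel_size, m.origin))
    meta = SceneMeta(scene.meta.genotype, (z0, z1), scene.meta.replicate, scene.meta.seed)
    out = Scene(filaments=filaments, points=points, masks=masks, meta=meta)
    if not filaments and all(len(p) == 0 for p in points) and all(
        m.n_foreground == 0 for m in masks
    ):
        warnings.warn("slab is disjoint from the scene: empty scene returned")
    return out


# ---------------------------------------------------------------------------
# whole-scene presets


@dataclass
class ScenePreset:
    """Everything needed to compose one synthetic cell scene."""

    assembly: AssemblyPreset
    nucleoid_gap: float  # nm between nucleoid surface and condensate surface
    cell_radius: float = 340.0
    cell_half_length: float = 460.0
    membrane_thickness: float = 8.0
    nucleoid_dims: tuple = (900.0, 260.0, 260.0)
    nucleoid_center_y: float = -150.0
    nucleoid_sigma_deg: float = 10.0
    nucleoid_lp: float = 20000.0
    nucleoid_n_filaments: int = 40
    ribosome_intensity: float = 1.8e-5
    ribosome_hard_core: float = 25.0
    slab_z0: float = -50.0
    slab_thickness: float = 100.0
    voxel_size: float = DEFAULT_VOXEL_SIZE


def _wt_preset():
    return ScenePreset(
        assembly=AssemblyPreset(
            genotype=Genotype.WT, n_filaments=60, filament_length=900.0,
            lp_mean=60.0, confinement=Sphere((0, 0, 0), 110.0),
            alignment_sigma_deg=None, ribosome_exclusion=True,
        ),
        nucleoid_gap=10.0,
    )


def _dpomz_preset():
    return ScenePreset(
        assembly=AssemblyPreset(
            genotype=Genotype.dPomZ, n_filaments=60, filament_length=1000.0,
            lp_mean=80.0, confinement=Ellipsoid((0, 0, 0), (180.0, 105.0, 105.0)),
            alignment_sigma_deg=None, ribosome_exclusion=True,
        ),
        nucleoid_gap=40.0,
    )


def _dpomy_preset():
    return ScenePreset(
        assembly=AssemblyPreset(
            genotype=Genotype.dPomY, n_filaments=50, filament_length=1200.0,
            lp_mean=350.0, confinement=Ellipsoid((0, 0, 0), (280.0, 95.0, 95.0)),
            alignment_sigma_deg=15.0, alignment_axis=(1.0, 0.0, 0.0),
            ribosome_exclusion=False,
        ),
        nucleoid_gap=65.0,
    )


GENOTYPE_PRESETS = {
    Genotype.WT: _wt_preset,
    Genotype.dPomZ: _dpomz_preset,
    Genotype.dPomY: _dpomy_preset,
}


def _shift_confinement(conf, offset):
    offset = np.asarray(offset, dtype=float)
    if isinstance(conf, EllipticCylinder):
        return EllipticCylinder(conf.center + offset, conf.axis, conf.half_length,
                                conf.r1, conf.r2)
    return Ellipsoid(conf.center + offset, conf.semi)


def generate_scene(genotype, rng_seed: int, preset: ScenePreset | None = None,
                   crop: bool = True) -> Scene:
    """Compose nucleoid + assembly + ribosomes + membrane and slab-crop.

    The assembly sits beside the nucleoid with a genotype-specific surface
    gap (WT smallest, dPomZ intermediate, dPomY largest); ribosome exclusion
    from the condensate is on for WT/dPomZ and off for dPomY.
    """
    genotype = Genotype(genotype)
    if preset is None:
        if genotype not in GENOTYPE_PRESETS:
            raise ValueError(f"no preset for genotype {genotype.value!r}")
        preset = GENOTYPE_PRESETS[genotype]()
    ss = np.random.SeedSequence(rng_seed)
    seed_nuc, seed_asm, seed_pts = (int(s) for s in ss.generate_state(3))

    voxel = preset.voxel_size
    r_out = preset.cell_radius
    half_len = preset.cell_half_length
    grid = GridSpec.around(
        (-half_len, -(r_out + 8), -(r_out + 8)),
        (half_len, r_out + 8, r_out + 8),
        voxel,
    )
    origin = np.asarray(grid.origin)

    # nucleoid bundle along the cell (x) axis
    nuc_center = (0.0, preset.nucleoid_center_y, 0.0)
    nuc_fils, nuc_mask = generate_nucleoid(
        (1.0, 0.0, 0.0), preset.nucleoid_dims, preset.nucleoid_sigma_deg,
        preset.nucleoid_lp, preset.nucleoid_n_filaments, seed_nuc,
        grid=grid, center=nuc_center,
    )

    # assembly placed above the nucleoid with the genotype gap
    asm = preset.assembly
    semi_y = asm.confinement.semi[1] if isinstance(asm.confinement, Ellipsoid) else asm.confinement.r1
    nucleoid_top = preset.nucleoid_center_y + preset.nucleoid_dims[1] / 2.0
    pad = asm.condensate_dilation_radius + asm.filament_radius + voxel / 2.0
    center_y = nucleoid_top + preset.nucleoid_gap + semi_y + pad
    asm = AssemblyPreset(**{**asm.__dict__,
                            "confinement": _shift_confinement(asm.confinement, (0.0, center_y, 0.0))})
    asm_fils, cond_mask = generate_assembly(asm, seed_asm, grid=grid)

    # analytic membrane shell and cytoplasm (cylinder about the x axis)
    yy = origin[1] + voxel * np.arange(grid.shape[1])
    zz = origin[2] + voxel * np.arange(grid.shape[2])
    rho = np.sqrt(yy[:, None] ** 2 + zz[None, :] ** 2)
    r_in = r_out - preset.membrane_thickness
    shell = (rho >= r_in) & (rho <= r_out)
    interior = rho < r_in
    membrane = VoxelMask(MaskLabel.membrane,
                         np.broadcast_to(shell[None], grid.shape).copy(), voxel, origin)
    cytoplasm = VoxelMask(MaskLabel.cytoplasm,
                          np.broadcast_to(interior[None], grid.shape).copy(), voxel, origin)

    exclusion = [nuc_mask]
    if asm.ribosome_exclusion:
        exclusion.append(cond_mask)
    ribosomes = generate_points(
        PointProcessParams(
            intensity=preset.ribosome_intensity,
            hard_core_distance=preset.ribosome_hard_core,
            domain=cytoplasm, exclusion=exclusion,
        ),
        seed_pts,
    )

    scene = Scene(
        filaments=asm_fils + nuc_fils,
        points=[ribosomes],
        masks=[cond_mask, nuc_mask, membrane, cytoplasm],
        meta=SceneMeta(genotype=genotype, seed=rng_seed),
    )
    if crop:
        scene = slab_crop(scene, preset.slab_z0, preset.slab_thickness)
    return scene
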