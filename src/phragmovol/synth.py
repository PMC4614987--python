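"""Synthetic chamber series and planispiral conchs with known ground truth.

Growth series follow the three-parameter logistic that chambered
cephalopod volumes trace through ontogeny,

    V_i = K / (1 + exp(-r (i - m))),

with three departures that real conchs show: a distinct (steeper)
embryonic log-slope before a breakpoint chamber, a multiplicative
terminal decline over the last few chambers (the "terminal countdown"),
and multiplicative lognormal measurement noise.  Default parameters are
chosen to emulate a mature modern *Nautilus*: volumes spanning ~0.001
to ~25 ml over ~32 chambers, an embryonic regime through chamber 5,
a single declining final chamber, and ~15% (log-scale) measurement
scatter.

The 3D generator produces planispiral shells — a circular or elliptical
tube swept along a logarithmic spiral, partitioned into chambers by
planar radial septa — as watertight triangle meshes, together with
ground-truth chamber volumes from numerical integration of the exact
solid of revolution (with a refinement-convergence report).  This gives
the volumetric layer an independent oracle that does not depend on
meshes or voxels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .fixtures import ChamberSeries
from .volumetrics import GeometryError, VolumeStack

__all__ = [
    "SeriesParams",
    "ShellParams",
    "ShellModel",
    "logistic_volume",
    "simulate_series",
    "simulate_cohort",
    "generate_shell",
    "voxelize",
]


@dataclass(frozen=True)
class SeriesParams:
    """Parameters of the synthetic chamber-volume series.

    K, r, m are the logistic asymptote (series volume unit), rate per
    chamber, and midpoint chamber.  ``embryo_break`` (b0) is the last
    chamber of the embryonic regime: chambers i <= b0 lie on a log-linear
    segment whose slope is ``embryo_slope_factor`` times the logistic
    log-slope at b0, anchored so that chamber b0 takes exactly the
    logistic value (the two regimes meet at b0).  The last
    ``countdown_k`` chambers are multiplied by successive powers of
    ``countdown_decay``.  Noise multiplies every volume by
    exp(noise_sigma * z), z standard normal.
    """

    K: float = 35.0
    r: float = 0.2
    m: float = 30.0
    embryo_break: int = 5
    embryo_slope_factor: float = 6.0
    countdown_k: int = 1
    countdown_decay: float = 0.85
    noise_sigma: float = 0.15
    n_chambers: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0:
            raise ValueError("K and r must be positive")
        if self.n_chambers < 1:
            raise ValueError("n_chambers must be >= 1")
        if not 0 <= self.countdown_k < self.n_chambers:
            raise ValueError("countdown_k must satisfy 0 <= countdown_k < n_chambers")
        if self.countdown_k and not 0 < self.countdown_decay < 1:
            raise ValueError("countdown_decay must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.embryo_break < 0:
            raise ValueError("embryo_break must be >= 0")
        if self.embryo_break and self.embryo_slope_factor <= 0:
            raise ValueError("embryo_slope_factor must be positive")


def logistic_volume(i, K: float, r: float, m: float):
    """The logistic growth curve V_i = K / (1 + exp(-r (i - m)))."""
    i = np.asarray(i, dtype=float)
    return K / (1.0 + np.exp(-r * (i - m)))


def _noiseless_volumes(p: SeriesParams) -> np.ndarray:
    i = np.arange(1, p.n_chambers + 1, dtype=float)
    v = logistic_volume(i, p.K, p.r, p.m)
    if p.embryo_break >= 1:
        b0 = float(p.embryo_break)
        v_b0 = float(logistic_volume(b0, p.K, p.r, p.m))
        # log-slope of the logistic at b0: d log V / di = r (1 - V/K)
        slope = p.embryo_slope_factor * p.r * (1.0 - v_b0 / p.K)
        pre = i <= b0
        v[pre] = v_b0 * np.exp(-slope * (b0 - i[pre]))
    if p.countdown_k:
        onset = p.n_chambers - p.countdown_k
        tail = i > onset
        v[tail] = v[tail] * p.countdown_decay ** (i[tail] - onset)
    return v


def simulate_series(params: SeriesParams, specimen_id: str = "synthetic") -> ChamberSeries:
    """Generate one synthetic chamber-volume series (unit: ml).

    Fully reproducible from ``params.seed``; with ``noise_sigma=0``,
    ``countdown_k=0`` and ``embryo_break=0`` every volume equals the
    closed-form logistic value exactly.
    """
    v = _noiseless_volumes(params)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        v = v * np.exp(params.noise_sigma * rng.standard_normal(len(v)))
    return ChamberSeries(
        specimen_id=specimen_id,
        volume_unit="ml",
        chambers=np.arange(1, params.n_chambers + 1),
        volumes=v,
        widths_mm=np.full(params.n_chambers, np.nan),
    )


def simulate_cohort(
    params_male: SeriesParams,
    params_female: SeriesParams,
    n_male: int,
    n_female: int,
    seed: int,
) -> list[tuple[ChamberSeries, str]]:
    """Generate a sex-labeled cohort of synthetic series.

    Per-specimen seeds are derived deterministically from ``seed`` via a
    seed sequence, so the cohort is reproducible and individual series
    are statistically independent.
    """
    if n_male < 1 or n_female < 1:
        raise ValueError("need at least one specimen per sex")
    sub = np.random.SeedSequence(seed).generate_state(n_male + n_female) & 0x7FFFFFFF
    out = []
    for j in range(n_male):
        p = dataclasses.replace(params_male, seed=int(sub[j]))
        out.append((simulate_series(p, specimen_id=f"M{j + 1:02d}"), "male"))
    for j in range(n_female):
        p = dataclasses.replace(params_female, seed=int(sub[n_male + j]))
        out.append((simulate_series(p, specimen_id=f"F{j + 1:02d}"), "female"))
    return out


# ---------------------------------------------------------------------------
# 3D planispiral shells

@dataclass(frozen=True)
class ShellParams:
    """Geometry of a synthetic planispiral conch.

    The tube centre line is the logarithmic spiral
    d(theta) = initial_radius * whorl_expansion**(theta / 2 pi) in the
    coiling plane z = 0; the coiling axis is z.  The aperture is a
    circle (or ellipse with height ratio ``aperture_b_over_a``) of
    radius ``aperture_fraction * d(theta)``, lying in the radial
    half-plane at angle theta, so the conch is self-similar.  Planar
    radial septa every ``septal_angle_deg`` partition the tube into
    ``n_chambers`` chambers.  ``translation`` must stay 0 (planispiral);
    it is exposed only so that the coiling mode is explicit.
    """

    whorl_expansion: float = 2.0
    translation: float = 0.0
    initial_radius: float = 5.0
    aperture_shape: str = "circle"  # "circle" | "ellipse"
    aperture_b_over_a: float = 1.0
    aperture_fraction: float = 0.25
    septal_angle_deg: float = 45.0
    n_chambers: int = 12
    mesh_theta_steps: int = 24  # theta subdivisions per chamber
    mesh_n_phi: int = 48  # vertices around the aperture

    def __post_init__(self) -> None:
        if self.whorl_expansion <= 1:
            raise GeometryError("whorl_expansion must be > 1")
        if self.translation != 0.0:
            raise GeometryError("only planispiral shells (translation = 0) are supported")
        if self.initial_radius <= 0 or self.septal_angle_deg <= 0:
            raise GeometryError("initial_radius and septal_angle_deg must be positive")
        if self.n_chambers < 1:
            raise GeometryError("n_chambers must be >= 1")
        if not 0 < self.aperture_fraction < 1:
            raise GeometryError("aperture_fraction must lie in (0, 1)")
        if self.aperture_shape not in ("circle", "ellipse"):
            raise GeometryError(f"unknown aperture_shape {self.aperture_shape!r}")
        if self.aperture_b_over_a <= 0:
            raise GeometryError("aperture_b_over_a must be positive")
        # successive whorls must not interpenetrate:
        # gap between centre lines one revolution apart is d (W - 1);
        # the tubes occupy f*d and f*d*W of it
        W, f = self.whorl_expansion, self.aperture_fraction
        if f * (1.0 + W) >= (W - 1.0):
            raise GeometryError(
                "self-intersecting geometry: aperture_fraction "
                f"{f} too large for whorl_expansion {W} "
                f"(requires f < (W-1)/(W+1) = {(W - 1) / (W + 1):.3f})"
            )


@dataclass
class ShellModel:
    """Generated shell: one watertight mesh per chamber plus ground truth."""

    params: ShellParams
    meshes: list[trimesh.Trimesh]
    ground_truth_volumes: np.ndarray
    #: per-refinement integration results: {"steps": [...], "volumes": [...],
    #: "max_rel_change": float} — the last refinement's relative change
    convergence: dict


def _b_over_a(p: ShellParams) -> float:
    return p.aperture_b_over_a if p.aperture_shape == "ellipse" else 1.0


def _chamber_mesh(p: ShellParams, theta0: float, theta1: float) -> trimesh.Trimesh:
    """Watertight tube segment between two radial septal half-planes."""
    n_t, n_phi = p.mesh_theta_steps, p.mesh_n_phi
    beta = _b_over_a(p)
    thetas = np.linspace(theta0, theta1, n_t + 1)
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)

    d = p.initial_radius * p.whorl_expansion ** (thetas / (2.0 * np.pi))
    a = p.aperture_fraction * d
    # ring vertices: rows = theta stations, cols = phi
    radial = d[:, None] + a[:, None] * np.cos(phis)[None, :]
    verts = np.empty((n_t + 1, n_phi, 3))
    verts[:, :, 0] = radial * np.cos(thetas)[:, None]
    verts[:, :, 1] = radial * np.sin(thetas)[:, None]
    verts[:, :, 2] = beta * a[:, None] * np.sin(phis)[None, :]
    V = verts.reshape(-1, 3)

    def vid(j, k):
        return j * n_phi + (k % n_phi)

    faces = []
    for j in range(n_t):
        for k in range(n_phi):
            # outward-oriented quad split into two triangles
            faces.append([vid(j, k), vid(j + 1, k), vid(j + 1, k + 1)])
            faces.append([vid(j, k), vid(j + 1, k + 1), vid(j, k + 1)])
    # septal end caps: triangle fans about the aperture centres
    c0 = len(V)
    c1 = len(V) + 1
    centers = np.array(
        [
            [d[0] * np.cos(thetas[0]), d[0] * np.sin(thetas[0]), 0.0],
            [d[-1] * np.cos(thetas[-1]), d[-1] * np.sin(thetas[-1]), 0.0],
        ]
    )
    V = np.vstack([V, centers])
    for k in range(n_phi):
        faces.append([c0, vid(0, k), vid(0, k + 1)])
        faces.append([c1, vid(n_t, k + 1), vid(n_t, k)])
    mesh = trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _septal_moment(p: ShellParams, theta: float) -> float:
    """Integrand of the solid-of-revolution volume: area x centroid radius.

    A cross-section at angle theta is an ellipse of semi-axes
    a = f d and b = beta a centred at radius d, so its first radial
    moment is pi a b d.
    """
    d = p.initial_radius * p.whorl_expansion ** (theta / (2.0 * np.pi))
    a = p.aperture_fraction * d
    return float(np.pi * a * (a * _b_over_a(p)) * d)


def _integrate_volumes(p: ShellParams, n_steps: int) -> np.ndarray:
    """Composite-Simpson chamber volumes with n_steps panels per chamber."""
    dtheta = np.radians(p.septal_angle_deg)
    out = np.empty(p.n_chambers)
    for ell in range(p.n_chambers):
        t0, t1 = ell * dtheta, (ell + 1) * dtheta
        ts = np.linspace(t0, t1, 2 * n_steps + 1)
        g = np.array([_septal_moment(p, t) for t in ts])
        h = (t1 - t0) / (2 * n_steps)
        out[ell] = h / 3.0 * (g[0] + g[-1] + 4 * g[1:-1:2].sum() + 2 * g[2:-2:2].sum())
    return out


def generate_shell(params: ShellParams, refinements: int = 3) -> ShellModel:
    """Generate the chamber meshes and integration ground truth.

    Ground-truth volumes come from numerically integrating the radial
    first moment of the aperture cross-section over each chamber's
    angular extent (the exact volume of the smooth solid between two
    septa).  The integration is repeated at ``refinements`` step sizes,
    each halving the previous step, and the relative change of the last
    refinement is reported as the convergence diagnostic.
    """
    dtheta = np.radians(params.septal_angle_deg)
    meshes = [
        _chamber_mesh(params, ell * dtheta, (ell + 1) * dtheta)
        for ell in range(params.n_chambers)
    ]
    steps, volumes = [], []
    n = 8
    for _ in range(max(2, refinements)):
        steps.append(n)
        volumes.append(_integrate_volumes(params, n))
        n *= 2
    last, prev = volumes[-1], volumes[-2]
    max_rel_change = float(np.max(np.abs(last - prev) / last))
    convergence = {
        "panels_per_chamber": steps,
        "volumes": [v.tolist() for v in volumes],
        "max_rel_change": max_rel_change,
    }
    return ShellModel(
        params=params,
        meshes=meshes,
        ground_truth_volumes=last,
        convergence=convergence,
    )


# ---------------------------------------------------------------------------
# voxelization

def _scanline_mask(mesh: trimesh.Trimesh, zs, ys, xs) -> np.ndarray:
    """Rasterize a closed mesh on a voxel-centre grid by x-ray parity.

    One ray per (z, y) row, cast along +x; voxel centres between odd and
    even surface crossings are inside.  Crossings are found per triangle
    by a barycentric point-in-triangle test of the ray's (y, z)
    coordinates against the triangle's (y, z) projection.  Ray
    coordinates are offset by tiny irrational fractions of the grid
    spacing so that rays through shared edges or vertices (which would
    break the crossing parity) have measure zero.
    """
    nz, ny, nx = len(zs), len(ys), len(xs)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    dy = ys[1] - ys[0] if ny > 1 else 1.0
    dz = zs[1] - zs[0] if nz > 1 else 1.0
    ry = ys + 1e-4 * dy * np.sqrt(2.0)
    rz = zs + 1e-4 * dz * np.sqrt(3.0)

    tri = mesh.vertices[mesh.faces]  # (n_tri, 3 vertices, xyz)
    crossings: dict[tuple[int, int], list[float]] = {}
    for p0, p1, p2 in tri:
        # 2D projection onto the (y, z) plane seen along the ray
        ay, az = p0[1], p0[2]
        by, bz = p1[1], p1[2]
        cy, cz = p2[1], p2[2]
        det = (by - ay) * (cz - az) - (cy - ay) * (bz - az)
        if abs(det) < 1e-14:
            continue  # triangle parallel to the ray; neighbours carry the parity
        ylo, yhi = min(ay, by, cy), max(ay, by, cy)
        zlo, zhi = min(az, bz, cz), max(az, bz, cz)
        jy = np.nonzero((ry >= ylo) & (ry <= yhi))[0]
        jz = np.nonzero((rz >= zlo) & (rz <= zhi))[0]
        if not len(jy) or not len(jz):
            continue
        Y, Z = np.meshgrid(ry[jy], rz[jz], indexing="ij")
        v = ((Y - ay) * (cz - az) - (cy - ay) * (Z - az)) / det
        w = ((by - ay) * (Z - az) - (Y - ay) * (bz - az)) / det
        u = 1.0 - v - w
        inside = (u >= 0.0) & (v >= 0.0) & (w >= 0.0)
        if not inside.any():
            continue
        xhit = u * p0[0] + v * p1[0] + w * p2[0]
        ii, kk = np.nonzero(inside)
        for a, b in zip(ii, kk):
            crossings.setdefault((int(jz[b]), int(jy[a])), []).append(float(xhit[a, b]))
    for (iz, iy), hits in crossings.items():
        hits = np.sort(hits)
        if len(hits) % 2:
            hits = hits[:-1]  # grazing contact; drop the unpaired crossing
        for lo, hi in zip(hits[0::2], hits[1::2]):
            sel = (xs > lo) & (xs < hi)
            mask[iz, iy, sel] = True
    return mask


def voxelize(
    meshes: list[trimesh.Trimesh],
    voxel_dims: tuple[float, float, float],
    margin_voxels: int = 1,
) -> VolumeStack:
    """Rasterize closed chamber meshes into a labeled stack.

    ``voxel_dims`` is (dz, dy, dx) in the mesh length unit and may be
    anisotropic.  Chamber ``l`` (1-based position in ``meshes``) is
    written as label ``l``; labels are disjoint — a voxel centre claimed
    by two meshes (possible only on shared septal surfaces) keeps the
    first label.
    """
    dz, dy, dx = (float(d) for d in voxel_dims)
    if min(dz, dy, dx) <= 0:
        raise ValueError(f"voxel dims must be positive, got {voxel_dims}")
    if not meshes:
        raise ValueError("no meshes to voxelize")
    lo = np.min([m.bounds[0] for m in meshes], axis=0)  # (x, y, z)
    hi = np.max([m.bounds[1] for m in meshes], axis=0)

    def centers(a, b, d):
        n = max(1, int(np.ceil((b - a) / d)) + 2 * margin_voxels)
        start = 0.5 * (a + b) - 0.5 * n * d + 0.5 * d
        return start + d * np.arange(n)

    xs, ys, zs = centers(lo[0], hi[0], dx), centers(lo[1], hi[1], dy), centers(lo[2], hi[2], dz)
    labels = np.zeros((len(zs), len(ys), len(xs)), dtype=np.int32)
    for ell, mesh in enumerate(meshes, start=1):
        inside = _scanline_mask(mesh, zs, ys, xs)
        labels[inside & (labels == 0)] = ell
    return VolumeStack(labels=labels, voxel_dims=(dz, dy, dx))
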