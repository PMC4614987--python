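"""Volume and width measurement from meshes and labeled voxel stacks.

Two measurement routes are supported, mirroring how chambered-conch
volumes are obtained in practice: (1) watertight triangulated surfaces
(one mesh per chamber, typically exported from segmentation software as
STL), measured by signed-tetrahedron summation; and (2) labeled voxel
stacks with anisotropic physical voxel dimensions, measured by exact
voxel counting.  Slice subsampling emulates tomographic workflows in
which only every k-th section is segmented.  A small buoyancy model
computes the cameral-liquid fill fraction needed for neutral buoyancy.

Axis convention: stacks are indexed (z, y, x); voxel_dims are
(dz, dy, dx) in mm; the coiling axis of a planispiral conch is the
stack z axis unless stated otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage

__all__ = [
    "VolumeStack",
    "BuoyancyInputs",
    "FillFractionResult",
    "MeshError",
    "GeometryError",
    "mesh_volume",
    "voxel_volumes",
    "label_chambers",
    "subsample_slices",
    "measure_width",
    "shell_volume_bounds",
    "neutral_fill_fraction",
    "load_mesh",
    "save_mesh",
    "load_stack",
    "save_stack",
]


class MeshError(ValueError):
    """A mesh violates the preconditions of a volumetric operation."""


class GeometryError(ValueError):
    """Degenerate or self-intersecting generated geometry."""


@dataclass
class VolumeStack:
    """A labeled 3D voxel array with physical voxel dimensions.

    ``labels`` is (z, y, x); 0 is background, labels 1..n are chambers
    in ontogenetic order.  ``voxel_dims`` is (dz, dy, dx) in mm and may
    be anisotropic.
    """

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, mm^3."""
        dz, dy, dx = self.voxel_dims
        return dz * dy * dx

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


# ---------------------------------------------------------------------------
# mesh volumetry

def _as_mesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Trimesh):
        return mesh
    return trimesh.Trimesh(vertices=np.asarray(mesh[0]), faces=np.asarray(mesh[1]), process=False)


def _signed_volume(mesh: trimesh.Trimesh) -> float:
    """Signed volume by the divergence theorem over triangles."""
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def mesh_volume(mesh) -> float:
    """Enclosed volume of a watertight triangulated surface, in mesh units^3.

    The volume is the sum of signed tetrahedra (origin, triangle),
    which is exact for closed, consistently oriented surfaces and
    independent of rigid motion.  The absolute value is returned, so the
    global orientation (inward vs. outward normals) does not matter.
    A file holding several disjoint closed components yields the sum of
    the component volumes.

    Raises :class:`MeshError` for non-watertight input, naming the
    number of open (boundary) edges.
    """
    mesh = _as_mesh(mesh)
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise MeshError(
            f"mesh is not watertight: {n_open} edges are not shared by exactly "
            "2 triangles"
        )
    bodies = mesh.split(only_watertight=True) if mesh.body_count > 1 else [mesh]
    return float(sum(abs(_signed_volume(b)) for b in bodies))


# ---------------------------------------------------------------------------
# voxel volumetry

def voxel_volumes(stack: VolumeStack, labels=None) -> dict[int, float]:
    """Physical volume per label: count(label) x dz*dy*dx, exactly.

    Returns a dict over labels 1..max (or the requested ``labels``);
    labels absent from the stack map to 0.0.
    """
    counts = np.bincount(stack.labels.ravel())
    if labels is None:
        labels = range(1, max(stack.n_labels, 0) + 1)
    vv = stack.voxel_volume
    return {
        int(l): (float(counts[l]) * vv if l < len(counts) else 0.0) for l in labels
    }


def _spiral_order(centroids: np.ndarray, coiling_axis: int) -> np.ndarray:
    """Ontogenetic ordering of chamber centroids about the coiling axis.

    Chambers of a planispiral conch lie along a spiral whose angular
    position increases monotonically through ontogeny.  Starting from
    the centroid closest to the axis, the ordering repeatedly takes the
    component with the smallest positive angular advance; ties break
    toward the smaller radius.  Valid whenever successive chambers are
    separated by less than a full revolution (always true for septate
    conchs).
    """
    planar_axes = [a for a in range(3) if a != coiling_axis]
    origin = centroids.mean(axis=0)
    rel = centroids[:, planar_axes] - origin[planar_axes]
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    rho = np.hypot(rel[:, 0], rel[:, 1])

    n = len(centroids)
    start = min(range(n), key=lambda i: (rho[i], theta[i]))

    def walk(sign: float) -> np.ndarray:
        remaining = list(range(n))
        order = [start]
        remaining.remove(start)
        while remaining:
            cur = order[-1]
            nxt = min(
                remaining,
                key=lambda i: ((sign * (theta[i] - theta[cur])) % (2 * np.pi), rho[i]),
            )
            order.append(nxt)
            remaining.remove(nxt)
        return np.array(order)

    # the conch may coil either way about the axis; keep the direction in
    # which the spiral radius grows most consistently
    candidates = [walk(+1.0), walk(-1.0)]
    scores = [int((np.diff(rho[o]) > 0).sum()) for o in candidates]
    return candidates[int(np.argmax(scores))]


#: 6-connectivity: thin septa must separate chambers, and 26-connectivity
#: would bridge across voxel corners
_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


def label_chambers(binary_stack, voxel_dims, coiling_axis: int = 0) -> VolumeStack:
    """Label connected chamber regions of a binary mask in ontogenetic order.

    Components are found under 6-connectivity and relabeled 1..n by
    increasing spiral angle of their centroids about the coiling axis
    (default: stack z axis).  Background stays 0.
    """
    mask = np.asarray(binary_stack).astype(bool)
    if mask.ndim != 3:
        raise ValueError("binary stack must be 3D (z, y, x)")
    raw, n = ndimage.label(mask, structure=_STRUCTURE_6)
    if n == 0:
        raise ValueError("no chamber components found in the binary stack")
    dims = np.asarray(voxel_dims, dtype=float)
    centroids_idx = np.array(ndimage.center_of_mass(mask, raw, index=range(1, n + 1)))
    centroids_mm = centroids_idx * dims  # physical coordinates, (z, y, x) order
    order = _spiral_order(centroids_mm, coiling_axis)
    relabel = np.zeros(n + 1, dtype=raw.dtype)
    relabel[order + 1] = np.arange(1, n + 1)
    return VolumeStack(labels=relabel[raw], voxel_dims=tuple(dims))


def subsample_slices(
    stack: VolumeStack, k: int, offset: int = 0
) -> tuple[VolumeStack, dict[int, float]]:
    """Keep every k-th z slice and estimate volumes by slab extrusion.

    Emulates segmenting only every k-th tomographic section: the reduced
    stack has slice spacing k*dz and each retained slice stands for a
    slab of k original slices (zeroth-order extrusion; no interpolation,
    matching the tomographic workflow being modeled).  ``offset`` picks
    which of the k interleaved slice subsets is kept.
    """
    k = int(k)
    nz = stack.labels.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > nz:
        raise ValueError(f"k={k} exceeds the number of slices ({nz})")
    if not 0 <= offset < k:
        raise ValueError(f"offset must lie in [0, k), got {offset}")
    dz, dy, dx = stack.voxel_dims
    reduced = VolumeStack(
        labels=stack.labels[offset::k].copy(), voxel_dims=(k * dz, dy, dx)
    )
    return reduced, voxel_volumes(reduced, labels=range(1, stack.n_labels + 1))


def measure_width(stack: VolumeStack, label: int, axis: int = 0) -> float:
    """Physical extent of a label along the coiling axis, in mm.

    Width is the axis-aligned occupied extent: (index span + 1) voxels
    times the voxel dimension along that axis.  For a planispiral conch
    the coiling axis is perpendicular to the plane of symmetry.
    """
    hits = np.any(
        stack.labels == label,
        axis=tuple(a for a in range(3) if a != axis),
    )
    idx = np.nonzero(hits)[0]
    if not len(idx):
        raise ValueError(f"label {label} not present in the stack")
    return float((idx[-1] - idx[0] + 1) * stack.voxel_dims[axis])


# ---------------------------------------------------------------------------
# mass / buoyancy

def shell_volume_bounds(
    mass_g: float, density_range: tuple[float, float] = (2.54, 2.62)
) -> tuple[float, float]:
    """Bounds on shell volume (cm^3) from shell mass and aragonite density.

    Given the plausible range of shell density (default 2.54-2.62
    g/cm^3 for nautilid aragonite), the volume lies in
    [mass/rho_max, mass/rho_min].
    """
    if mass_g < 0:
        raise ValueError(f"mass must be >= 0, got {mass_g}")
    lo, hi = sorted(density_range)
    if lo <= 0:
        raise ValueError("densities must be positive")
    return (mass_g / hi, mass_g / lo)


@dataclass(frozen=True)
class BuoyancyInputs:
    """Volumes (cm^3) and densities (g/cm^3) entering the buoyancy balance."""

    shell_volume: float
    soft_body_volume: float
    cameral_volume: float
    shell_density: float = 2.58
    soft_density: float = 1.06
    liquid_density: float = 1.025
    seawater_density: float = 1.025

    def __post_init__(self) -> None:
        for name in ("shell_volume", "soft_body_volume", "cameral_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("shell_density", "soft_density", "liquid_density", "seawater_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FillFractionResult:
    """Cameral-liquid fill fraction for neutral buoyancy.

    ``status`` is "ok" when the fraction lies in [0, 1];
    "negative" when the animal sinks even with empty chambers
    (required fraction < 0); "exceeds_one" when neutrality is out of
    reach even with flooded chambers (required fraction > 1); and
    "undefined" when there is no cameral volume to fill yet the body is
    not neutral.  The raw solution is reported instead of being clamped.
    """

    fraction: float
    status: str
    residual: float


def neutral_fill_fraction(b: BuoyancyInputs) -> FillFractionResult:
    """Solve the mass balance for the neutral-buoyancy fill fraction.

    Neutrality requires

        m_shell + m_soft + f * V_cam * rho_liquid
            = rho_sw * (V_shell + V_soft + V_cam)

    i.e. total mass equals the mass of displaced seawater.  The returned
    residual is the balance mismatch at the reported fraction, relative
    to the displaced mass.
    """
    dry_mass = b.shell_volume * b.shell_density + b.soft_body_volume * b.soft_density
    displaced = b.seawater_density * (
        b.shell_volume + b.soft_body_volume + b.cameral_volume
    )
    liquid_capacity = b.cameral_volume * b.liquid_density
    needed = displaced - dry_mass
    if liquid_capacity == 0.0:
        if needed == 0.0:
            return FillFractionResult(0.0, "ok", 0.0)
        return FillFractionResult(math_inf_sign(needed), "undefined", abs(needed) / max(displaced, 1e-300))
    f = needed / liquid_capacity
    residual = abs(dry_mass + f * liquid_capacity - displaced) / max(displaced, 1e-300)
    if f < 0:
        status = "negative"
    elif f > 1:
        status = "exceeds_one"
    else:
        status = "ok"
    return FillFractionResult(float(f), status, float(residual))


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


# ---------------------------------------------------------------------------
# file I/O

def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL (ASCII or binary) as a single mesh."""
    mesh = trimesh.load(str(path), force="mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as binary STL."""
    _as_mesh(mesh).export(str(path))


def save_stack(stack: VolumeStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) records voxel dimensions in mm and the
    axis order, which TIFF alone does not carry reliably.
    """
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), stack.labels.astype(np.uint16))
    sidecar = {
        "voxel_dims_mm": list(stack.voxel_dims),
        "axis_order": "zyx",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_stack(path: str | Path) -> VolumeStack:
    """Read a multi-page TIFF stack and its JSON sidecar."""
    import tifffile

    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing voxel-dimension sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("axis_order", "zyx") != "zyx":
        raise ValueError(f"unsupported axis order {meta.get('axis_order')!r}")
    labels = tifffile.imread(str(path)).astype(np.int32)
    if labels.ndim == 2:
        labels = labels[None]
    return VolumeStack(labels=labels, voxel_dims=tuple(meta["voxel_dims_mm"]))
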