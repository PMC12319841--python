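"""Voxel-mesh phantoms of randomly placed infinite cylinders.

A phantom is a 3D integer substrate-label array plus a 3D off-resonance map
(Tesla, computed at B0 = 1 T) on a regular grid covering a physical field of
view.  Cylinders model blood vessels: the susceptibility difference between
(partly deoxygenated) blood and tissue perturbs the field around each vessel.
For an infinite cylinder the perturbation has a closed form:

    dBz = 2*pi*B0*(1-Y)*dchi * (R/r)^2 * cos(2*phi) * sin^2(theta)   r >= R
    dBz = 2*pi*B0*(1-Y)*dchi * (cos^2(theta) - 1/3)                  r <  R

with R the cylinder radius, r the perpendicular distance to the axis, theta
the angle between axis and B0, phi the azimuth of the field point measured
from the projection of B0 onto the plane orthogonal to the axis, Y the blood
oxygenation fraction and dchi the susceptibility difference between fully
deoxygenated blood and tissue in cgs units (the 2*pi prefactor absorbs the
cgs->field conversion; dchi_SI = 4*pi*dchi_cgs).

An independent finite-perturber (FFT dipole-kernel convolution) field solver
is provided for validation of the analytic map.

Voxel convention: voxel (i,j,k) covers the half-open box
[i*vox_x, (i+1)*vox_x) x ... ; fields are evaluated at voxel centers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder: a point on the axis, a unit direction, a radius (um)."""

    point: np.ndarray
    direction: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("cylinder direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        if not self.radius > 0:
            raise ValueError("cylinder radius must be positive")

    @property
    def theta(self) -> float:
        """Angle between the cylinder axis and B0 (z), in [0, pi/2]."""
        return float(np.arccos(min(1.0, abs(self.direction[2]))))


@dataclass(frozen=True)
class FieldParams:
    """Physical parameters of the susceptibility field.

    b0 in Tesla (phantom maps are conventionally generated at 1 T and scaled
    at run time), y the blood oxygenation fraction in [0, 1] (1 = fully
    oxygenated, so (1-y) scales the perturbation), delta_chi the
    blood-tissue susceptibility difference in cgs units (0.11 ppm default),
    theta an optional override of the axis-to-B0 angle (radians); when None
    the angle is derived from the cylinder geometry.
    """

    b0: float = 1.0
    y: float = 0.0
    delta_chi: float = 0.11e-6
    theta: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.y <= 1.0:
            raise ValueError("oxygenation fraction y must lie in [0, 1]")
        if self.delta_chi < 0:
            raise ValueError("delta_chi must be non-negative")


@dataclass
class VoxelPhantom:
    """Substrate labels + off-resonance map on a regular grid.

    substrate: 3D integer array, labels in [0, n_substrates)
    db0:       3D float array, Tesla at B0 = 1 T, same shape
    fov:       physical box size, um, 3-vector
    attrs:     free-form metadata persisted to HDF5 (seed, bvf, ...)
    """

    substrate: np.ndarray
    db0: np.ndarray
    fov: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.substrate = np.asarray(self.substrate)
        if not np.issubdtype(self.substrate.dtype, np.integer):
            raise ValueError("substrate labels must be integers")
        self.db0 = np.asarray(self.db0)
        self.fov = np.asarray(self.fov, dtype=float)
        if self.substrate.ndim != 3:
            raise ValueError("substrate must be a 3D array")
        if self.db0.shape != self.substrate.shape:
            raise ValueError("substrate and db0 must have identical shapes")
        if self.fov.shape != (3,) or not np.all(self.fov > 0):
            raise ValueError("fov must be three positive lengths (um)")
        if not np.all(np.isfinite(self.db0)):
            raise ValueError("db0 must be finite everywhere")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.substrate.shape)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths of one voxel, um."""
        return self.fov / self.grid

    @property
    def n_substrates(self) -> int:
        return int(self.substrate.max()) + 1


def _voxel_centers(fov, grid):
    fov = np.asarray(fov, dtype=float)
    grid = np.asarray(grid, dtype=int)
    axes = [((np.arange(g) + 0.5) * f / g).astype(np.float32) for g, f in zip(grid, fov)]
    return np.meshgrid(*axes, indexing="ij")


def _grid_r2_q(fov, grid, cyl: Cylinder, need_q: bool):
    """Perpendicular distance^2 (and B0-projection dot) on the voxel grid.

    Exploits separability: with d = x - p expressed per axis, both
    t = d . u and q = d . e1 are sums of three 1D terms, so only two or three
    full-grid broadcast operations are needed per cylinder.
    """
    fov = np.asarray(fov, dtype=float)
    grid = np.asarray(grid, dtype=int)
    u = cyl.direction
    dax = [
        (((np.arange(g) + 0.5) * f / g) - p).astype(np.float32)
        for g, f, p in zip(grid, fov, cyl.point)
    ]
    shapes = [(-1, 1, 1), (1, -1, 1), (1, 1, -1)]
    t = sum(
        (d * np.float32(u[i])).reshape(shapes[i]) for i, d in enumerate(dax)
    )
    d2 = sum((d * d).reshape(shapes[i]) for i, d in enumerate(dax))
    r2 = d2 - t * t
    np.maximum(r2, 0.0, out=r2)
    if not need_q:
        return r2, None
    e1 = np.array([0.0, 0.0, 1.0]) - u[2] * u
    n = np.linalg.norm(e1)
    if n < 1e-12:
        return r2, np.zeros_like(r2)
    e1 = e1 / n
    q = sum((d * np.float32(e1[i])).reshape(shapes[i]) for i, d in enumerate(dax))
    return r2, q


def _perp_geometry(X, Y, Z, cyl: Cylinder):
    """Perpendicular distance^2 to the axis and the in-plane B0-projection dot."""
    u = cyl.direction
    dx = X - np.float32(cyl.point[0])
    dy = Y - np.float32(cyl.point[1])
    dz = Z - np.float32(cyl.point[2])
    t = dx * np.float32(u[0]) + dy * np.float32(u[1]) + dz * np.float32(u[2])
    r2 = dx * dx + dy * dy + dz * dz - t * t
    # e1 = normalized projection of z_hat onto the plane orthogonal to the axis
    e1 = np.array([0.0, 0.0, 1.0]) - u[2] * u
    n = np.linalg.norm(e1)
    if n < 1e-12:  # axis parallel to B0; exterior term vanishes anyway
        q = np.zeros_like(r2)
    else:
        e1 = e1 / n
        q = dx * np.float32(e1[0]) + dy * np.float32(e1[1]) + dz * np.float32(e1[2])
    return r2, q


def cylinder_field_offset(pos, cyl: Cylinder, fp: FieldParams):
    """Field offset dBz (Tesla) at position(s) ``pos`` from one cylinder.

    ``pos`` is a 3-vector or an (..., 3) array of um coordinates.  Uses the
    two-branch infinite-cylinder closed form; r = 0 falls in the interior
    branch.
    """
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    p = pos.reshape(-1, 3)
    fpc = _with_theta(fp, cyl)
    r2, q = _perp_geometry(p[:, 0], p[:, 1], p[:, 2], cyl)
    out = _branch_field(r2, q, cyl.radius, fpc, first_interior=np.ones_like(r2, bool))
    return float(out[0]) if single else out.reshape(pos.shape[:-1])


def _branch_field(r2, q, radius, fp: FieldParams, first_interior):
    """Evaluate the two-branch field given perpendicular geometry.

    ``first_interior`` marks where the interior term applies (containing
    cylinder not shadowed by an earlier one); inside-but-shadowed voxels
    contribute zero.
    """
    theta = fp.theta
    if theta is None:
        # caller passes per-cylinder geometry; theta derived there
        raise ValueError("theta required")
    sin2t = np.sin(theta) ** 2
    c = TWO_PI * fp.b0 * (1.0 - fp.y) * fp.delta_chi
    r2 = np.asarray(r2, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    inside = r2 < radius * radius
    with np.errstate(divide="ignore", invalid="ignore"):
        ext = c * sin2t * radius * radius * (2.0 * q * q - r2) / (r2 * r2)
    interior = c * (np.cos(theta) ** 2 - 1.0 / 3.0)
    out = np.where(inside, np.where(first_interior, interior, 0.0), ext)
    return out


def _with_theta(fp: FieldParams, cyl: Cylinder) -> FieldParams:
    if fp.theta is not None:
        return fp
    return FieldParams(fp.b0, fp.y, fp.delta_chi, cyl.theta)


def voxelize_cylinders(cylinders, fov, grid) -> np.ndarray:
    """Label voxels whose centers fall inside any cylinder with 1, else 0."""
    mask = np.zeros(tuple(np.asarray(grid, dtype=int)), dtype=bool)
    for cyl in cylinders:
        r2, _ = _grid_r2_q(fov, grid, cyl, need_q=False)
        mask |= r2 < cyl.radius * cyl.radius
    return mask.astype(np.uint8)


def compose_fieldmap(cylinders, fov, grid, fp: FieldParams) -> np.ndarray:
    """Superpose cylinder fields at voxel centers; float32 Tesla.

    Each voxel receives the exterior term of every cylinder it lies outside.
    A voxel inside one or more cylinders receives the interior term of the
    first containing cylinder (cylinder list order) and nothing from other
    containing cylinders.
    """
    shape = tuple(np.asarray(grid, dtype=int))
    total = np.zeros(shape, dtype=np.float64)
    inside_any = np.zeros(shape, dtype=bool)
    for cyl in cylinders:
        fpc = _with_theta(fp, cyl)
        r2, q = _grid_r2_q(fov, grid, cyl, need_q=True)
        inside = r2 < cyl.radius * cyl.radius
        total += _branch_field(r2, q, cyl.radius, fpc, first_interior=~inside_any)
        inside_any |= inside
    return total.astype(np.float32)


def place_random_cylinders(
    fov,
    grid,
    radius: float,
    target_bvf: float,
    orientation="perpendicular",
    seed: int = 0,
    max_cylinders: int = 10000,
):
    """Add uniformly placed cylinders until the voxelized BVF reaches target.

    orientation: "perpendicular" (axis uniform in the plane orthogonal to B0),
    "random" (isotropic axis), or an explicit unit 3-vector shared by all
    cylinders.  Overlaps are allowed; labeling is the union (label 1 inside
    any cylinder, 0 outside).  Returns (cylinders, substrate, achieved_bvf).
    """
    fov = np.asarray(fov, dtype=float)
    grid = np.asarray(grid, dtype=int)
    if not 0.0 <= target_bvf < 1.0:
        raise ValueError("target_bvf must lie in [0, 1)")
    vox = fov / grid
    if radius < vox.max():
        warnings.warn(
            f"cylinder radius {radius} um is below the voxel edge {vox.max():.3g} um; "
            "the voxelized cross-section will be inaccurate",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mask = np.zeros(tuple(grid), dtype=bool)
    cylinders: list[Cylinder] = []
    bvf = 0.0
    while bvf < target_bvf:
        if len(cylinders) >= max_cylinders:
            raise RuntimeError(
                f"target BVF {target_bvf} not reached after {max_cylinders} cylinders "
                f"(achieved {bvf:.4f})"
            )
        point = rng.random(3) * fov
        if isinstance(orientation, str) and orientation == "perpendicular":
            a = rng.random() * TWO_PI
            direction = np.array([np.cos(a), np.sin(a), 0.0])
        elif isinstance(orientation, str) and orientation == "random":
            v = rng.standard_normal(3)
            direction = v / np.linalg.norm(v)
        else:
            direction = np.asarray(orientation, dtype=float)
            direction = direction / np.linalg.norm(direction)
        cyl = Cylinder(point, direction, radius)
        r2, _ = _grid_r2_q(fov, grid, cyl, need_q=False)
        mask |= r2 < radius * radius
        cylinders.append(cyl)
        bvf = float(np.count_nonzero(mask)) / mask.size
    logger.info("placed %d cylinders, achieved BVF %.4f", len(cylinders), bvf)
    return cylinders, mask.astype(np.uint8), bvf


def make_cylinder_phantom(
    fov,
    grid,
    radius,
    target_bvf,
    orientation="perpendicular",
    seed=0,
    fp: FieldParams | None = None,
) -> VoxelPhantom:
    """Random-cylinder phantom with its analytic field map (B0 = 1 T, Y = 0).

    The stored map is generated at unit (1-Y); simulations rescale it by
    B0*(1-Y_state) analytically, which is exact by linearity of the field.
    """
    fp = fp or FieldParams()
    cylinders, substrate, bvf = place_random_cylinders(
        fov, grid, radius, target_bvf, orientation, seed
    )
    db0 = compose_fieldmap(cylinders, fov, grid, fp)
    attrs = {
        "bvf_achieved": bvf,
        "seed": seed,
        "radius_um": float(radius),
        "y_gen": fp.y,
        "delta_chi": fp.delta_chi,
        "n_cylinders": len(cylinders),
    }
    return VoxelPhantom(substrate, db0, np.asarray(fov, dtype=float), attrs)


def dipole_fieldmap(chi: np.ndarray, fov, pad=(1, 1, 1)) -> np.ndarray:
    """Finite-perturber field solver: FFT dipole-kernel convolution.

    ``chi`` is a 3D map of SI susceptibility (dimensionless; for the cylinder
    model chi = 4*pi*delta_chi_cgs*(1-Y) inside vessels, 0 outside).  Returns
    dBz / B0 on the same grid with periodic boundary conditions.  The k-space
    dipole kernel is 1/3 - kz^2/k^2, with the k = 0 term set to zero (zero
    spatial mean).  ``pad`` zero-pads each axis by an integer factor before
    the transform (and crops the original window afterwards) to suppress
    wrap-around images of the source; keep pad = 1 along an axis a structure
    is meant to continue through periodically (e.g. a cylinder axis).  Used
    as an independent oracle for the analytic cylinder field; it is never
    the simulation path.
    """
    chi = np.asarray(chi, dtype=float)
    fov = np.asarray(fov, dtype=float)
    pad = np.asarray(pad, dtype=int)
    if np.any(pad > 1):
        grid0 = np.asarray(chi.shape)
        big = grid0 * pad
        lo = (big - grid0) // 2
        chi_p = np.zeros(big)
        chi_p[lo[0]:lo[0] + grid0[0], lo[1]:lo[1] + grid0[1], lo[2]:lo[2] + grid0[2]] = chi
        out = dipole_fieldmap(chi_p, fov * pad, pad=(1, 1, 1))
        return out[lo[0]:lo[0] + grid0[0], lo[1]:lo[1] + grid0[1], lo[2]:lo[2] + grid0[2]]
    grid = chi.shape
    ks = [np.fft.fftfreq(g, d=f / g) for g, f in zip(grid, fov)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx * kx + ky * ky + kz * kz
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - np.where(k2 > 0, kz * kz / np.where(k2 > 0, k2, 1.0), 0.0)
    kernel.flat[0] = 0.0
    return np.real(np.fft.ifftn(np.fft.fftn(chi) * kernel))


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

_RESERVED_ATTRS = ("fov",)


def write_phantom(ph: VoxelPhantom, path) -> None:
    """Write a phantom: datasets /substrate, /db0; attribute fov plus metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("substrate", data=ph.substrate.astype(np.uint16))
        f.create_dataset("db0", data=ph.db0.astype(np.float32))
        f.attrs["fov"] = np.asarray(ph.fov, dtype=np.float64)
        for k, v in ph.attrs.items():
            if k not in _RESERVED_ATTRS:
                f.attrs[k] = v


def read_phantom(path) -> VoxelPhantom:
    """Read a phantom file; a missing /db0 dataset loads as an all-zero map."""
    with h5py.File(path, "r") as f:
        if "substrate" not in f:
            raise ValueError(f"{path}: missing required dataset /substrate")
        substrate = f["substrate"][...]
        if "db0" in f:
            db0 = f["db0"][...]
            if db0.shape != substrate.shape:
                raise ValueError(
                    f"{path}: /db0 shape {db0.shape} does not match "
                    f"/substrate shape {substrate.shape}"
                )
        else:
            logger.warning("%s: no /db0 dataset; off-resonance set to zero", path)
            db0 = np.zeros(substrate.shape, dtype=np.float32)
        if "fov" not in f.attrs:
            raise ValueError(f"{path}: missing required attribute fov")
        fov = np.asarray(f.attrs["fov"], dtype=float)
        attrs = {k: f.attrs[k] for k in f.attrs if k not in _RESERVED_ATTRS}
    return VoxelPhantom(substrate, db0, fov, attrs)
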