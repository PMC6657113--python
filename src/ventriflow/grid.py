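"""Gridded 4D velocity data and chamber masks.

Data model for time-resolved three-directional phase-contrast velocity
fields on a regular voxel grid, together with the per-phase binary
segmentation of the ventricular cavity. Velocities are stored in m/s,
voxel spacing in mm; all unit conversion to reporting units (mJ, mW,
mL/s) happens at the computation boundary, never here.

Also houses the velocity-aliasing forward model (phase wraps by 2*VENC),
its correction, and the application of a given rigid transform to a mask
series (the transform itself comes from an external registration step and
is an input).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised when grids, shapes or spacings are inconsistent."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice over one reconstructed cardiac cycle.

    Parameters
    ----------
    nx, ny, nz : int
        Voxel counts along each spatial axis.
    dx, dy, dz : float
        Voxel spacing in mm.
    nt : int
        Number of reconstructed cardiac phases (30 in a typical
        retrospectively gated acquisition).
    rr_ms : float
        Duration of the cardiac cycle in ms. Phases are uniformly spaced
        across it (retrospective gating).
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    nt: int = 1
    rr_ms: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz, self.nt) < 1:
            raise GridError("voxel and phase counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise GridError("voxel spacing must be positive")
        if self.rr_ms <= 0:
            raise GridError("rr_ms must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def voxel_volume_ml(self) -> float:
        # 1 mL = 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    def coordinates_mm(self, center: tuple[float, float, float] | None = None):
        """Voxel-center world coordinates (mm) as three broadcastable arrays.

        Voxel i sits at i*spacing; `center` (mm) is subtracted if given.
        """
        cx, cy, cz = center if center is not None else (0.0, 0.0, 0.0)
        x = np.arange(self.nx)[:, None, None] * self.dx - cx
        y = np.arange(self.ny)[None, :, None] * self.dy - cy
        z = np.arange(self.nz)[None, None, :] * self.dz - cz
        return x, y, z


@dataclass
class VelocityField:
    """Three-component velocity per voxel per cardiac phase.

    `v` has shape (nx, ny, nz, nt, 3) in m/s; `venc` is the velocity
    encoding limit in m/s (velocities beyond +-venc alias by 2*venc).
    """

    grid: VoxelGrid
    v: np.ndarray
    venc: float = 1.5

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        expected = (*self.grid.shape, self.grid.nt, 3)
        if self.v.shape != expected:
            raise GridError(f"velocity shape {self.v.shape} != grid shape {expected}")
        if not np.all(np.isfinite(self.v)):
            raise GridError("velocity field contains non-finite values")
        if self.venc <= 0:
            raise GridError("venc must be positive")

    def phase(self, t: int) -> np.ndarray:
        """Velocity components at phase t, shape (nx, ny, nz, 3)."""
        return self.v[..., t, :]


@dataclass
class SegmentationMask:
    """Per-phase binary chamber mask on the field's grid.

    `m` has shape (nx, ny, nz, nt) with values in {0, 1}.
    """

    grid: VoxelGrid
    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        expected = (*self.grid.shape, self.grid.nt)
        if self.m.shape != expected:
            raise GridError(f"mask shape {self.m.shape} != grid shape {expected}")
        vals = np.unique(self.m)
        if not np.all(np.isin(vals, (0, 1))):
            raise GridError("mask values must be 0 or 1")
        self.m = self.m.astype(bool)

    def phase(self, t: int) -> np.ndarray:
        return self.m[..., t]


@dataclass(frozen=True)
class PhasePartition:
    """Disjoint split of the cardiac phases into systole and diastole.

    Derived upstream from valve-tracking flow-time curves; consumed here
    as an input.
    """

    systole_frames: frozenset[int]
    diastole_frames: frozenset[int]

    def __init__(self, systole_frames, diastole_frames):
        object.__setattr__(self, "systole_frames", frozenset(int(i) for i in systole_frames))
        object.__setattr__(self, "diastole_frames", frozenset(int(i) for i in diastole_frames))
        if not self.systole_frames or not self.diastole_frames:
            raise GridError("both systole and diastole frame sets must be non-empty")
        if self.systole_frames & self.diastole_frames:
            raise GridError("systole and diastole frames must be disjoint")

    def validate_for(self, nt: int) -> None:
        if self.systole_frames | self.diastole_frames != set(range(nt)):
            raise GridError(f"partition must cover exactly phases 0..{nt - 1}")

    @property
    def nt(self) -> int:
        return len(self.systole_frames) + len(self.diastole_frames)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body transform: world' = R @ world + t, translation in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GridError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise GridError("rotation must be orthonormal with determinant +1")

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        """Build from 12 row-major numbers: 3x3 rotation then translation."""
        a = np.asarray(values, dtype=float).ravel()
        if a.size != 12:
            raise GridError("rigid transform needs 12 numbers (row-major R, then t)")
        return cls(a[:9].reshape(3, 3), a[9:])


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_4d(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise GridError(f"{path}: expected a 4D volume, got ndim={data.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_velocity_nifti(paths_per_component, venc: float, rr_ms: float = 1000.0) -> VelocityField:
    """Read three 4D NIfTI volumes (one per velocity component, m/s).

    The three files must agree in shape and voxel spacing; phases run
    along the 4th axis. Grid spacing is taken from the NIfTI header (mm).
    """
    if len(paths_per_component) != 3:
        raise GridError("exactly three component paths required (vx, vy, vz)")
    vols, zooms = [], None
    for p in paths_per_component:
        data, z = _load_4d(p)
        if vols and (data.shape != vols[0].shape or not np.allclose(z, zooms)):
            raise GridError("velocity components disagree in shape or spacing")
        zooms = z if zooms is None else zooms
        vols.append(data)
    v = np.stack(vols, axis=-1)
    if not np.all(np.isfinite(v)):
        raise GridError("velocity volumes contain non-finite voxels")
    nx, ny, nz, nt = vols[0].shape
    grid = VoxelGrid(nx, ny, nz, *zooms, nt=nt, rr_ms=rr_ms)
    return VelocityField(grid, v, venc=venc)


def write_velocity_nifti(field: VelocityField, paths_per_component) -> None:
    """Write one 4D NIfTI per velocity component, spacing in the header."""
    if len(paths_per_component) != 3:
        raise GridError("exactly three component paths required (vx, vy, vz)")
    affine = np.diag((*field.grid.spacing_mm, 1.0))
    for c, p in enumerate(paths_per_component):
        img = nib.Nifti1Image(field.v[..., c], affine)
        img.header.set_zooms((*field.grid.spacing_mm, 1.0))
        nib.save(img, str(p))


def read_mask_nifti(path, rr_ms: float = 1000.0) -> SegmentationMask:
    """Read a 4D {0,1} NIfTI mask."""
    data, zooms = _load_4d(path)
    nx, ny, nz, nt = data.shape
    grid = VoxelGrid(nx, ny, nz, *zooms, nt=nt, rr_ms=rr_ms)
    return SegmentationMask(grid, data.round().astype(np.uint8))


def write_mask_nifti(mask: SegmentationMask, path) -> None:
    affine = np.diag((*mask.grid.spacing_mm, 1.0))
    img = nib.Nifti1Image(mask.m.astype(np.uint8), affine)
    img.header.set_zooms((*mask.grid.spacing_mm, 1.0))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Velocity aliasing
# ---------------------------------------------------------------------------

def wrap_velocity(field: VelocityField) -> VelocityField:
    """Forward aliasing model: fold every component into [-venc, venc).

    Phase-contrast MRI records velocity as a phase angle, so any true
    velocity v maps onto ((v + venc) mod 2*venc) - venc.
    """
    venc = field.venc
    wrapped = np.mod(field.v + venc, 2.0 * venc) - venc
    return VelocityField(field.grid, wrapped, venc=venc)


def _resolve_component(vol: np.ndarray, mask3: np.ndarray, venc: float) -> np.ndarray:
    """Unwrap one component volume at one phase by seeded region growing.

    Each connected in-mask component is grown breadth-first from a
    deterministic seed; a voxel whose value differs from the median of
    its already-resolved in-mask 6-neighbours by more than venc is
    corrected by the single +-2*venc step that minimises the difference.
    Finally the wrap branch of the whole component is chosen as the one
    (shift in {-2venc, 0, +2venc}) that alters the fewest voxels relative
    to the recorded data — the recorded branch is right for the majority
    of voxels in any plausible acquisition.
    """
    out = vol.copy()
    labels, nlab = ndimage.label(mask3)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = vol.shape
    for lab in range(1, nlab + 1):
        comp = labels == lab
        idx = np.argwhere(comp)
        # seed: voxel with the most in-mask neighbours, ties by lowest index
        nb_count = sum(
            np.pad(comp, 1)[1 + o[0]: shape[0] + 1 + o[0],
                            1 + o[1]: shape[1] + 1 + o[1],
                            1 + o[2]: shape[2] + 1 + o[2]]
            for o in offsets
        )
        best = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))]
        counts = nb_count[tuple(best.T)]
        seed = tuple(best[int(np.argmax(counts))])
        resolved = np.zeros(shape, dtype=bool)
        resolved[seed] = True
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for o in offsets:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if not all(0 <= q[k] < shape[k] for k in range(3)):
                    continue
                if not comp[q] or resolved[q]:
                    continue
                ref_vals = [
                    out[q[0] + oo[0], q[1] + oo[1], q[2] + oo[2]]
                    for oo in offsets
                    if all(0 <= q[k] + oo[k] < shape[k] for k in range(3))
                    and resolved[q[0] + oo[0], q[1] + oo[1], q[2] + oo[2]]
                ]
                ref = float(np.median(ref_vals))
                val = out[q]
                if abs(val - ref) > venc:
                    corrected = val + 2.0 * venc * (1 if ref > val else -1)
                    if abs(corrected - ref) < abs(val - ref):
                        out[q] = corrected
                resolved[q] = True
                queue.append(q)
        # global branch fix for the component
        shifts = (-2.0 * venc, 0.0, 2.0 * venc)
        changed = [int(np.sum(~np.isclose(out[comp] + s, vol[comp]))) for s in shifts]
        s = shifts[int(np.argmin(changed))]
        if s != 0.0:
            out[comp] += s
    return out


def unwrap_velocity(field: VelocityField, mask: SegmentationMask) -> VelocityField:
    """Correct single-wrap velocity aliasing inside the chamber mask.

    Out-of-mask voxels are left untouched (their velocities are noise).
    Only a single +-2*venc correction per voxel is applied.
    """
    if mask.grid.shape != field.grid.shape or mask.grid.nt != field.grid.nt:
        raise GridError("mask grid does not match field grid")
    v = field.v.copy()
    for t in range(field.grid.nt):
        m3 = mask.phase(t)
        if not m3.any():
            continue
        for c in range(3):
            v[..., t, c] = _resolve_component(v[..., t, c], m3, field.venc)
    return VelocityField(field.grid, v, venc=field.venc)


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def apply_rigid_to_mask(mask: SegmentationMask, transform: RigidTransform) -> SegmentationMask:
    """Resample the mask under a rigid transform, nearest-neighbour.

    The transform acts on world coordinates (mm, voxel-centred,
    world = index * spacing); output voxels that pull from outside the
    grid are 0. Binary in/out only — no partial-volume weighting.
    """
    spacing = np.asarray(mask.grid.spacing_mm)
    # output voxel j pulls from input voxel i = S^-1 (R^-1 (S j - t))
    Rinv = transform.rotation.T
    M = np.diag(1.0 / spacing) @ Rinv @ np.diag(spacing)
    offset = np.diag(1.0 / spacing) @ (-Rinv @ transform.translation)
    out = np.zeros_like(mask.m)
    for t in range(mask.grid.nt):
        out[..., t] = ndimage.affine_transform(
            mask.m[..., t].astype(np.uint8), M, offset=offset, order=0,
            mode="constant", cval=0,
        )
    return SegmentationMask(mask.grid, out)
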