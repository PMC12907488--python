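"""Seeded synthetic head-CT phantoms with ground-truth subregion labels
and known analytic volumes.

The phantom is a 256-cube, 1 mm isotropic head: an ellipsoidal skull
shell around noisy brain parenchyma, with the twelve ventricular
subregions carved out as CSF-filled geometric primitives — ellipsoids
for the bodies, horns, atria and midline ventricles, arcs of tori
(curved tubes) for the thin posterior and temporal horns.  Left/right
primitives are mirror images before pose jitter; subregion volumes
scale with the cube of a ventriculomegaly factor and are known in
closed form, which anchors the volumetry checks.

Default HU values sit inside the 0-80 CSF window (CSF 8 +- 2,
parenchyma 35 +- 3) so the windowed contrast mimics the clinical
CSF/parenchyma separation the pipeline is built around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ventriseg.image_io import LabelVolume, NativeVolume
from ventriseg.subregions import SUBREGIONS

GRID = 256
HEAD_CENTER = np.array([128.0, 128.0, 128.0])


def _rot(euler_deg) -> np.ndarray:
    return Rotation.from_euler("xyz", euler_deg, degrees=True).as_matrix()


def _to_local(pts, center: np.ndarray, rot: np.ndarray):
    """Local coordinates of broadcastable grid axes (x, y, z) in a
    primitive's frame; returns three broadcast arrays."""
    x, y, z = pts
    c = center.astype(np.float32)
    r = rot.astype(np.float32)
    dx, dy, dz = x - c[0], y - c[1], z - c[2]
    u = r[0, 0] * dx + r[1, 0] * dy + r[2, 0] * dz
    v = r[0, 1] * dx + r[1, 1] * dy + r[2, 1] * dz
    w = r[0, 2] * dx + r[1, 2] * dy + r[2, 2] * dz
    return u, v, w


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned-by-default ellipsoid; center is relative to the head
    center in mm, +x right / +y anterior / +z superior."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def analytic_volume(self, scale: float = 1.0) -> float:
        a, b, c = (s * scale for s in self.semi_axes)
        return 4.0 / 3.0 * math.pi * a * b * c

    def mirrored(self) -> "Ellipsoid":
        cx, cy, cz = self.center
        rx, ry, rz = self.euler_deg
        return Ellipsoid((-cx, cy, cz), self.semi_axes, (rx, -ry, -rz))

    def _frame(self, pose: np.ndarray):
        center = HEAD_CENTER + pose @ np.asarray(self.center)
        rot = pose @ _rot(self.euler_deg)
        return center, rot

    def bounding_radius(self, scale: float) -> float:
        return max(self.semi_axes) * scale

    def contains(self, pts, pose: np.ndarray, scale: float) -> np.ndarray:
        # quadratic form q = d^T M d with M = R diag(a^-2) R^T, accumulated
        # from separable 1D/2D terms so no full-grid temporaries are needed
        center, rot = self._frame(pose)
        ax = np.asarray(self.semi_axes, dtype=np.float64) * scale
        m = (rot @ np.diag(1.0 / ax ** 2) @ rot.T).astype(np.float32)
        x, y, z = pts
        dx = (x.ravel() - np.float32(center[0]))
        dy = (y.ravel() - np.float32(center[1]))
        dz = (z.ravel() - np.float32(center[2]))
        q = np.empty((dx.size, dy.size, dz.size), dtype=np.float32)
        q[:] = ((m[0, 0] * dx * dx)[:, None]
                + (m[1, 1] * dy * dy)[None, :])[:, :, None]
        q += (m[2, 2] * dz * dz)[None, None, :]
        q += (2.0 * m[0, 1] * np.outer(dx, dy))[:, :, None]
        q += (2.0 * m[0, 2] * np.outer(dx, dz))[:, None, :]
        q += (2.0 * m[1, 2] * np.outer(dy, dz))[None, :, :]
        return q <= 1.0


@dataclass(frozen=True)
class TubeArc:
    """Arc of a torus: a curved tube of radius ``tube_radius`` around a
    circular arc of radius ``arc_radius`` spanning ``arc_deg`` degrees.

    In the local frame the arc lies in the xy-plane, centered on the +x
    axis; ends are cut by radial planes, so the closed-form volume
    pi * theta * R * r^2 is exact.
    """

    center: tuple[float, float, float]
    arc_radius: float
    tube_radius: float
    arc_deg: float
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mirror: bool = False

    def analytic_volume(self, scale: float = 1.0) -> float:
        theta = math.radians(self.arc_deg)
        return math.pi * theta * (self.arc_radius * scale) * (self.tube_radius * scale) ** 2

    def mirrored(self) -> "TubeArc":
        cx, cy, cz = self.center
        return TubeArc((-cx, cy, cz), self.arc_radius, self.tube_radius,
                       self.arc_deg, self.euler_deg, mirror=not self.mirror)

    def bounding_radius(self, scale: float) -> float:
        return (self.arc_radius + self.tube_radius) * scale

    def _local_rot(self) -> np.ndarray:
        rot = _rot(self.euler_deg)
        if self.mirror:
            # reflect about the sagittal plane; the arc is symmetric under
            # its local y-flip, so Mx R My is the mirrored orientation
            rot = np.diag([-1.0, 1.0, 1.0]) @ rot @ np.diag([1.0, -1.0, 1.0])
        return rot

    def contains(self, pts, pose: np.ndarray, scale: float) -> np.ndarray:
        center = HEAD_CENTER + pose @ np.asarray(self.center)
        rot = pose @ self._local_rot()
        u, v, w = _to_local(pts, center, rot)
        u, v, w = np.broadcast_arrays(u, v, w)
        r_xy = np.hypot(u, v)
        tube = np.hypot(r_xy - self.arc_radius * scale, w)
        angle = np.abs(np.arctan2(v, u))
        return (tube <= self.tube_radius * scale) & \
               (angle <= math.radians(self.arc_deg) / 2.0)


def default_subregions() -> dict:
    """Primitive per subregion, mm, sized to realistic (mildly
    hydrocephalic) magnitudes: lateral-ventricle bodies ~20 ml, horns
    and atria a few ml, posterior horns under 1 ml."""
    right = {
        "body_right_lateral": Ellipsoid((21.0, 2.0, 20.0), (12.0, 25.0, 13.0)),
        "right_anterior_horn": Ellipsoid((15.0, 48.0, 8.0), (7.0, 9.0, 9.0)),
        "right_atrium": Ellipsoid((22.0, -38.0, 8.0), (8.0, 9.0, 9.0)),
        "right_posterior_horn": TubeArc((16.0, -62.0, 8.0), 11.0, 3.5, 90.0,
                                        euler_deg=(0.0, 0.0, -90.0)),
        "right_temporal_horn": TubeArc((38.0, -10.0, -18.0), 18.0, 4.5, 90.0),
    }
    midline = {
        "third_ventricle": Ellipsoid((0.0, 10.0, 6.0), (3.5, 14.0, 10.0)),
        "fourth_ventricle": Ellipsoid((0.0, -20.0, -20.0), (5.0, 8.0, 7.0)),
    }
    out = dict(midline)
    for name, prim in right.items():
        out[name] = prim
        out[name.replace("right", "left", 1) if name.startswith("right")
            else "body_left_lateral"] = prim.mirrored()
    return out


@dataclass
class PhantomSpec:
    """Everything that determines one phantom, reproducible from the seed."""

    seed: int = 0
    skull_semi_axes: tuple[float, float, float] = (78.0, 95.0, 85.0)
    skull_thickness: float = 6.0
    parenchyma_hu: tuple[float, float] = (35.0, 3.0)
    csf_hu: tuple[float, float] = (8.0, 2.0)
    bone_hu: float = 900.0
    air_hu: float = -1000.0
    noise_sd: float = 4.0
    subregion_params: dict = field(default_factory=default_subregions)
    ventriculomegaly_scale: float = 1.0
    pose_euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose_jitter: float = 5.0  # max |degrees| per axis for cohort draws

    def __post_init__(self):
        if self.ventriculomegaly_scale < 0.5:
            raise ValueError("ventriculomegaly_scale must be >= 0.5")
        missing = {c.name for c in SUBREGIONS} - set(self.subregion_params)
        if missing:
            raise ValueError(f"subregion primitives missing: {sorted(missing)}")


def _grid_points(lo: np.ndarray, hi: np.ndarray):
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = tuple(np.arange(s.start, s.stop, dtype=np.float32) for s in sl)
    return sl, (axes[0][:, None, None], axes[1][None, :, None],
                axes[2][None, None, :])


def _voxelize(prim, pose: np.ndarray, scale: float,
              grid: int = GRID) -> tuple[tuple, np.ndarray]:
    center = HEAD_CENTER + pose @ np.asarray(prim.center)
    r = prim.bounding_radius(scale) + 2.0
    lo = np.clip(np.floor(center - r), 0, grid)
    hi = np.clip(np.ceil(center + r) + 1, 0, grid)
    sl, pts = _grid_points(lo, hi)
    return sl, prim.contains(pts, pose, scale)


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[NativeVolume, LabelVolume, dict]:
    """Generate (CT volume, label volume, analytic volumes in ml).

    Deterministic in ``spec.seed``.  Raises on overlapping subregions
    ("subregion collision") and on subregions reaching bone or leaving
    the skull interior.
    """
    rng = np.random.default_rng(spec.seed)
    pose = _rot(spec.pose_euler)
    grid = GRID
    ax = np.arange(grid, dtype=np.float32)
    pts = (ax[:, None, None], ax[None, :, None], ax[None, None, :])

    outer = Ellipsoid((0.0, 0.0, 0.0), spec.skull_semi_axes)
    inner = Ellipsoid((0.0, 0.0, 0.0),
                      tuple(a - spec.skull_thickness for a in spec.skull_semi_axes))
    outer_mask = outer.contains(pts, pose, 1.0)
    inner_mask = inner.contains(pts, pose, 1.0)

    labels = np.zeros((grid,) * 3, dtype=np.int16)
    analytic_ml: dict[str, float] = {}
    s = spec.ventriculomegaly_scale
    for cls in SUBREGIONS:
        prim = spec.subregion_params[cls.name]
        sl, mask = _voxelize(prim, pose, s, grid)
        mask = np.broadcast_to(mask, tuple(q.stop - q.start for q in sl))
        region = labels[sl]
        if np.any(region[mask] != 0):
            raise ValueError("subregion collision")
        if np.any(~inner_mask[sl][mask]):
            raise ValueError(f"subregion {cls.name} outside skull interior")
        region[mask] = cls.label_value
        analytic_ml[cls.name] = prim.analytic_volume(s) / 1000.0

    hu = np.full((grid,) * 3, spec.air_hu, dtype=np.float32)
    tissue_field = rng.standard_normal(hu.shape, dtype=np.float32)
    hu[outer_mask] = spec.bone_hu
    par = inner_mask & (labels == 0)
    hu[par] = spec.parenchyma_hu[0] + spec.parenchyma_hu[1] * tissue_field[par]
    csf = labels > 0
    hu[csf] = spec.csf_hu[0] + spec.csf_hu[1] * tissue_field[csf]
    hu += spec.noise_sd * rng.standard_normal(hu.shape, dtype=np.float32)

    native = NativeVolume(data=hu, spacing=(1.0, 1.0, 1.0), affine=np.eye(4))
    label_volume = LabelVolume(labels=labels, frame="native",
                               spacing=(1.0, 1.0, 1.0), affine=np.eye(4))
    return native, label_volume, analytic_ml


def phantom_cohort(n: int, base_spec: PhantomSpec | None = None,
                   seed: int = 0) -> list[tuple[NativeVolume, LabelVolume, dict]]:
    """A cohort of phantoms with per-subject ventricular scale, pose
    jitter and noise; subject i is reproducible from (seed, i) alone."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_spec or PhantomSpec()
    out = []
    for i in range(n):
        ss = np.random.SeedSequence([seed, i])
        rng = np.random.default_rng(ss)
        scale = float(rng.uniform(0.9, 1.25))
        jitter = tuple(float(v) for v in
                       rng.uniform(-base.pose_jitter, base.pose_jitter, 3))
        subject_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        spec = replace(base, seed=subject_seed, ventriculomegaly_scale=scale,
                       pose_euler=jitter)
        out.append(generate_phantom(spec))
    return out


def cohort_scale_moment() -> float:
    """E[s^3] of the cohort ventriculomegaly scale s ~ U(0.9, 1.25)."""
    lo, hi = 0.9, 1.25
    return (hi ** 4 - lo ** 4) / (4 * (hi - lo))
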