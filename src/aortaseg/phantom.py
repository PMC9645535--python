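"""Synthetic aortic CT phantoms with analytic ground truth.

A phantom is a tube of circular cross-section swept along a smooth spline
centerline, with a thin wall and an abdominal aneurysmal bulge that may
contain a crescentic intraluminal thrombus eating into the lumen.  Two
"HU-like" renditions are produced for every spec: a contrast analogue
(bright lumen, thin slices) and a non-contrast analogue (lumen intensity
close to surrounding tissue, thicker slices).  Because every voxel label is
a deterministic function of the analytic geometry, the phantom provides
exact oracles for diameters, volumes and the centerline — the quantities
the morphometry layer is meant to recover.

Partial-volume handling: a voxel's class is decided by its center point
(no anti-aliasing).  ``subvoxel_volumes`` quantifies the resulting
discretisation error by subdividing boundary voxels 5x5x5 and counting
sub-centers against the same analytic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .core import BACKGROUND, LUMEN, WALL_ILT, LabelMask, Volume

__all__ = [
    "GeometryError",
    "IntensityModel",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "CenterCurve",
    "generate_phantom",
    "generate_cohort",
    "analytic_profile",
    "subvoxel_volumes",
    "straight_tube_spec",
    "default_abdominal_spec",
    "arch_spec",
]

# internal region codes (finer than the 3 output labels)
_BG, _LUMEN, _WALL, _THROMBUS = 0, 1, 2, 3


class GeometryError(ValueError):
    """Raised when the requested anatomy does not fit the voxel grid."""


@dataclass(frozen=True)
class IntensityModel:
    """Mean HU-like values per tissue region.

    Defaults mimic soft-tissue CT: contrast-opacified blood ~300, unenhanced
    blood within a few HU of muscle/soft tissue (~40), mural thrombus
    slightly hypodense.  No DICOM rescale machinery; values are plain floats.
    """

    lumen_contrast: float = 300.0
    lumen_noncontrast: float = 45.0
    wall: float = 60.0
    thrombus: float = 30.0
    background: float = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic aorta.

    The lumen radius along the vessel is piecewise-linear in *normalized*
    arc length (fraction of total curve length), built from a baseline tube
    radius plus a bulge segment whose peak radius exceeds the tube radius
    (the aneurysm is a dilatation).  The crescentic thrombus lives in the
    bulge segment: it spans an angular fraction ``thrombus_fraction`` of the
    circumference and thickens inward to ``thrombus_depth_frac`` of the
    local lumen radius at the crescent center, tapering to zero at its
    angular edges and at the bulge boundaries.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.25)
    centerline_control_points: tuple[tuple[float, float, float], ...] = ()
    tube_radius: float = 10.0
    bulge_radius: float = 22.0
    bulge_center_frac: float = 0.62
    bulge_width_frac: float = 0.36
    wall_thickness: float = 2.0
    thrombus_fraction: float = 0.55
    thrombus_depth_frac: float = 0.55
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    noise_sd: float = 10.0
    noncontrast_slice_thickness: float | None = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        if self.tube_radius <= 0 or self.bulge_radius <= 0:
            raise ValueError("radii must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if not 0.0 <= self.thrombus_fraction <= 1.0:
            raise ValueError("thrombus_fraction must lie in [0, 1]")
        if not 0.0 <= self.thrombus_depth_frac < 1.0:
            raise ValueError("thrombus_depth_frac must lie in [0, 1)")
        if self.bulge_radius <= self.tube_radius:
            raise ValueError("bulge max radius must exceed the adjacent tube radius")
        if not 0.0 < self.bulge_width_frac < 1.0:
            raise ValueError("bulge_width_frac must lie in (0, 1)")

    # ------------------------------------------------------------------
    def control_points(self) -> np.ndarray:
        """Control points; a straight axial tube through the grid center
        when none were given."""
        if self.centerline_control_points:
            return np.asarray(self.centerline_control_points, dtype=float)
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        cx, cy = extent[0] / 2, extent[1] / 2
        zs = np.linspace(0.02, 0.98, 5) * extent[2]
        return np.column_stack([np.full(5, cx), np.full(5, cy), zs])

    def radius_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear lumen-radius profile: (arc fractions, radii mm)."""
        c, w = self.bulge_center_frac, self.bulge_width_frac
        lo, hi = max(c - w / 2, 1e-3), min(c + w / 2, 1.0 - 1e-3)
        fr = np.array([0.0, lo, (lo + c) / 2, c, (c + hi) / 2, hi, 1.0])
        r_mid = (self.tube_radius + self.bulge_radius) / 2
        rr = np.array(
            [
                self.tube_radius,
                self.tube_radius,
                r_mid,
                self.bulge_radius,
                r_mid,
                self.tube_radius,
                self.tube_radius,
            ]
        )
        return fr, rr

    def lumen_radius(self, s_frac: np.ndarray) -> np.ndarray:
        fr, rr = self.radius_knots()
        return np.interp(np.clip(s_frac, 0.0, 1.0), fr, rr)


class CenterCurve:
    """Interpolating cubic spline through control points with arc-length
    parameterization by dense polyline summation (step <= 0.25 mm keeps the
    arc-length error well under 0.1 mm)."""

    def __init__(self, control_points: np.ndarray, step_mm: float = 0.25):
        cp = np.asarray(control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
            raise ValueError("need >= 2 control points of dimension 3")
        chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
        if chord[-1] <= 0:
            raise ValueError("degenerate control polygon")
        if len(cp) == 2:  # CubicSpline needs >= 3 points; a segment is linear anyway
            mid = cp.mean(axis=0)
            cp = np.vstack([cp[0], mid, cp[1]])
            chord = np.r_[0.0, chord[-1] / 2, chord[-1]]
        self._spline = CubicSpline(chord, cp, axis=0)
        # dense resampling for arc length
        t = np.linspace(chord[0], chord[-1], max(int(np.ceil(chord[-1] / step_mm)), 8) + 1)
        pts = self._spline(t)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.points = pts
        self.arc = np.r_[0.0, np.cumsum(seg)]
        self.length = float(self.arc[-1])
        self.tangents = self._unit_tangents(pts)
        self.n1, self.n2 = self._transport_frames(self.tangents)

    @staticmethod
    def _unit_tangents(pts: np.ndarray) -> np.ndarray:
        t = np.gradient(pts, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    @staticmethod
    def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # rotation-minimizing frames: project the previous normal off the new tangent
        n1 = np.empty_like(tangents)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, tangents[0])) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = ref - np.dot(ref, tangents[0]) * tangents[0]
        n1[0] = v / np.linalg.norm(v)
        for i in range(1, len(tangents)):
            v = n1[i - 1] - np.dot(n1[i - 1], tangents[i]) * tangents[i]
            nrm = np.linalg.norm(v)
            n1[i] = v / nrm if nrm > 1e-12 else n1[i - 1]
        n2 = np.cross(tangents, n1)
        return n1, n2

    def at(self, s: np.ndarray) -> np.ndarray:
        """Points at arc lengths ``s`` (mm), by interpolation of the dense
        polyline."""
        s = np.atleast_1d(np.clip(s, 0.0, self.length))
        out = np.column_stack(
            [np.interp(s, self.arc, self.points[:, k]) for k in range(3)]
        )
        return out


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    label_mask: LabelMask
    region_mask: np.ndarray  # {0 bg, 1 lumen, 2 wall, 3 thrombus}, label-mask grid
    centerline_points: np.ndarray  # (n, 3) world mm, superior -> inferior
    centerline_arc: np.ndarray  # (n,) cumulative mm
    profile_arc: np.ndarray  # (m,) arc positions mm
    lumen_diameter_mm: np.ndarray  # pre-thrombus lumen diameter at profile_arc
    outer_diameter_mm: np.ndarray  # lumen + 2 * wall at profile_arc
    lumen_volume_mm3: float
    ws_ilt_volume_mm3: float
    total_volume_mm3: float
    noncontrast_label_mask: LabelMask | None = None

    def diameter_oracle(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """True (lumen, outer) diameters in mm at arc positions ``s``."""
        s = np.asarray(s, dtype=float)
        lum = np.interp(s, self.profile_arc, self.lumen_diameter_mm)
        out = np.interp(s, self.profile_arc, self.outer_diameter_mm)
        return lum, out

    def diameters_near(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """True (lumen, outer) diameters at the arc positions of the truth
        centerline samples nearest to arbitrary world points — the robust way
        to compare a *measured* profile (whose arc origin may differ because
        skeletons erode at the ends) against the oracle."""
        _, idx = cKDTree(self.centerline_points).query(np.atleast_2d(points))
        return self.diameter_oracle(self.centerline_arc[idx])

    @property
    def bulge_apex_arc(self) -> float:
        """Arc position (mm) of the maximal outer diameter."""
        return float(self.profile_arc[int(np.argmax(self.outer_diameter_mm))])


@dataclass
class PhantomCase:
    """One cohort member: paired volumes plus truth and its spec."""

    spec: PhantomSpec
    contrast: Volume
    noncontrast: Volume
    truth: PhantomTruth


# ----------------------------------------------------------------------
# classification against the analytic geometry
# ----------------------------------------------------------------------


def _classify_points(points: np.ndarray, spec: PhantomSpec, curve: CenterCurve,
                     tree: cKDTree) -> np.ndarray:
    """Region code for arbitrary world-mm points (vectorized)."""
    dist, idx = tree.query(points, k=1, workers=-1)
    s_frac = curve.arc[idx] / curve.length
    r_lum = spec.lumen_radius(s_frac)
    r_out = r_lum + spec.wall_thickness

    region = np.zeros(len(points), dtype=np.uint8)
    inside_outer = dist <= r_out
    # flat end caps: points projecting beyond the first/last curve sample
    # along the local tangent are outside (no spherical caps)
    for end_idx, sign in ((0, -1.0), (len(curve.points) - 1, 1.0)):
        at_end = inside_outer & (idx == end_idx)
        if at_end.any():
            v_end = points[at_end] - curve.points[end_idx]
            proj = v_end @ curve.tangents[end_idx]
            beyond = np.zeros_like(at_end)
            beyond[at_end] = sign * proj > 0
            inside_outer &= ~beyond
    if not inside_outer.any():
        return region

    # radial/angular coordinates only needed near the tube
    sub = np.flatnonzero(inside_outer)
    v = points[sub] - curve.points[idx[sub]]
    a1 = np.einsum("ij,ij->i", v, curve.n1[idx[sub]])
    a2 = np.einsum("ij,ij->i", v, curve.n2[idx[sub]])
    theta = np.arctan2(a2, a1)

    r_inner = _thrombus_inner_radius(spec, s_frac[sub], theta, r_lum[sub])
    d = dist[sub]
    lum = d < r_inner
    wall = (~lum) & (d <= r_lum[sub])  # thrombus occupies lumen radii above r_inner
    annulus = (~lum) & (~wall) & (d <= r_out[sub])
    region[sub[lum]] = _LUMEN
    region[sub[wall]] = _THROMBUS
    region[sub[annulus]] = _WALL
    return region


def _thrombus_inner_radius(spec: PhantomSpec, s_frac: np.ndarray, theta: np.ndarray,
                           r_lum: np.ndarray) -> np.ndarray:
    """Inner lumen boundary after carving the thrombus crescent.

    Crescent center at angle 0 (first transport normal); depth tapers as a
    half-cosine both angularly and along the bulge segment."""
    if spec.thrombus_fraction <= 0 or spec.thrombus_depth_frac <= 0:
        return r_lum
    half_ang = np.pi * spec.thrombus_fraction
    c, w = spec.bulge_center_frac, spec.bulge_width_frac
    ang_ok = np.abs(theta) <= half_ang
    s_rel = (s_frac - c) / (w / 2)
    seg_ok = np.abs(s_rel) <= 1.0
    depth = np.zeros_like(r_lum)
    m = ang_ok & seg_ok
    if m.any():
        ang_taper = np.cos(0.5 * np.pi * np.abs(theta[m]) / half_ang)
        seg_taper = np.cos(0.5 * np.pi * np.abs(s_rel[m]))
        depth[m] = spec.thrombus_depth_frac * ang_taper * seg_taper
    return r_lum * (1.0 - depth)


def _voxel_centers(shape: tuple[int, int, int], spacing: tuple[float, float, float]
                   ) -> np.ndarray:
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    g = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def _build_curve(spec: PhantomSpec) -> tuple[CenterCurve, cKDTree]:
    curve = CenterCurve(spec.control_points())
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    r_max = spec.bulge_radius + spec.wall_thickness
    lo = curve.points.min(axis=0)
    hi = curve.points.max(axis=0)
    # radial containment is required in-plane; the tube may be cut by the
    # axial (z) faces, as clinical acquisitions crop the aorta
    if (lo[:2] - r_max < 0).any() or (hi[:2] + r_max > extent[:2]).any() or \
            lo[2] < -spec.spacing[2] or hi[2] > extent[2] + spec.spacing[2]:
        raise GeometryError(
            f"curve plus max outer radius {r_max:.1f} mm does not fit the "
            f"{tuple(spec.grid_shape)} grid of extent {np.round(extent, 1)} mm"
        )
    return curve, cKDTree(curve.points)


def _label_grid(spec: PhantomSpec, curve: CenterCurve, tree: cKDTree,
                shape: tuple[int, int, int], spacing: tuple[float, float, float]
                ) -> np.ndarray:
    pts = _voxel_centers(shape, spacing)
    return _classify_points(pts, spec, curve, tree).reshape(shape)


def _render(region: np.ndarray, model: IntensityModel, lumen_mean: float,
            noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    means = np.array([model.background, lumen_mean, model.wall, model.thrombus],
                     dtype=np.float32)
    img = means[region]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=region.shape).astype(np.float32)
    return img.astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, PhantomTruth]:
    """Generate the paired contrast / non-contrast rendition of one phantom.

    The label grid is a deterministic function of the spec; the seed controls
    only the additive Gaussian noise, so identical spec+seed gives
    bit-identical output.
    """
    curve, tree = _build_curve(spec)
    region = _label_grid(spec, curve, tree, spec.grid_shape, spec.spacing)
    labels = np.where(region == _LUMEN, LUMEN,
                      np.where(region >= _WALL, WALL_ILT, BACKGROUND)).astype(np.uint8)
    mask = LabelMask(labels, spec.spacing)

    rng = np.random.default_rng(spec.seed)
    im = spec.intensity_model
    contrast = Volume(_render(region, im, im.lumen_contrast, spec.noise_sd, rng),
                      spec.spacing)

    nc_mask: LabelMask | None = None
    if spec.noncontrast_slice_thickness and \
            abs(spec.noncontrast_slice_thickness - spec.spacing[2]) > 1e-9:
        sz = spec.noncontrast_slice_thickness
        nz = max(int(round(spec.grid_shape[2] * spec.spacing[2] / sz)), 4)
        nc_shape = (spec.grid_shape[0], spec.grid_shape[1], nz)
        nc_spacing = (spec.spacing[0], spec.spacing[1], sz)
        nc_region = _label_grid(spec, curve, tree, nc_shape, nc_spacing)
        nc_labels = np.where(nc_region == _LUMEN, LUMEN,
                             np.where(nc_region >= _WALL, WALL_ILT, BACKGROUND)
                             ).astype(np.uint8)
        nc_mask = LabelMask(nc_labels, nc_spacing)
        noncontrast = Volume(
            _render(nc_region, im, im.lumen_noncontrast, spec.noise_sd, rng),
            nc_spacing)
    else:
        noncontrast = Volume(_render(region, im, im.lumen_noncontrast,
                                     spec.noise_sd, rng), spec.spacing)
        nc_mask = mask

    truth = _make_truth(spec, curve, mask, region, nc_mask)
    return contrast, noncontrast, truth


def _make_truth(spec: PhantomSpec, curve: CenterCurve, mask: LabelMask,
                region: np.ndarray, nc_mask: LabelMask | None) -> PhantomTruth:
    arc = np.arange(0.0, curve.length + 1e-9, 1.0)
    s_frac = arc / curve.length
    lum_d = 2.0 * spec.lumen_radius(s_frac)
    out_d = lum_d + 2.0 * spec.wall_thickness
    vol = mask.voxel_volume_mm3
    lumen_v = float(np.count_nonzero(region == _LUMEN)) * vol
    ws_v = float(np.count_nonzero(region >= _WALL)) * vol
    return PhantomTruth(
        label_mask=mask,
        region_mask=region,
        centerline_points=curve.points.copy(),
        centerline_arc=curve.arc.copy(),
        profile_arc=arc,
        lumen_diameter_mm=lum_d,
        outer_diameter_mm=out_d,
        lumen_volume_mm3=lumen_v,
        ws_ilt_volume_mm3=ws_v,
        total_volume_mm3=lumen_v + ws_v,
        noncontrast_label_mask=nc_mask,
    )


# ----------------------------------------------------------------------
# sub-voxel oracle
# ----------------------------------------------------------------------


def subvoxel_volumes(spec: PhantomSpec, subdiv: int = 5) -> dict[str, float]:
    """Reference volumes by sub-voxel counting against the analytic geometry.

    Each voxel intersecting the surface band is subdivided ``subdiv``^3 and
    its sub-centers classified exactly; interior/exterior voxels are counted
    whole.  Returns lumen, wall/thrombus and total volumes in mm^3.
    """
    if subdiv < 2:
        raise ValueError("subdiv must be >= 2")
    curve, tree = _build_curve(spec)
    shape, spacing = spec.grid_shape, spec.spacing
    pts = _voxel_centers(shape, spacing)
    dist, idx = tree.query(pts, k=1, workers=-1)
    s_frac = curve.arc[idx] / curve.length
    r_lum = spec.lumen_radius(s_frac)
    r_out = r_lum + spec.wall_thickness
    band = max(spacing) * np.sqrt(3) / 2 + 1e-6
    # boundary voxels: near the outer surface, the lumen surface, or (when a
    # thrombus is present) anywhere inside the lumen radius in the bulge
    near = (np.abs(dist - r_out) < band) | (np.abs(dist - r_lum) < band)
    if spec.thrombus_fraction > 0 and spec.thrombus_depth_frac > 0:
        near |= dist < r_lum + band
    interior = ~near
    region_full = _classify_points(pts[interior], spec, curve, tree)
    vol = float(np.prod(spacing))
    counts = np.bincount(region_full, minlength=4).astype(float) * vol

    # refine the band
    b_pts = pts[near]
    offs = (np.arange(subdiv) + 0.5) / subdiv - 0.5
    sub_offsets = np.stack(np.meshgrid(offs * spacing[0], offs * spacing[1],
                                       offs * spacing[2], indexing="ij"),
                           axis=-1).reshape(-1, 3)
    sub_vol = vol / subdiv**3
    chunk = max(1, 2_000_000 // len(sub_offsets))
    for start in range(0, len(b_pts), chunk):
        blk = b_pts[start:start + chunk]
        sub = (blk[:, None, :] + sub_offsets[None, :, :]).reshape(-1, 3)
        reg = _classify_points(sub, spec, curve, tree)
        counts += np.bincount(reg, minlength=4).astype(float) * sub_vol

    lumen = counts[_LUMEN]
    ws = counts[_WALL] + counts[_THROMBUS]
    return {"lumen_mm3": lumen, "ws_ilt_mm3": ws, "total_mm3": lumen + ws}


# ----------------------------------------------------------------------
# diameter-profile oracle
# ----------------------------------------------------------------------


def analytic_profile(truth: PhantomTruth, step: float):
    """True outer-diameter profile sampled along arc length at ``step`` mm."""
    from .morphometry import DiameterProfile

    if step <= 0:
        raise ValueError("step must be positive")
    length = float(truth.centerline_arc[-1])
    if step > length:
        raise ValueError(f"step {step} mm exceeds curve length {length:.1f} mm")
    pos = np.arange(0.0, length + 1e-9, step)
    _, outer = truth.diameter_oracle(pos)
    return DiameterProfile(arc_mm=pos, diameter_mm=outer)


# ----------------------------------------------------------------------
# canonical specs and cohorts
# ----------------------------------------------------------------------


def straight_tube_spec(radius: float = 10.0, wall: float = 2.0,
                       grid: tuple[int, int, int] = (48, 48, 60),
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       **kw) -> PhantomSpec:
    """A straight axial cylinder (no bulge growth beyond epsilon, no
    thrombus) spanning the full z extent — the workhorse for analytic
    checks: lumen volume is exactly pi r^2 L with L = grid extent."""
    extent = np.asarray(grid) * np.asarray(spacing)
    cx, cy = extent[0] / 2, extent[1] / 2
    zs = np.linspace(0.0, extent[2], 5)
    pts = tuple((cx, cy, z) for z in zs)
    return PhantomSpec(
        grid_shape=grid, spacing=spacing,
        centerline_control_points=pts, tube_radius=radius,
        bulge_radius=radius + 1e-6 if "bulge_radius" not in kw else kw.pop("bulge_radius"),
        wall_thickness=wall, thrombus_fraction=0.0, thrombus_depth_frac=0.0,
        noncontrast_slice_thickness=None, **kw)


def default_abdominal_spec(seed: int = 0,
                           grid: tuple[int, int, int] = (96, 96, 96),
                           spacing: tuple[float, float, float] = (1.0, 1.0, 1.25)
                           ) -> PhantomSpec:
    """Desk-scale abdominal aneurysm analogue: gently curved aorta with a
    fusiform bulge (peak outer diameter ~48 mm, clearly aneurysmal) and a
    crescentic thrombus, at CTA-like slice thickness by default."""
    ex = np.asarray(grid) * np.asarray(spacing)
    cx, cy = ex[0] / 2, ex[1] / 2
    zf = np.array([0.02, 0.25, 0.50, 0.75, 0.98]) * ex[2]
    dx = np.array([-6.0, -2.0, 4.0, 2.0, -2.0])
    dy = np.array([4.0, 0.0, -4.0, -2.0, 2.0])
    pts = tuple((cx + a, cy + b, z) for a, b, z in zip(dx, dy, zf))
    return PhantomSpec(
        grid_shape=tuple(grid), spacing=tuple(spacing),
        centerline_control_points=pts, tube_radius=10.0, bulge_radius=22.0,
        bulge_center_frac=0.62, bulge_width_frac=0.36, wall_thickness=2.0,
        thrombus_fraction=0.55, thrombus_depth_frac=0.55, seed=seed)


def arch_spec(seed: int = 0, grid: tuple[int, int, int] = (96, 96, 112),
              spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)) -> PhantomSpec:
    """Candy-cane phantom with an aortic arch: ascending limb, arch, and a
    long descending/abdominal limb carrying the aneurysm.  Used to exercise
    the two-box (thoracic + abdominal) contrast ROI rule."""
    ex = np.asarray(grid) * np.asarray(spacing)
    cx = ex[0] / 2
    y_asc, y_desc = ex[1] * 0.62, ex[1] * 0.38
    z_top = 8.0
    pts = (
        (cx, y_asc, ex[2] * 0.38),          # aortic-root end of ascending limb
        (cx, y_asc, ex[2] * 0.18),
        (cx, (y_asc + y_desc) / 2, z_top),  # arch apex (most superior)
        (cx, y_desc, ex[2] * 0.18),
        (cx, y_desc, ex[2] * 0.45),
        (cx, y_desc, ex[2] * 0.70),
        (cx, y_desc, ex[2] * 0.97),         # iliac end
    )
    return PhantomSpec(
        grid_shape=grid, spacing=spacing, centerline_control_points=pts,
        tube_radius=9.0, bulge_radius=18.0, bulge_center_frac=0.80,
        bulge_width_frac=0.18, wall_thickness=2.0, thrombus_fraction=0.5,
        thrombus_depth_frac=0.5, seed=seed)


#: Cohort randomization ranges (documented constants).  Radii in mm follow
#: clinical scale: normal infrarenal aorta ~2 cm diameter, aneurysm >3 cm.
COHORT_RANGES = {
    "tube_radius": (8.0, 12.0),
    "bulge_radius_excess": (6.0, 14.0),   # bulge radius = tube + excess
    "bulge_center_frac": (0.50, 0.75),
    "bulge_width_frac": (0.25, 0.42),
    "wall_thickness": (1.5, 2.5),
    "thrombus_fraction": (0.3, 0.8),
    "thrombus_depth_frac": (0.35, 0.65),
    "bend_amplitude_mm": (0.0, 6.0),
}


def generate_cohort(n: int, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomSpec]:
    """Draw ``n`` randomized phantom specs around ``base_spec``.

    Curve control points get smooth lateral perturbations; radius, wall and
    thrombus parameters are drawn uniformly from :data:`COHORT_RANGES`.
    Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_spec or default_abdominal_spec()
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    extent = np.asarray(base.grid_shape) * np.asarray(base.spacing)
    for i in range(n):
        r = COHORT_RANGES
        tube = rng.uniform(*r["tube_radius"])
        bulge = tube + rng.uniform(*r["bulge_radius_excess"])
        cp = base.control_points().copy()
        amp = rng.uniform(*r["bend_amplitude_mm"])
        phase = rng.uniform(0, 2 * np.pi, size=2)
        zn = (cp[:, 2] - cp[0, 2]) / max(cp[-1, 2] - cp[0, 2], 1e-9)
        cp[:, 0] += amp * np.sin(np.pi * zn + phase[0])
        cp[:, 1] += amp * np.sin(np.pi * zn + phase[1])
        margin = bulge + base.wall_thickness + 2.0
        cp[:, :2] = np.clip(cp[:, :2], margin, extent[:2] - margin)
        specs.append(replace(
            base,
            centerline_control_points=tuple(map(tuple, cp)),
            tube_radius=float(tube),
            bulge_radius=float(bulge),
            bulge_center_frac=float(rng.uniform(*r["bulge_center_frac"])),
            bulge_width_frac=float(rng.uniform(*r["bulge_width_frac"])),
            wall_thickness=float(rng.uniform(*r["wall_thickness"])),
            thrombus_fraction=float(rng.uniform(*r["thrombus_fraction"])),
            thrombus_depth_frac=float(rng.uniform(*r["thrombus_depth_frac"])),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs
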