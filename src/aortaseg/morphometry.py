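"""Morphometric assessment of aortic segmentations.

Extracts the clinically reported 1-D/2-D/3-D measurements from label masks
(axial caliper diameters, the three-slice protocol, maximal axial area,
per-class volumes), second-order features (topology-preserving thinning
centerlines, diameter profiles in planes orthogonal to the centerline,
straightened/curved-planar views), and the agreement statistics used to
compare two measurement sources (DICE, closest-point and Hausdorff
centerline deviations, profile RMSE / percentage difference, Bland-Altman
bias with 95% CI and limits of agreement, Spearman rank correlation, ICC,
coefficients of variation).

Caliper conventions: in *axial* slices the AP diameter is the extent of the
largest in-plane component along the fixed anatomical y-axis and the
transverse diameter along x (extent = (index span + 1) x spacing, i.e. the
pixel-footprint caliper, so a single pixel measures one spacing unit).  In
*oblique* planes orthogonal to the centerline anatomical axes are
undefined, so the diameter is the maximal Feret diameter of the component
containing the centerline point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree, ConvexHull
from scipy.stats import spearmanr

from .core import LabelMask, Volume, require_same_geometry

__all__ = [
    "Centerline",
    "DiameterProfile",
    "MorphometryReport",
    "AgreementStats",
    "dice_score",
    "class_volumes",
    "axial_diameters",
    "three_slice_protocol",
    "max_axial_area",
    "extract_centerline",
    "centerline_deviation",
    "hausdorff_distance",
    "orthogonal_diameter_profile",
    "compare_profiles",
    "straightened_view",
    "agreement_stats",
    "morphometry_report",
]

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# types
# ----------------------------------------------------------------------


@dataclass
class Centerline:
    """Ordered world-mm points with cumulative arc length (superior first)."""

    points: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("centerline needs (n, 3) points, n >= 1")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if len(seg) and (seg <= 0).any():
            raise ValueError("consecutive centerline points must be distinct")
        self.arc_length = np.r_[0.0, np.cumsum(seg)]

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def at(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.clip(s, 0.0, self.length))
        return np.column_stack(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)])


@dataclass
class DiameterProfile:
    """Maximal diameter (mm) as a function of arc length (mm)."""

    arc_mm: np.ndarray
    diameter_mm: np.ndarray

    def __post_init__(self) -> None:
        self.arc_mm = np.asarray(self.arc_mm, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.arc_mm.shape != self.diameter_mm.shape:
            raise ValueError("arc and diameter arrays must align")
        if len(self.arc_mm) and (np.diff(self.arc_mm) <= 0).any():
            raise ValueError("profile positions must be strictly increasing")
        if (self.diameter_mm[np.isfinite(self.diameter_mm)] <= 0).any():
            raise ValueError("diameters must be positive where defined")

    @property
    def max_diameter_mm(self) -> float:
        return float(np.nanmax(self.diameter_mm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"arc_length_mm": self.arc_mm,
                             "diameter_mm": self.diameter_mm})


@dataclass
class ThreeSliceResult:
    """AP + transverse calipers at the max-AP slice and +/- 10 mm."""

    measurements: list[dict]  # slice_z, offset_mm, ap_mm, transverse_mm
    truncated: bool


@dataclass
class MorphometryReport:
    max_ap_diameter_mm: float
    max_transverse_diameter_mm: float
    max_axial_area_mm2: float
    lumen_volume_mm3: float
    ws_ilt_volume_mm3: float
    total_volume_mm3: float
    three_slice: ThreeSliceResult | None = None
    diameter_profile: DiameterProfile | None = None

    def to_dict(self) -> dict:
        d = {
            "max_ap_diameter_mm": self.max_ap_diameter_mm,
            "max_transverse_diameter_mm": self.max_transverse_diameter_mm,
            "max_axial_area_mm2": self.max_axial_area_mm2,
            "lumen_volume_mm3": self.lumen_volume_mm3,
            "ws_ilt_volume_mm3": self.ws_ilt_volume_mm3,
            "total_volume_mm3": self.total_volume_mm3,
        }
        if self.three_slice is not None:
            d["three_slice"] = {"measurements": self.three_slice.measurements,
                                "truncated": self.three_slice.truncated}
        if self.diameter_profile is not None:
            d["diameter_profile"] = {
                "arc_length_mm": self.diameter_profile.arc_mm.tolist(),
                "diameter_mm": self.diameter_profile.diameter_mm.tolist(),
            }
        return d


# ----------------------------------------------------------------------
# overlap and volumes
# ----------------------------------------------------------------------


def _binary(m: LabelMask, cls: int | None) -> np.ndarray:
    return m.foreground() if cls is None else m.binary(cls)


def dice_score(a: LabelMask, b: LabelMask, cls: int | None = None) -> float:
    """2|A n B| / (|A| + |B|) for one class (``None`` = any foreground);
    two empty sets score 1 by convention."""
    require_same_geometry(a, b)
    ba, bb = _binary(a, cls), _binary(b, cls)
    denom = int(np.count_nonzero(ba)) + int(np.count_nonzero(bb))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(ba & bb) / denom


def class_volumes(m: LabelMask) -> dict[str, float]:
    """Per-class volumes (mm^3): voxel count x voxel volume."""
    vv = m.voxel_volume_mm3
    lumen = float(np.count_nonzero(m.data == 1)) * vv
    ws = float(np.count_nonzero(m.data == 2)) * vv
    return {"lumen_mm3": lumen, "ws_ilt_mm3": ws, "total_mm3": lumen + ws}


# ----------------------------------------------------------------------
# axial calipers
# ----------------------------------------------------------------------


def _largest_component_2d(sl: np.ndarray) -> np.ndarray | None:
    lab, n = ndimage.label(sl)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def axial_diameters(m: LabelMask, cls: int | None = None) -> pd.DataFrame:
    """Per-axial-slice AP (y) and transverse (x) extents of the largest
    in-plane component, in mm.  Slices without the class are absent."""
    b = _binary(m, cls)
    sx, sy, _ = m.spacing
    rows = []
    for z in range(m.shape[2]):
        comp = _largest_component_2d(b[:, :, z])
        if comp is None:
            continue
        xs, ys = np.nonzero(comp)
        rows.append({
            "slice_z": z,
            "ap_mm": (ys.max() - ys.min() + 1) * sy,
            "transverse_mm": (xs.max() - xs.min() + 1) * sx,
        })
    return pd.DataFrame(rows, columns=["slice_z", "ap_mm", "transverse_mm"])


def three_slice_protocol(m: LabelMask, cls: int | None = None,
                         offset_mm: float = 10.0) -> ThreeSliceResult:
    """Six calipers from three slices: the max-AP slice and the nearest
    slices ``offset_mm`` above and below it.  A span exceeding the mask
    extent yields a truncated, flagged result."""
    df = axial_diameters(m, cls)
    if df.empty:
        raise ValueError("mask contains no voxels of the requested class")
    zmax = int(df.loc[df["ap_mm"].idxmax(), "slice_z"])
    dz = m.spacing[2]
    step = max(int(round(offset_mm / dz)), 1)
    present = set(df["slice_z"].astype(int))
    rows, truncated = [], False
    for off, z in ((-offset_mm, zmax - step), (0.0, zmax), (offset_mm, zmax + step)):
        if z in present:
            r = df[df["slice_z"] == z].iloc[0]
            rows.append({"slice_z": z, "offset_mm": off,
                         "ap_mm": float(r["ap_mm"]),
                         "transverse_mm": float(r["transverse_mm"])})
        else:
            truncated = True
            log.warning("three-slice protocol: slice at %+g mm missing", off)
    return ThreeSliceResult(rows, truncated)


def max_axial_area(m: LabelMask, cls: int | None = None) -> float:
    """Maximum over axial slices of in-plane voxel count x pixel area (mm^2)."""
    b = _binary(m, cls)
    if not b.any():
        return 0.0
    per_slice = b.sum(axis=(0, 1))
    return float(per_slice.max()) * m.spacing[0] * m.spacing[1]


# ----------------------------------------------------------------------
# centerlines
# ----------------------------------------------------------------------


def extract_centerline(m: LabelMask, cls: int | None = None) -> Centerline:
    """Centerline by topology-preserving 3D thinning.

    The class region (largest connected component if several, logged) is
    skeletonized with Lee's homotopic thinning; side branches are pruned to
    the longest geodesic path through the 26-connected skeleton graph,
    ordered superior -> inferior, and converted to world mm.
    """
    from skimage.morphology import skeletonize

    b = _binary(m, cls)
    if not b.any():
        raise ValueError("cannot extract a centerline from an empty class")
    lab, n = ndimage.label(b, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        log.warning("centerline: %d components, keeping largest (%d voxels)",
                    n, int(sizes[keep - 1]))
        b = lab == keep
    if np.count_nonzero(b) == 1:
        pt = np.argwhere(b)[0]
        return Centerline(pt[None, :] * np.asarray(m.spacing) + np.asarray(m.origin))
    skel = skeletonize(b)
    if not skel.any():  # tiny blobs can thin to nothing; fall back to centroid
        pt = np.mean(np.argwhere(b), axis=0)
        return Centerline(pt[None, :] * np.asarray(m.spacing) + np.asarray(m.origin))
    path_vox = _longest_path(np.argwhere(skel), np.asarray(m.spacing))
    pts = path_vox * np.asarray(m.spacing) + np.asarray(m.origin)
    if pts[0, 2] > pts[-1, 2] or (
            pts[0, 2] == pts[-1, 2]
            and tuple(pts[0])[::-1] > tuple(pts[-1])[::-1]):
        pts = pts[::-1]  # superior (low z index) first; lexicographic tie-break
    return Centerline(pts)


def _longest_path(vox: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Longest geodesic path through 26-connected voxels (double-sweep
    Dijkstra with path reconstruction)."""
    tree = cKDTree(vox)
    # neighbours within a 26-neighbourhood (chebyshev distance 1)
    pairs = tree.query_pairs(r=1.0 + 1e-9, p=np.inf, output_type="ndarray")
    if len(pairs) == 0:
        return vox[:1]
    d = np.linalg.norm((vox[pairs[:, 0]] - vox[pairs[:, 1]]) * spacing, axis=1)
    n = len(vox)
    g = coo_matrix((np.r_[d, d], (np.r_[pairs[:, 0], pairs[:, 1]],
                                  np.r_[pairs[:, 1], pairs[:, 0]])), shape=(n, n))
    g = g.tocsr()
    dist0 = dijkstra(g, indices=0)
    a = _farthest(dist0, vox)
    dist_a, pred = dijkstra(g, indices=a, return_predecessors=True)
    b = _farthest(dist_a, vox)
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return vox[np.array(path[::-1])]


def _farthest(dist: np.ndarray, vox: np.ndarray) -> int:
    finite = np.where(np.isfinite(dist), dist, -1.0)
    best = finite.max()
    cand = np.flatnonzero(finite >= best - 1e-9)
    # deterministic tie-break: lexicographically smallest endpoint voxel
    order = np.lexsort(vox[cand].T[::-1])
    return int(cand[order[0]])


def centerline_deviation(c1: Centerline, c2: Centerline,
                         symmetric: bool = True) -> float:
    """Mean closest-point (Euclidean) distance between two centerlines,
    symmetrized by averaging both directions."""
    d12 = _directed_mean(c1.points, c2.points)
    if not symmetric:
        return d12
    return 0.5 * (d12 + _directed_mean(c2.points, c1.points))


def _directed_mean(a: np.ndarray, b: np.ndarray) -> float:
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.mean(d))


def hausdorff_distance(c1: Centerline, c2: Centerline) -> float:
    """Symmetric Hausdorff distance: the greatest distance from a point of
    one line to the closest point of the other (upper bound of the mean
    closest-point deviation)."""
    d12, _ = cKDTree(c2.points).query(c1.points, k=1)
    d21, _ = cKDTree(c1.points).query(c2.points, k=1)
    return float(max(d12.max(), d21.max()))


# ----------------------------------------------------------------------
# orthogonal-plane measurements
# ----------------------------------------------------------------------


def _smoothed_tangents(c: Centerline, window: int = 5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Moving-average smoothing of the points, tangents by finite
    differences along arc length."""
    pts = c.points
    if len(pts) >= window:
        kernel = np.ones(window) / window
        # odd reflection keeps the endpoints fixed (no end shrinkage)
        sm = np.column_stack([
            np.convolve(np.pad(pts[:, k], window // 2, mode="reflect",
                               reflect_type="odd"), kernel, mode="valid")
            for k in range(3)])
    else:
        sm = pts.copy()
    if len(sm) == 1:
        return sm, np.array([[0.0, 0.0, 1.0]])
    t = np.gradient(sm, axis=0)
    nrm = np.linalg.norm(t, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return sm, t / nrm


def _frames_along(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n1 = np.empty_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, tangents[0]) * tangents[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, len(tangents)):
        v = n1[i - 1] - np.dot(n1[i - 1], tangents[i]) * tangents[i]
        nn = np.linalg.norm(v)
        n1[i] = v / nn if nn > 1e-12 else n1[i - 1]
    return n1, np.cross(tangents, n1)


def _plane_samples(vol: Volume, center: np.ndarray, n1: np.ndarray,
                   n2: np.ndarray, half_width_mm: float, res_mm: float,
                   order: int) -> tuple[np.ndarray, float]:
    r = np.arange(-half_width_mm, half_width_mm + 1e-9, res_mm)
    u, v = np.meshgrid(r, r, indexing="ij")
    pts = (center[None, None, :] + u[..., None] * n1[None, None, :]
           + v[..., None] * n2[None, None, :])
    idx = vol.world_to_index(pts.reshape(-1, 3)).T
    out = ndimage.map_coordinates(np.asarray(vol.data, np.float32), idx,
                                  order=order, mode="constant", cval=0.0)
    return out.reshape(u.shape), res_mm


def orthogonal_diameter_profile(m: LabelMask, c: Centerline,
                                step_mm: float = 1.0, cls: int | None = None,
                                half_width_mm: float | None = None
                                ) -> DiameterProfile:
    """Maximal Feret diameter of the mask in planes orthogonal to the
    centerline, sampled every ``step_mm`` of arc length.

    The in-plane component containing the centerline point is measured; a
    plane where the point falls outside the class (or outside the grid) is
    marked missing and dropped from the profile.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    b = _binary(m, cls).astype(np.float32)
    bvol = Volume(b, m.spacing, m.origin)
    if half_width_mm is None:
        half_width_mm = 0.5 * float(max(np.asarray(m.shape)[:2]
                                        * np.asarray(m.spacing)[:2]))
        half_width_mm = min(half_width_mm, 60.0)
    res = float(min(m.spacing))
    sm, tg = _smoothed_tangents(c)
    sm_arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))]
    positions = np.arange(0.0, sm_arc[-1] + 1e-9, step_mm)
    arcs, diams = [], []
    for s in positions:
        i = int(np.searchsorted(sm_arc, s, side="right")) - 1
        i = min(max(i, 0), len(sm) - 1)
        if i + 1 < len(sm) and sm_arc[i + 1] > sm_arc[i]:
            w = (s - sm_arc[i]) / (sm_arc[i + 1] - sm_arc[i])
            center = (1 - w) * sm[i] + w * sm[i + 1]
            tang = (1 - w) * tg[i] + w * tg[i + 1]
        else:
            center, tang = sm[i], tg[i]
        tang = tang / np.linalg.norm(tang)
        n1, n2 = _frames_along(tang[None])
        plane, _ = _plane_samples(bvol, center, n1[0], n2[0], half_width_mm,
                                  res, order=0)
        d = _feret_of_center_component(plane > 0.5, res)
        if d is not None:
            arcs.append(s)
            diams.append(d)
    return DiameterProfile(np.asarray(arcs), np.asarray(diams))


def _feret_of_center_component(plane: np.ndarray, res_mm: float) -> float | None:
    h = plane.shape[0]
    ci = h // 2
    lab, n = ndimage.label(plane)
    if n == 0 or lab[ci, ci] == 0:
        return None
    comp = lab == lab[ci, ci]
    pts = np.argwhere(comp).astype(float)
    if len(pts) == 1:
        return res_mm
    if len(pts) > 3:
        # boundary of convex hull is enough for the max pairwise distance
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # collinear points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    dmax = np.sqrt((diff**2).sum(-1)).max()
    return float(max(dmax * res_mm, res_mm))


def compare_profiles(p1: DiameterProfile, p2: DiameterProfile
                     ) -> tuple[float, float]:
    """(RMSE mm, mean percentage difference) over the overlapping arc range;
    the second profile is linearly interpolated onto the first's positions."""
    lo = max(p1.arc_mm.min(), p2.arc_mm.min())
    hi = min(p1.arc_mm.max(), p2.arc_mm.max())
    if hi <= lo:
        raise ValueError("profiles do not overlap in arc length")
    sel = (p1.arc_mm >= lo) & (p1.arc_mm <= hi)
    d1 = p1.diameter_mm[sel]
    d2 = np.interp(p1.arc_mm[sel], p2.arc_mm, p2.diameter_mm)
    diff = d1 - d2
    rmse = float(np.sqrt(np.mean(diff**2)))
    mean_pair = (d1 + d2) / 2.0
    pct = float(np.mean(np.abs(diff) / mean_pair) * 100.0)
    return rmse, pct


def straightened_view(v: Volume, c: Centerline, half_width_mm: float = 40.0,
                      step_mm: float = 1.0) -> Volume:
    """Curved-planar ('straightened') reformation: orthogonal-plane resamples
    stacked along arc length (output z-axis = arc length)."""
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    res = float(min(v.spacing))
    sm, tg = _smoothed_tangents(c)
    sm_arc = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))]
    positions = np.arange(0.0, sm_arc[-1] + 1e-9, step_mm)
    slices = []
    for s in positions:
        center = np.column_stack(
            [np.interp(s, sm_arc, sm[:, k]) for k in range(3)])[0]
        tang = np.column_stack(
            [np.interp(s, sm_arc, tg[:, k]) for k in range(3)])[0]
        tang = tang / np.linalg.norm(tang)
        n1, n2 = _frames_along(tang[None])
        plane, _ = _plane_samples(v, center, n1[0], n2[0], half_width_mm, res,
                                  order=1)
        slices.append(plane)
    data = np.stack(slices, axis=-1)
    return Volume(data.astype(np.float32), (res, res, step_mm))


# ----------------------------------------------------------------------
# agreement statistics
# ----------------------------------------------------------------------


@dataclass
class AgreementStats:
    """Bland-Altman / reliability summary of paired measurements."""

    n: int
    bias: float
    bias_ci95: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    sd_diff: float
    spearman_r: float
    icc: float
    pct_cv: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "bias": self.bias,
            "bias_ci95": list(self.bias_ci95),
            "limits_of_agreement": list(self.limits_of_agreement),
            "sd_diff": self.sd_diff, "spearman_r": self.spearman_r,
            "icc": self.icc, "pct_cv": self.pct_cv,
        }


def agreement_stats(pairs) -> AgreementStats:
    """Agreement between measured and reference values.

    ``pairs`` is a sequence of (measured, reference).  Bias is the mean
    difference with its 95% CI (bias +/- 1.96 SD/sqrt(n)); limits of
    agreement are bias +/- 1.96 SD.  ICC is the two-way random, absolute
    agreement, single-rater variant (ICC(2,1)); %CV is the RMS over pairs
    of each pair's SD divided by its mean (zero-mean pairs are excluded and
    logged).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (measured, reference) pairs")
    x, y = arr[:, 0], arr[:, 1]
    diff = x - y
    n = len(arr)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half_ci = 1.96 * sd / np.sqrt(n)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        rho = 1.0 if np.allclose(x, y) else float("nan")
    else:
        rho = float(spearmanr(x, y).statistic)
    means = (x + y) / 2.0
    keep = np.abs(means) > 1e-12
    if not keep.all():
        log.warning("%%CV: excluding %d zero-mean pair(s)", int((~keep).sum()))
    pair_sd = np.abs(diff[keep]) / np.sqrt(2.0)
    pct_cv = float(np.sqrt(np.mean((pair_sd / np.abs(means[keep]))**2)) * 100.0) \
        if keep.any() else float("nan")
    return AgreementStats(
        n=n, bias=bias,
        bias_ci95=(bias - half_ci, bias + half_ci),
        limits_of_agreement=(bias - 1.96 * sd, bias + 1.96 * sd),
        sd_diff=sd, spearman_r=rho, icc=icc_two_way_single(x, y),
        pct_cv=pct_cv)


def icc_two_way_single(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    import pingouin as pg

    n = len(x)
    df = pd.DataFrame({
        "target": np.r_[np.arange(n), np.arange(n)],
        "rater": ["a"] * n + ["b"] * n,
        "rating": np.r_[x, y],
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="rating")
    # label differs across pingouin versions: "ICC2" vs "ICC(A,1)"
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


# ----------------------------------------------------------------------
# convenience report
# ----------------------------------------------------------------------


def morphometry_report(m: LabelMask, cls: int | None = None,
                       with_profile: bool = True,
                       profile_step_mm: float = 2.0) -> MorphometryReport:
    """Full per-volume measurement record for one mask."""
    df = axial_diameters(m, cls)
    vols = class_volumes(m)
    profile = None
    three = None
    if not df.empty:
        three = three_slice_protocol(m, cls)
        if with_profile:
            cl = extract_centerline(m, cls)
            if len(cl.points) > 1:
                profile = orthogonal_diameter_profile(m, cl, profile_step_mm, cls)
    return MorphometryReport(
        max_ap_diameter_mm=float(df["ap_mm"].max()) if not df.empty else 0.0,
        max_transverse_diameter_mm=(float(df["transverse_mm"].max())
                                    if not df.empty else 0.0),
        max_axial_area_mm2=max_axial_area(m, cls),
        lumen_volume_mm3=vols["lumen_mm3"],
        ws_ilt_volume_mm3=vols["ws_ilt_mm3"],
        total_volume_mm3=vols["total_mm3"],
        three_slice=three,
        diameter_profile=profile,
    )
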