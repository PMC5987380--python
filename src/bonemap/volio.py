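"""Volume I/O and preprocessing for whole-bone micro-CT analysis.

Volumes are (z, y, x) arrays with isotropic voxels; z is proximodistal with
z = 0 at the proximal end, and percent-of-length positions are measured from
the proximal end.  Stacks are stored as multi-page TIFF with a JSON sidecar
carrying the voxel size — a stack without a stated voxel size is rejected
rather than assumed.

The preprocessing chain mirrors standard whole-bone workflows: global
minimum thresholding, per-slice connected-component tracking to remove the
fibula, principal-axis (or landmark-chord) longitudinal alignment, and
anchoring of the metaphyseal trabecular region of interest at the
"trabecular bridge" slice where the two primary-spongiosa islands connect.

Connectivity conventions are fixed package-wide: 26-connectivity in 3D,
8-connectivity in 2D.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

STRUCT_3D = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
STRUCT_2D = np.ones((3, 3), dtype=bool)      # 8-connectivity


@dataclass
class VoxelVolume:
    """A 3D scalar or boolean lattice with isotropic voxel size in microns."""

    data: np.ndarray
    voxel_um: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    @property
    def shape(self):
        return self.data.shape


def write_stack(vol: VoxelVolume, path) -> None:
    """Multi-page TIFF plus JSON sidecar; boolean data stored as uint8."""
    path = Path(path)
    data = vol.data
    is_binary = data.dtype == bool
    tifffile.imwrite(path, data.astype(np.uint8) if is_binary else data,
                     photometric="minisblack")
    sidecar = {
        "voxel_um": float(vol.voxel_um),
        "axis_order": "zyx",
        "dtype": str(data.dtype),
        "is_binary": is_binary,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> VoxelVolume:
    """Read a TIFF stack; the sidecar must state an isotropic voxel size."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing sidecar {sidecar_path}: voxel size unknown; "
                         "refusing to assume a default")
    sidecar = json.loads(sidecar_path.read_text())
    voxel = sidecar.get("voxel_um")
    if voxel is None:
        raise ValueError("sidecar lacks voxel_um")
    if isinstance(voxel, (list, tuple)):
        if len(set(float(v) for v in voxel)) != 1:
            raise ValueError(f"anisotropic voxels {voxel} are not supported")
        voxel = float(voxel[0])
    data = tifffile.imread(path)
    if data.ndim != 3 or min(data.shape) < 2:
        raise ValueError(f"not a 3D volume: shape {data.shape}")
    if sidecar.get("is_binary"):
        data = data.astype(bool)
    return VoxelVolume(data, float(voxel))


def _grayscale_percentiles(data: np.ndarray) -> str:
    qs = [1, 25, 50, 75, 99, 100]
    vals = np.percentile(data, qs)
    return ", ".join(f"p{q}={v:.3g}" for q, v in zip(qs, vals))


def threshold_minimum(vol: VoxelVolume, thr: float) -> VoxelVolume:
    """Global minimum threshold: bone where value >= thr."""
    data = vol.data
    if thr > data.max():
        raise ValueError(
            f"threshold {thr:g} above grayscale maximum; "
            f"percentiles: {_grayscale_percentiles(data)}")
    mask = data >= thr
    if not mask.any():
        raise ValueError(
            f"empty mask at threshold {thr:g}; "
            f"percentiles: {_grayscale_percentiles(data)}")
    return VoxelVolume(mask, vol.voxel_um)


def suggest_threshold(vol: VoxelVolume) -> float:
    """Otsu threshold on the grayscale histogram, as a starting point."""
    return float(threshold_otsu(vol.data))


def despeckle(vol: VoxelVolume, min_size: int = 50) -> VoxelVolume:
    """Drop 26-connected components smaller than ``min_size`` voxels.

    Standard post-threshold cleanup: isolated noise speckles are not bone.
    """
    mask = vol.data.astype(bool)
    lbl, n = ndimage.label(mask, structure=STRUCT_3D)
    if n == 0:
        return VoxelVolume(mask, vol.voxel_um)
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return VoxelVolume(np.isin(lbl, keep), vol.voxel_um)


# ---------------------------------------------------------------------------
# fibula removal


def remove_fibula(vol: VoxelVolume, seed_point=None) -> tuple[VoxelVolume, dict]:
    """Keep the tibial component chain; drop secondary (fibula) components.

    Per-slice 8-connected components are tracked from the proximal end: the
    retained chain starts at the largest proximal component (or a supplied
    (y, x) seed point) and follows the nearest-centroid component slice to
    slice.  Where a previously separate secondary component fuses with the
    chain, the slice is split by a watershed on the distance transform
    seeded at the two tracked centroids and only the tibial half is kept;
    affected slices are logged in the returned info dict.
    """
    mask = vol.data
    if not mask.any():
        raise ValueError("empty mask")
    out = np.zeros_like(mask)
    info = {"fused_slices": [], "removed_voxels": 0}
    nz = mask.shape[0]
    ks = [k for k in range(nz) if mask[k].any()]
    k0 = ks[0]
    lbl, n = ndimage.label(mask[k0], structure=STRUCT_2D)
    areas = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
    if seed_point is not None:
        tib_lab = lbl[tuple(np.asarray(seed_point, dtype=int))]
        if tib_lab == 0:
            raise ValueError("seed point not on bone")
    else:
        order = np.argsort(areas)[::-1]
        if n > 1 and areas[order[0]] == areas[order[1]]:
            raise ValueError(
                "ambiguous proximal slice: two equal-size components; "
                "supply a manual seed point")
        tib_lab = int(order[0]) + 1
    tib_centroid = np.array(ndimage.center_of_mass(mask[k0], lbl, tib_lab))
    tib_area = float(areas[tib_lab - 1])
    prev_tib = None
    fib_centroid = None
    fib_area = 0.0

    for k in ks:
        lbl, n = ndimage.label(mask[k], structure=STRUCT_2D)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        cents = np.array(ndimage.center_of_mass(mask[k], lbl, idx), ndmin=2)
        areas = ndimage.sum_labels(np.ones_like(lbl), lbl, index=idx)
        # track by overlap with the previous tibial slice; fall back to the
        # nearest centroid where slices do not overlap (e.g. strong shift)
        if prev_tib is not None:
            overlaps = ndimage.sum_labels(prev_tib.astype(np.float64), lbl,
                                          index=idx)
        else:
            overlaps = np.zeros(n)
        if overlaps.max() > 0:
            tib_lab = int(idx[np.argmax(overlaps)])
        else:
            d = np.linalg.norm(cents - tib_centroid, axis=1)
            tib_lab = int(idx[np.argmin(d)])
        tib_slice = lbl == tib_lab
        fused = (
            fib_centroid is not None
            and tib_slice[tuple(np.clip(np.round(fib_centroid).astype(int), 0,
                                        np.array(tib_slice.shape) - 1))]
            and areas[tib_lab - 1] > tib_area + 0.5 * max(fib_area, 1.0)
        )
        if fused:
            # split the merged component between the two tracked centroids
            dist = ndimage.distance_transform_edt(tib_slice)
            markers = np.zeros(tib_slice.shape, dtype=np.int32)
            tc = np.clip(np.round(tib_centroid).astype(int), 0,
                         np.array(tib_slice.shape) - 1)
            fc = np.clip(np.round(fib_centroid).astype(int), 0,
                         np.array(tib_slice.shape) - 1)
            markers[tuple(tc)] = 1
            markers[tuple(fc)] = 2
            split = watershed(-dist, markers, mask=tib_slice)
            tib_slice = split == 1
            fib_centroid = np.array(ndimage.center_of_mass(split == 2)) \
                if (split == 2).any() else fib_centroid
            info["fused_slices"].append(k)
        # intramedullary components (inside the filled tibial silhouette)
        # are trabecular bone, not fibula: keep them
        filled_tib = ndimage.binary_fill_holes(tib_slice)
        keep = tib_slice.copy()
        exterior = []
        for lab in idx:
            if lab == tib_lab:
                continue
            comp = lbl == lab
            if filled_tib[comp].all():
                keep |= comp
            else:
                exterior.append(lab)
        if not fused and exterior:
            big = max(exterior, key=lambda lab: areas[lab - 1])
            fib_centroid = cents[big - 1]
            fib_area = float(areas[big - 1])
        out[k] = keep
        prev_tib = tib_slice
        tib_centroid = np.array(ndimage.center_of_mass(tib_slice))
        tib_area = float(tib_slice.sum())
    info["removed_voxels"] = int(mask.sum() - out.sum())
    return VoxelVolume(out, vol.voxel_um), info


# ---------------------------------------------------------------------------
# longitudinal alignment


@dataclass
class AlignedBone:
    """Binary bone volume in canonical proximodistal orientation."""

    mask: np.ndarray
    voxel_um: float
    length_mm: float
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    @property
    def n_slices(self) -> int:
        return self.mask.shape[0]

    def percentile_index(self, percent: float) -> int:
        """Slice index at percent of bone length from the proximal end."""
        if not 0.0 <= percent <= 100.0:
            raise ValueError(f"percent {percent} outside [0, 100]")
        return int(round(percent / 100.0 * (self.n_slices - 1)))


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix (zyx coords) sending the unit vector ``axis`` to +z."""
    z = np.array([1.0, 0.0, 0.0])  # z is the first array axis
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def align_longitudinal(vol: VoxelVolume, landmarks=None,
                       angle_tol_deg: float = 0.1) -> AlignedBone:
    """Rotate the bone so its long axis is parallel to z, then crop.

    Default mode aligns the principal inertia axis of the voxel cloud;
    landmark mode aligns the chord through two supplied (z, y, x) voxel
    points.  Binary data is resampled nearest-neighbour so voxel counts are
    preserved to within resampling tolerance.  Rotations smaller than
    ``angle_tol_deg`` are skipped (identity path).
    """
    mask = vol.data.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask).astype(float)
    center = coords.mean(axis=0)
    if landmarks is not None:
        p1, p2 = (np.asarray(p, dtype=float) for p in landmarks)
        axis = p2 - p1
        axis /= np.linalg.norm(axis)
    else:
        cov = np.cov((coords - center).T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < 2.0 * evals[-2]:
            raise ValueError("no dominant longitudinal axis: voxel cloud is "
                             "nearly isotropic")
        axis = evecs[:, -1]
    if axis[0] < 0:
        axis = -axis
    rot = _rotation_to_z(axis)
    angle = np.degrees(np.arccos(np.clip(rot.trace() / 2.0 - 0.5, -1, 1)))

    if angle < angle_tol_deg:
        aligned = mask
        transform = np.eye(4)
    else:
        # output bounding box of the rotated input corners
        shp = np.array(mask.shape, dtype=float)
        corners = np.array([[i, j, k] for i in (0, shp[0]) for j in (0, shp[1])
                            for k in (0, shp[2])])
        rc = (corners - center) @ rot.T
        lo, hi = rc.min(axis=0), rc.max(axis=0)
        out_shape = np.ceil(hi - lo).astype(int) + 3
        out_center = (out_shape - 1) / 2.0
        # affine_transform maps output voxel o to input voxel R^T (o-c') + c
        offset = center - rot.T @ out_center
        aligned = ndimage.affine_transform(
            mask.astype(np.uint8), rot.T, offset=offset,
            output_shape=tuple(out_shape), order=0, prefilter=False).astype(bool)
        transform = np.eye(4)
        transform[:3, :3] = rot
        transform[:3, 3] = out_center - rot @ center

    occ = np.any(aligned, axis=(1, 2))
    z_idx = np.flatnonzero(occ)
    occ_y = np.flatnonzero(np.any(aligned, axis=(0, 2)))
    occ_x = np.flatnonzero(np.any(aligned, axis=(0, 1)))
    pad = 2
    cropped = aligned[
        z_idx[0]:z_idx[-1] + 1,
        max(occ_y[0] - pad, 0):occ_y[-1] + 1 + pad,
        max(occ_x[0] - pad, 0):occ_x[-1] + 1 + pad,
    ]
    length_mm = cropped.shape[0] * vol.voxel_um / 1000.0
    return AlignedBone(cropped, vol.voxel_um, length_mm, transform)


# ---------------------------------------------------------------------------
# trabecular ROI anchoring


def slice_envelope(slice_mask: np.ndarray) -> np.ndarray:
    """Interior envelope of one slice: filled cortical shell minus the shell.

    The cortical shell is the union of 2D components touching the outer
    boundary of the filled silhouette; the envelope is the shell's interior,
    which contains the medullary cavity and any trabecular bone within it.
    """
    if not slice_mask.any():
        return np.zeros_like(slice_mask)
    filled = ndimage.binary_fill_holes(slice_mask)
    boundary = filled & ~ndimage.binary_erosion(filled, structure=STRUCT_2D)
    lbl, n = ndimage.label(slice_mask, structure=STRUCT_2D)
    outer_labels = np.unique(lbl[boundary])
    cortex = np.isin(lbl, outer_labels[outer_labels > 0])
    return ndimage.binary_fill_holes(cortex) & ~cortex


def _intramedullary(mask: np.ndarray) -> np.ndarray:
    env = np.zeros_like(mask)
    for k in range(mask.shape[0]):
        env[k] = slice_envelope(mask[k])
    return mask & env


def find_trabecular_reference(aligned: AlignedBone, min_size: int = 27) -> int:
    """Slice where the two primary-spongiosa islands first connect.

    Returns the most proximal slice index k such that the intramedullary
    bone in slices [0, k] forms a single 26-connected component (components
    smaller than ``min_size`` voxels are ignored).  A single island from the
    start returns its most proximal slice with a warning.
    """
    intra = _intramedullary(aligned.mask)
    if not intra.any():
        raise ValueError("no intramedullary bone: cannot anchor trabecular ROI")

    def ncomp(k):
        lbl, n = ndimage.label(intra[:k + 1], structure=STRUCT_3D)
        if n == 0:
            return 0
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
        return int((sizes >= min_size).sum())

    nz = intra.shape[0]
    kmax = int(np.flatnonzero(np.any(intra, axis=(1, 2)))[-1])
    if ncomp(kmax) > 1:
        raise ValueError("intramedullary islands never connect; supply a "
                         "manual reference slice")
    k_first = int(np.flatnonzero(np.any(intra, axis=(1, 2)))[0])
    # grow a window until two islands are visible; if never, degenerate case
    k_two = None
    k = k_first
    while k <= kmax:
        n = ncomp(k)
        if n >= 2:
            k_two = k
            break
        if n == 1 and k > k_first + max(3, nz // 50):
            break
        k += 1
    if k_two is None:
        warnings.warn("single continuous intramedullary lattice; using its "
                      "most proximal slice as reference")
        return k_first
    lo, hi = k_two, kmax          # ncomp(lo) >= 2, ncomp(hi) == 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ncomp(mid) == 1:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class TrabecularROI:
    """Anchored trabecular region: bone mask and interior envelope."""

    bone: np.ndarray
    envelope: np.ndarray
    slices: tuple[int, int]
    voxel_um: float


def extract_trabecular_roi(aligned: AlignedBone, ref_slice: int,
                           fraction: float = 0.05) -> TrabecularROI:
    """ROI spanning ``fraction`` of bone length distal of the reference slice."""
    nz = aligned.n_slices
    n_roi = int(round(fraction * nz))
    if n_roi < 1:
        raise ValueError(f"fraction {fraction:g} yields an empty ROI")
    if ref_slice < 0 or ref_slice + n_roi > nz:
        raise ValueError(f"ROI [{ref_slice}, {ref_slice + n_roi}) exits the "
                         f"volume of {nz} slices")
    sl = slice(ref_slice, ref_slice + n_roi)
    sub = aligned.mask[sl]
    env = np.zeros_like(sub)
    for k in range(sub.shape[0]):
        env[k] = slice_envelope(sub[k])
    return TrabecularROI(sub & env, env, (ref_slice, ref_slice + n_roi),
                         aligned.voxel_um)
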