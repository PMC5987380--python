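"""Synthetic long-bone phantoms with analytic ground truth.

A phantom emulates a murine tibia: a hollow cortical shaft whose
cross-section is an elliptical ring with prescribed semi-axis, wall-thickness
and ellipticity profiles along the bone, whose centroid follows a circular
arc (one-parameter curvature, quantified by the midshaft sagitta), plus an
optional fibula-like secondary rod, an optional metaphyseal trabecular
lattice with a known "bridge" slice, and two calibration rods of known
attenuation outside the bone.

Every geometric quantity the downstream morphometry measures is also
available in closed form (:class:`GroundTruth`), computed from the
continuous specification and never from voxels — the one exception being
trabecular bone volume fraction, whose realized voxel count on the phantom
grid is itself the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from ._ellipse import WALL_MODES, ring_properties, voxelize_ellipse, voxelize_ring
from .volio import VoxelVolume

Profile = Callable[[np.ndarray], np.ndarray]


def as_profile(value) -> Profile:
    """Wrap a scalar as a constant profile of normalized length z in [0, 1]."""
    if callable(value):
        return value
    return lambda z, v=float(value): np.full_like(np.asarray(z, dtype=float), v)


@dataclass
class FibulaSpec:
    """A straight secondary rod running parallel to the tibial shaft."""

    radius_mm: float = 0.15
    offset_mm: float = 0.9          # in-plane distance from the tibial centroid
    offset_angle_deg: float = 90.0  # direction of that offset
    span: tuple[float, float] = (0.10, 0.80)  # z-fraction range
    fused: bool = False             # if True the rod touches the cortex


@dataclass
class TrabLatticeSpec:
    """Periodic trabecular lattice clipped to the metaphyseal envelope.

    ``span`` anchors the lattice in normalized length; ``bridge_z`` is the
    slice (as a z fraction) at which the two primary-spongiosa islands are
    connected by a one-plate "bridge" — the landmark the reference finder
    must recover.
    """

    lattice_kind: str = "rods"      # rods | plates | spheres-removed
    spacing_mm: float = 0.25
    element_thickness_mm: float = 0.06
    principal_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    target_bvtv_percent: float | None = None
    span: tuple[float, float] = (0.04, 0.18)
    bridge_z: float = 0.07
    island_gap_mm: float = 0.25

    def validate(self) -> None:
        if self.lattice_kind not in ("rods", "plates", "spheres-removed"):
            raise ValueError(f"unknown lattice kind {self.lattice_kind!r}")
        if self.spacing_mm <= self.element_thickness_mm:
            raise ValueError("lattice spacing must exceed element thickness")
        if not self.span[0] <= self.bridge_z <= self.span[1]:
            raise ValueError("bridge_z must lie inside the lattice span")


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic bone."""

    length_mm: float = 17.0
    voxel_um: float = 5.0
    outer_a: object = 0.75          # scalar or profile, mm (semi-major)
    outer_b: object = 0.60          # scalar or profile, mm (semi-minor)
    wall_thickness: object = 0.25   # scalar or profile, mm
    wall_mode: str = "offset"
    curvature_sagitta_mm: float = 0.0
    curvature_plane_angle_deg: float = 0.0
    fibula: FibulaSpec | None = None
    trabecular: TrabLatticeSpec | None = None
    bone_value: float = 150.0
    background_value: float = 10.0
    noise_sd: float = 0.0
    #: attenuation of the two density-calibration rods; None omits them
    calibration_rod_values: tuple[float, float] | None = (80.0, 200.0)
    seed: int = 0

    def profiles(self) -> tuple[Profile, Profile, Profile]:
        return (as_profile(self.outer_a), as_profile(self.outer_b),
                as_profile(self.wall_thickness))

    def validate(self) -> None:
        if self.length_mm <= 0 or self.voxel_um <= 0:
            raise ValueError("length_mm and voxel_um must be positive")
        if self.wall_mode not in WALL_MODES:
            raise ValueError(f"unknown wall mode {self.wall_mode!r}")
        a_p, b_p, t_p = self.profiles()
        z = np.linspace(0.0, 1.0, 257)
        a, b, t = a_p(z), b_p(z), t_p(z)
        bad = ~(t < np.minimum(a, b))
        if bad.any():
            raise ValueError(
                f"degenerate annulus: wall >= semi-axis at z={z[bad][0]:.3f}"
            )
        vox_mm = self.voxel_um / 1000.0
        if (t / vox_mm).min() < 4.0:
            raise ValueError(
                f"thinnest wall {t.min():.4f} mm spans fewer than 4 voxels at "
                f"voxel_um={self.voxel_um:g}; refine the grid"
            )
        if self.trabecular is not None:
            self.trabecular.validate()


@dataclass
class GroundTruth:
    """Closed-form per-slice section properties plus realized trabecular truth."""

    z_mm: np.ndarray
    csa: np.ndarray
    i_min: np.ndarray
    i_max: np.ndarray
    j: np.ndarray
    ellipticity: np.ndarray
    ct_th: np.ndarray
    centroid_xy_mm: np.ndarray      # (nz, 2)
    filled_area: np.ndarray
    r_eq: np.ndarray
    arm_mm: np.ndarray              # perpendicular centroid-to-chord distance
    length_mm: float
    voxel_um: float
    fibula_mask: np.ndarray | None = None
    trab_mask: np.ndarray | None = None
    envelope_mask: np.ndarray | None = None
    rod_masks: tuple[np.ndarray, np.ndarray] | None = None
    bridge_slice: int | None = None
    realized_bvtv_percent: float | None = None
    tb_th_mm: float | None = None
    fabric_direction: np.ndarray | None = None

    def profile_frame(self, percents: Sequence[float]) -> pd.DataFrame:
        """Ground-truth section properties sampled at percent-of-length sites."""
        nz = len(self.z_mm)
        idx = np.clip(np.round(np.asarray(percents) / 100.0 * (nz - 1)), 0, nz - 1)
        idx = idx.astype(int)
        return pd.DataFrame({
            "percent": np.asarray(percents, dtype=float),
            "slice": idx,
            "csa_mm2": self.csa[idx],
            "i_min_mm4": self.i_min[idx],
            "i_max_mm4": self.i_max[idx],
            "j_mm4": self.j[idx],
            "ellipticity": self.ellipticity[idx],
            "ct_th_mm": self.ct_th[idx],
            "arm_mm": self.arm_mm[idx],
            "r_eq_mm": self.r_eq[idx],
        })


def arc_deviation(z_mm: np.ndarray, length_mm: float, sagitta_mm: float) -> np.ndarray:
    """Perpendicular deviation of a circular arc from its chord.

    The arc passes through both bone ends and deviates by the sagitta at
    midshaft; zero sagitta gives a straight axis.
    """
    z = np.asarray(z_mm, dtype=float)
    if sagitta_mm == 0.0:
        return np.zeros_like(z)
    half = length_mm / 2.0
    r_arc = (sagitta_mm**2 + half**2) / (2.0 * sagitta_mm)
    return np.sqrt(np.maximum(r_arc**2 - (z - half) ** 2, 0.0)) - (r_arc - sagitta_mm)


def _lattice_pattern(spec: TrabLatticeSpec, xg, yg, zg, rng) -> np.ndarray:
    """Periodic bone-phase pattern evaluated at voxel centres (mm coords)."""
    n = np.asarray(spec.principal_direction, dtype=float)
    n /= np.linalg.norm(n)
    # orthonormal frame (u, v, n)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    s = spec.spacing_mm
    cu = xg * u[0] + yg * u[1] + zg * u[2]
    cv = xg * v[0] + yg * v[1] + zg * v[2]
    cn = xg * n[0] + yg * n[1] + zg * n[2]
    if spec.lattice_kind == "plates":
        # slabs normal to the u axis -> fabric long axes lie in the plate plane
        t = (s * spec.target_bvtv_percent / 100.0
             if spec.target_bvtv_percent is not None else spec.element_thickness_mm)
        if not 0 < t < s:
            raise ValueError(f"plate thickness {t:g} outside achievable (0, {s:g})")
        return np.mod(cu, s) < t
    if spec.lattice_kind == "rods":
        # rods along n on a square grid in the (u, v) plane
        if spec.target_bvtv_percent is not None:
            frac = spec.target_bvtv_percent / 100.0
            if frac >= np.pi / 4:
                raise ValueError(
                    f"rod lattice cannot reach BV/TV {spec.target_bvtv_percent:g}%;"
                    f" achievable range is (0, {100 * np.pi / 4:.1f}%)"
                )
            r = s * np.sqrt(frac / np.pi)
        else:
            r = spec.element_thickness_mm / 2.0
        du = np.mod(cu, s) - s / 2.0
        dv = np.mod(cv, s) - s / 2.0
        return du**2 + dv**2 < r**2
    # spheres-removed: solid minus a cubic lattice of spherical voids
    if spec.target_bvtv_percent is None:
        return np.ones(np.broadcast_shapes(xg.shape, yg.shape, zg.shape), dtype=bool)
    frac = spec.target_bvtv_percent / 100.0
    r3 = 3.0 * s**3 * (1.0 - frac) / (4.0 * np.pi)
    r = r3 ** (1.0 / 3.0)
    du = np.mod(cu + s / 2.0, s) - s / 2.0
    dv = np.mod(cv + s / 2.0, s) - s / 2.0
    dn = np.mod(cn + s / 2.0, s) - s / 2.0
    return du**2 + dv**2 + dn**2 >= r**2


def generate_trabecular_lattice(
    spec: TrabLatticeSpec,
    envelope: np.ndarray,
    voxel_um: float,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Periodic lattice clipped to a boolean envelope volume (z, y, x order).

    Returns the bone mask and the realized metrics: BV/TV from voxel counts
    (the ground truth), the nominal element thickness, and the principal
    fabric direction.
    """
    spec.validate()
    vox = voxel_um / 1000.0
    nz, ny, nx = envelope.shape
    zc = (np.arange(nz) + 0.5) * vox + origin_mm[2]
    yc = (np.arange(ny) + 0.5) * vox + origin_mm[1]
    xc = (np.arange(nx) + 0.5) * vox + origin_mm[0]
    zg = zc[:, None, None]
    yg = yc[None, :, None]
    xg = xc[None, None, :]
    rng = np.random.default_rng(seed)
    pattern = _lattice_pattern(spec, xg, yg, zg, rng)
    mask = pattern & envelope
    n_env = int(envelope.sum())
    if n_env == 0:
        raise ValueError("empty envelope")
    realized = {
        "bvtv_percent": 100.0 * mask.sum() / n_env,
        "target_bvtv_percent": spec.target_bvtv_percent,
        "tb_th_mm": spec.element_thickness_mm,
        "fabric_direction": np.asarray(spec.principal_direction, dtype=float)
        / np.linalg.norm(spec.principal_direction),
    }
    return mask, realized


def _rod_positions(half_x: float, half_y: float, rod_r: float, vox: float):
    x = half_x + rod_r + 4 * vox
    return [(x, -half_y / 2.0), (x, half_y / 2.0)]


def generate_bone(spec: PhantomSpec) -> tuple[VoxelVolume, VoxelVolume, GroundTruth]:
    """Voxelize one phantom.

    Returns the grayscale volume (attenuation units, partial-volume blur and
    optional Gaussian noise, calibration rods included), the exact binary
    bone volume (centre-point inclusion, no anti-aliasing), and the analytic
    ground truth.  Arrays are indexed (z, y, x) with z proximodistal,
    z = 0 proximal.
    """
    spec.validate()
    vox = spec.voxel_um / 1000.0
    nz = int(round(spec.length_mm / vox))
    zc = (np.arange(nz) + 0.5) * vox
    zfrac = zc / spec.length_mm
    a_p, b_p, t_p = spec.profiles()
    a, b, t = a_p(zfrac), b_p(zfrac), t_p(zfrac)

    dev = arc_deviation(zc, spec.length_mm, spec.curvature_sagitta_mm)
    phi = np.deg2rad(spec.curvature_plane_angle_deg)
    cx = dev * np.cos(phi)
    cy = dev * np.sin(phi)

    # grid extents: bone + fibula + margin; calibration rods beyond +x
    margin = 4 * vox
    half_x = (np.abs(cx) + a).max() + margin
    half_y = (np.abs(cy) + a).max() + margin
    if spec.fibula is not None:
        f = spec.fibula
        ang = np.deg2rad(f.offset_angle_deg)
        half_x = max(half_x, (np.abs(cx + f.offset_mm * np.cos(ang)) + f.radius_mm).max() + margin)
        half_y = max(half_y, (np.abs(cy + f.offset_mm * np.sin(ang)) + f.radius_mm).max() + margin)
    rod_r = 6 * vox
    if spec.calibration_rod_values is not None:
        rods_xy = _rod_positions(half_x, half_y, rod_r, vox)
        x_max = rods_xy[0][0] + rod_r + margin
    else:
        rods_xy = []
        x_max = half_x
    nx = int(np.ceil(2 * x_max / vox))
    ny = int(np.ceil(2 * half_y / vox))
    xc = (np.arange(nx) - (nx - 1) / 2.0) * vox
    yc = (np.arange(ny) - (ny - 1) / 2.0) * vox
    xg = xc[None, :]
    yg = yc[:, None]

    binary = np.zeros((nz, ny, nx), dtype=bool)
    for k in range(nz):
        binary[k] = voxelize_ring(xg, yg, cx[k], cy[k], a[k], b[k], t[k],
                                  mode=spec.wall_mode)

    fibula_mask = None
    if spec.fibula is not None:
        f = spec.fibula
        ang = np.deg2rad(f.offset_angle_deg)
        fibula_mask = np.zeros_like(binary)
        k0, k1 = (int(round(f.span[0] * nz)), int(round(f.span[1] * nz)))
        for k in range(k0, k1):
            fibula_mask[k] = voxelize_ellipse(
                xg, yg, cx[k] + f.offset_mm * np.cos(ang),
                cy[k] + f.offset_mm * np.sin(ang), f.radius_mm, f.radius_mm)
        binary |= fibula_mask

    trab_mask = None
    envelope_mask = None
    bridge_slice = None
    realized = {}
    if spec.trabecular is not None:
        ts = spec.trabecular
        k0, k1 = int(round(ts.span[0] * nz)), int(round(ts.span[1] * nz))
        bridge_slice = int(round(ts.bridge_z * nz))
        # medullary envelope: the cavity interior, eroded four voxels so the
        # lattice stays separated from the cortex even after the one-voxel
        # partial-volume blur dilates both under thresholding
        envelope_mask = np.zeros_like(binary)
        for k in range(k0, k1):
            outer_full = voxelize_ellipse(xg, yg, cx[k], cy[k], a[k], b[k])
            cavity = outer_full & ~binary[k]
            envelope_mask[k] = ndimage.binary_erosion(
                cavity, structure=np.ones((3, 3), dtype=bool), iterations=4)
        lattice, realized = generate_trabecular_lattice(
            ts, envelope_mask, spec.voxel_um,
            origin_mm=(xc[0] - vox / 2.0, yc[0] - vox / 2.0, 0.0), seed=spec.seed)
        # two islands split by an in-plane gap, each with a connecting spine,
        # joined only by a one-plate bridge at the bridge slice
        gap = ts.island_gap_mm / 2.0
        trab_mask = np.zeros_like(binary)
        spine_r = max(ts.element_thickness_mm / 2.0, 2 * vox)
        for k in range(k0, k1):
            side_l = (xg - cx[k]) < -gap
            side_r = (xg - cx[k]) > gap
            sl = lattice[k] & np.broadcast_to(side_l | side_r, lattice[k].shape)
            # spines keep each island 26-connected along z
            for sx in (-(gap + spec.trabecular.spacing_mm / 2.0),
                       gap + spec.trabecular.spacing_mm / 2.0):
                sl |= voxelize_ellipse(xg, yg, cx[k] + sx, cy[k],
                                       spine_r, spine_r) & envelope_mask[k]
            trab_mask[k] = sl & envelope_mask[k]
        if k0 <= bridge_slice < k1:
            # bridge plate as thick as a trabecular element so it survives
            # partial-volume blur and thresholding
            nb = max(int(np.ceil(ts.element_thickness_mm / vox)), 2)
            for kk in range(bridge_slice, min(bridge_slice + nb, k1)):
                trab_mask[kk] |= envelope_mask[kk]
        binary |= trab_mask
        n_env = envelope_mask[k0:k1].sum()
        realized["bvtv_percent"] = 100.0 * trab_mask[k0:k1].sum() / max(n_env, 1)

    # grayscale: bone + calibration rods, partial-volume blur, noise
    gray = np.full(binary.shape, spec.background_value, dtype=np.float32)
    gray[binary] = spec.bone_value
    rod_masks = []
    for (rx, ry), val in zip(rods_xy, spec.calibration_rod_values or ()):
        rm = np.broadcast_to(voxelize_ellipse(xg, yg, rx, ry, rod_r, rod_r),
                             binary.shape)
        rod_masks.append(np.ascontiguousarray(rm))
        gray[rm] = val
    gray = gaussian_filter(gray, sigma=1.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, gray.shape).astype(np.float32)

    props = [ring_properties(a[k], b[k], t[k], mode=spec.wall_mode)
             for k in range(nz)]
    gt = GroundTruth(
        z_mm=zc,
        csa=np.array([p["csa"] for p in props]),
        i_min=np.array([p["i_min"] for p in props]),
        i_max=np.array([p["i_max"] for p in props]),
        j=np.array([p["j"] for p in props]),
        ellipticity=np.array([p["ellipticity"] for p in props]),
        ct_th=np.array([p["ct_th"] for p in props]),
        centroid_xy_mm=np.column_stack([cx, cy]),
        filled_area=np.array([p["filled_area"] for p in props]),
        r_eq=np.array([p["r_eq"] for p in props]),
        arm_mm=dev,
        length_mm=spec.length_mm,
        voxel_um=spec.voxel_um,
        fibula_mask=fibula_mask,
        trab_mask=trab_mask,
        envelope_mask=envelope_mask,
        rod_masks=tuple(rod_masks),
        bridge_slice=bridge_slice,
        realized_bvtv_percent=realized.get("bvtv_percent"),
        tb_th_mm=realized.get("tb_th_mm"),
        fabric_direction=realized.get("fabric_direction"),
    )
    grayscale = VoxelVolume(gray, spec.voxel_um)
    binary_vol = VoxelVolume(binary, spec.voxel_um)
    return grayscale, binary_vol, gt


# ---------------------------------------------------------------------------
# factorial cohorts


@dataclass
class Effect:
    """A parameter shift applied to the animals matching ``where``.

    ``where`` maps factor names to required levels (a conjunction), so a
    single-factor entry encodes a main-effect shift and a multi-factor entry
    a cell-specific (interaction-bearing) shift.
    """

    param: str
    where: dict
    add: float = 0.0
    mul: float = 1.0


#: baseline shaft parameters for a cohort animal (mm unless noted);
#: ellipticity is the principal second-moment ratio Imax/Imin of the section.
DEFAULT_BASELINE = {
    "length_mm": 17.0,
    "a_mid_mm": 0.75,
    "ellipticity": 1.5,
    "wall_mm": 0.25,
    "sagitta_mm": 0.25,
    "taper": 0.25,
    "bump_amount": 0.0,
    "bump_lo": 0.30,
    "bump_hi": 0.40,
}


@dataclass
class CohortDesign:
    """Full 2 (genotype) x 2 (sex) x 3 (age) factorial cohort."""

    genotypes: tuple[str, str] = ("CBA", "STR")
    sexes: tuple[str, str] = ("M", "F")
    ages: tuple[int, ...] = (10, 20, 40)
    n_per_cell: int = 5
    baseline: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    effect_map: list[Effect] = field(default_factory=list)
    noise_map: dict = field(default_factory=dict)
    voxel_um: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        known = set(self.baseline)
        for e in self.effect_map:
            if e.param not in known:
                raise ValueError(f"effect references unknown parameter {e.param!r}")
            for f in e.where:
                if f not in ("genotype", "sex", "age"):
                    raise ValueError(f"unknown factor {f!r} in effect")
        for p in self.noise_map:
            if p not in known:
                raise ValueError(f"noise references unknown parameter {p!r}")


def build_spec(params: dict, voxel_um: float = 5.0, seed: int = 0,
               trabecular: TrabLatticeSpec | None = None) -> PhantomSpec:
    """Phantom spec from a flat cohort parameter dict.

    The semi-major axis follows a symmetric quadratic flare
    a(z) = a_mid * (1 + taper * (2z - 1)^2); the ellipticity profile is a
    baseline plus a rectangular bump on [bump_lo, bump_hi]; the wall uses the
    ``scaled`` model so the section's Imax/Imin equals the ellipticity
    parameter exactly.
    """
    p = params

    def a_prof(z, p=dict(p)):
        return p["a_mid_mm"] * (1.0 + p["taper"] * (2.0 * np.asarray(z) - 1.0) ** 2)

    def e_prof(z, p=dict(p)):
        z = np.asarray(z, dtype=float)
        e = np.full_like(z, p["ellipticity"])
        e[(z >= p["bump_lo"]) & (z <= p["bump_hi"])] += p["bump_amount"]
        return e

    # scaled wall model: Imax/Imin = (a/b)**2 exactly, so b = a / sqrt(e)
    def b_prof(z, a_prof=a_prof, e_prof=e_prof):
        return a_prof(z) / np.sqrt(e_prof(z))

    return PhantomSpec(
        length_mm=p["length_mm"],
        voxel_um=voxel_um,
        outer_a=a_prof,
        outer_b=b_prof,
        wall_thickness=p["wall_mm"],
        wall_mode="scaled",
        curvature_sagitta_mm=p["sagitta_mm"],
        trabecular=trabecular,
        seed=seed,
    )


def generate_cohort(design: CohortDesign) -> tuple[list[tuple[dict, PhantomSpec]], pd.DataFrame]:
    """Materialize a factorial cohort.

    Returns one (parameter dict, PhantomSpec) per animal plus the covariate
    table (animal id, genotype, sex, age, per-animal seed).  Identical design
    seeds reproduce identical cohorts bit for bit.
    """
    design.validate()
    cells = [(g, s, a) for g in design.genotypes for s in design.sexes
             for a in design.ages]
    n_animals = len(cells) * design.n_per_cell
    children = np.random.SeedSequence(design.seed).spawn(n_animals)
    animals = []
    rows = []
    i = 0
    for g, s, a in cells:
        for _ in range(design.n_per_cell):
            seed_i = int(children[i].generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(seed_i)
            params = dict(design.baseline)
            for e in design.effect_map:
                levels = {"genotype": g, "sex": s, "age": a}
                if all(levels[f] == v for f, v in e.where.items()):
                    params[e.param] = params[e.param] * e.mul + e.add
            for pname, sd in design.noise_map.items():
                params[pname] = params[pname] + rng.normal(0.0, sd)
            spec = build_spec(params, voxel_um=design.voxel_um, seed=seed_i)
            animals.append((params, spec))
            rows.append({"animal": f"a{i:03d}", "genotype": g, "sex": s,
                         "age": a, "seed": seed_i})
            i += 1
    return animals, pd.DataFrame(rows)


def cohort_groundtruth_profiles(
    animals: list[tuple[dict, PhantomSpec]],
    covariates: pd.DataFrame,
    percents: Sequence[float],
    measurement_sd: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Analytic per-percent section properties for every cohort animal.

    This evaluates each animal's ground truth in closed form — no
    voxelization — and optionally adds per-site Gaussian measurement noise
    (``measurement_sd`` maps response column to sd), emulating what the image
    pipeline would report.  Long format: one row per (animal, percent).
    """
    rng = np.random.default_rng(seed)
    percents = np.asarray(percents, dtype=float)
    frames = []
    for (params, spec), (_, cov) in zip(animals, covariates.iterrows()):
        zf = percents / 100.0
        a_p, b_p, t_p = spec.profiles()
        a, b, t = a_p(zf), b_p(zf), t_p(zf)
        props = [ring_properties(a[k], b[k], t[k], mode=spec.wall_mode)
                 for k in range(len(zf))]
        dev = arc_deviation(zf * spec.length_mm, spec.length_mm,
                            spec.curvature_sagitta_mm)
        df = pd.DataFrame({
            "percent": percents,
            "csa_mm2": [p["csa"] for p in props],
            "i_min_mm4": [p["i_min"] for p in props],
            "i_max_mm4": [p["i_max"] for p in props],
            "j_mm4": [p["j"] for p in props],
            "ellipticity": [p["ellipticity"] for p in props],
            "ct_th_mm": [p["ct_th"] for p in props],
            "arm_mm": dev,
        })
        for col in ("animal", "genotype", "sex", "age"):
            df[col] = cov[col]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if measurement_sd:
        for col, sd in measurement_sd.items():
            out[col] = out[col] + rng.normal(0.0, sd, len(out))
    return out
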