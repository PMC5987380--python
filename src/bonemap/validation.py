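"""End-to-end validation suites against analytic ground truth.

Because no scan data ships with the package, validation is oracle-based:
every suite generates phantoms whose morphometry is known in closed form,
runs the production measurement path on the voxelized data, and reports the
discrepancies.  The suites double as the package's acceptance battery:

* geometry: randomized elliptical-ring sections vs closed-form CSA, Imin,
  Imax, J and wall thickness, plus rotation invariance;
* trabecular: lattice phantoms vs voxel-count BV/TV, analytic plate/rod
  thickness and separation, fabric-anisotropy ordering and invariance;
* curvature: arc phantoms vs the prescribed sagitta and normalized lever
  arm;
* statistics: factorial-model type-I error and localized-interaction
  recovery on synthetic cohorts;
* determinism: byte-identical reruns of the demo pipeline.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom, shapeload, statmap, trabecular, volio
from ._ellipse import ring_properties, voxelize_ring
from .cortical import profile_whole_bone, slice_geometry


def _pixel_grid(extent_mm: float, voxel_mm: float):
    n = int(np.ceil(2 * extent_mm / voxel_mm))
    g = (np.arange(n) - (n - 1) / 2.0) * voxel_mm
    return g[None, :], g[:, None]


def geometry_oracle_suite(seed: int = 0, n_phantoms: int = 20,
                          voxel_um: float = 12.5) -> dict:
    """Randomized constant-wall elliptical rings vs closed form.

    Walls are kept thick relative to the pixel size (the documented
    accuracy floor of inscribed-disc thickness); the outer semi-minor axis
    always spans >= 40 pixels.  Reports worst-case relative errors (%),
    the polar-moment identity residual, and worst-case rotation
    non-invariance (%) over a random section orientation per phantom.
    """
    rng = np.random.default_rng(seed)
    vox = voxel_um / 1000.0
    worst = {k: 0.0 for k in ("csa", "i_min", "i_max", "j", "ct_th")}
    j_resid = 0.0
    rot_dev = 0.0
    angle_err = 0.0
    for _ in range(n_phantoms):
        b = rng.uniform(1.3, 1.6)
        a = b * rng.uniform(1.02, 1.25)
        t = rng.uniform(0.75, min(0.95, 0.85 * b * b / a))
        truth = ring_properties(a, b, t, mode="offset")
        xg, yg = _pixel_grid(a + 4 * vox, vox)
        m = voxelize_ring(xg, yg, 0.0, 0.0, a, b, t, mode="offset")
        sg = slice_geometry(m, voxel_um)
        meas = {"csa": sg.csa_mm2, "i_min": sg.i_min_mm4,
                "i_max": sg.i_max_mm4, "j": sg.j_mm4, "ct_th": sg.ct_th_mm}
        for k in worst:
            worst[k] = max(worst[k], abs(meas[k] / truth[k] - 1.0))
        j_resid = max(j_resid, abs(sg.j_mm4 - sg.i_min_mm4 - sg.i_max_mm4))
        theta = rng.uniform(15.0, 75.0)
        mr = voxelize_ring(xg, yg, 0.0, 0.0, a, b, t, mode="offset",
                           angle_deg=theta)
        sr = slice_geometry(mr, voxel_um)
        for v0, v1 in ((sg.csa_mm2, sr.csa_mm2), (sg.i_min_mm4, sr.i_min_mm4),
                       (sg.i_max_mm4, sr.i_max_mm4), (sg.j_mm4, sr.j_mm4)):
            rot_dev = max(rot_dev, abs(v1 / v0 - 1.0))
        shift = abs((sr.principal_angle_deg - sg.principal_angle_deg) % 180.0)
        shift = min(shift, 180.0 - shift)
        angle_err = max(angle_err, abs(shift - theta))
    return {
        "max_rel_err_pct": {k: 100.0 * v for k, v in worst.items()},
        "j_identity_max_abs": j_resid,
        "rotation_max_dev_pct": 100.0 * rot_dev,
        "principal_angle_max_err_deg": angle_err,
        "n_phantoms": n_phantoms,
    }


def trabecular_oracle_suite(seed: int = 0, n_directions: int = 128,
                            voxel_um: float = 50.0) -> dict:
    """Lattice phantoms vs voxel-count and analytic oracles."""
    shape = (64, 64, 64)
    env = np.ones(shape, dtype=bool)
    vox = voxel_um / 1000.0
    zz, yy, xx = np.mgrid[:shape[0], :shape[1], :shape[2]]
    c = (np.array(shape) - 1) / 2.0
    voi = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= 26**2

    plates = phantom.TrabLatticeSpec("plates", spacing_mm=0.4,
                                     element_thickness_mm=0.1,
                                     principal_direction=(0, 1, 0),
                                     span=(0, 1), bridge_z=0.5)
    m_pl, r_pl = phantom.generate_trabecular_lattice(plates, env, voxel_um,
                                                     seed=seed)
    bvtv_meas = trabecular.bvtv(m_pl, env)
    bvtv_exact = abs(bvtv_meas - r_pl["bvtv_percent"]) == 0.0
    # realized plate thickness/gap on this grid (whole voxel layers)
    t_real = round(plates.element_thickness_mm / vox) * vox
    s_real = plates.spacing_mm
    th_err_vox = abs(trabecular.tb_th(m_pl, voxel_um) - t_real) / vox
    sp_err_vox = abs(trabecular.tb_sp(m_pl, env, voxel_um)
                     - (s_real - t_real)) / vox

    rods = phantom.TrabLatticeSpec("rods", spacing_mm=0.4,
                                   element_thickness_mm=0.15, span=(0, 1),
                                   bridge_z=0.5, target_bvtv_percent=25.0)
    m_rod, _ = phantom.generate_trabecular_lattice(rods, env, voxel_um,
                                                   seed=seed)
    iso = phantom.TrabLatticeSpec("spheres-removed", spacing_mm=0.4,
                                  element_thickness_mm=0.1, span=(0, 1),
                                  bridge_z=0.5, target_bvtv_percent=25.0)
    m_iso, _ = phantom.generate_trabecular_lattice(iso, env, voxel_um,
                                                   seed=seed)
    da_pl, _ = trabecular.degree_of_anisotropy(m_pl, n_directions, voi=voi)
    da_rod, info_rod = trabecular.degree_of_anisotropy(m_rod, n_directions,
                                                       voi=voi)
    da_iso, _ = trabecular.degree_of_anisotropy(m_iso, n_directions, voi=voi)
    # rotation invariance: the same rod lattice tilted 30 degrees
    ang = np.deg2rad(30.0)
    rods_tilt = phantom.TrabLatticeSpec(
        "rods", spacing_mm=0.4, element_thickness_mm=0.15, span=(0, 1),
        bridge_z=0.5, target_bvtv_percent=25.0,
        principal_direction=(0.0, np.sin(ang), np.cos(ang)))
    m_tilt, _ = phantom.generate_trabecular_lattice(rods_tilt, env, voxel_um,
                                                    seed=seed)
    da_tilt, _ = trabecular.degree_of_anisotropy(m_tilt, n_directions, voi=voi)
    return {
        "bvtv_percent": bvtv_meas,
        "bvtv_matches_voxel_count": bool(bvtv_exact),
        "plate_tb_th_err_vox": th_err_vox,
        "plate_tb_sp_err_vox": sp_err_vox,
        "da_plates": da_pl,
        "da_rods": da_rod,
        "da_isotropic": da_iso,
        "da_ordering_ok": bool(da_pl > da_rod > da_iso),
        "da_rotation_delta": abs(da_tilt - da_rod),
        "rod_axis_alignment_deg": float(np.degrees(np.arccos(
            min(abs(info_rod["long_axis"][0]), 1.0)))),
    }


def curvature_suite(seed: int = 0, voxel_um: float = 25.0,
                    sagittas=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5)) -> dict:
    """Arc phantoms: recover midshaft moment arm and normalized lever arm."""
    vox = voxel_um / 1000.0
    arm_err_vox = 0.0
    lever_err_pct = 0.0
    straight_zero = True
    for s in sagittas:
        spec = phantom.PhantomSpec(
            length_mm=8.0, voxel_um=voxel_um, outer_a=1.0, outer_b=0.8,
            wall_thickness=0.25, wall_mode="axis", curvature_sagitta_mm=s,
            calibration_rod_values=None, seed=seed)
        _, binary, gt = phantom.generate_bone(spec)
        aligned = volio.AlignedBone(binary.data, voxel_um, spec.length_mm)
        prof = profile_whole_bone(aligned)
        arms = shapeload.moment_arm_profile(prof)
        lever = shapeload.curvature_lever_arm(prof, arms)
        i50 = int(np.argwhere(prof.percents == 50.0)[0][0])
        mid = len(gt.arm_mm) // 2
        truth_lever = gt.arm_mm[mid] / gt.r_eq[mid]
        if s == 0.0:
            straight_zero = straight_zero and float(arms.arm_mm.max()) == 0.0 \
                and lever == 0.0
        else:
            arm_err_vox = max(arm_err_vox, abs(arms.arm_mm[i50] - s) / vox)
            lever_err_pct = max(lever_err_pct,
                                100.0 * abs(lever / truth_lever - 1.0))
    return {
        "straight_bone_exactly_zero": bool(straight_zero),
        "midshaft_arm_max_err_vox": arm_err_vox,
        "lever_arm_max_err_pct": lever_err_pct,
        "sagittas_mm": list(sagittas),
    }


def localized_effect_suite(seed: int = 0, n_per_cell: int = 5) -> dict:
    """Recovery of a genotype-by-sex interaction injected at 30-40% only.

    The cohort carries a +0.3 ellipticity shift for one genotype-sex cell
    restricted to the 30-40% window, animal-level parameter noise and
    small per-site measurement noise.  Reports the fraction of non-blue
    interaction bands inside the window and the fraction of blue bands
    outside it.
    """
    design = phantom.CohortDesign(
        n_per_cell=n_per_cell,
        effect_map=[phantom.Effect("bump_amount",
                                   {"genotype": "STR", "sex": "M"}, add=0.3)],
        noise_map={"ellipticity": 0.05},
        seed=seed)
    animals, cov = phantom.generate_cohort(design)
    percents = np.arange(10.0, 91.0)
    profiles = phantom.cohort_groundtruth_profiles(
        animals, cov, percents, measurement_sd={"ellipticity": 0.01},
        seed=seed)
    res = statmap.heatmap_statmap(profiles, ["ellipticity"])["ellipticity"]
    row = list(statmap.EFFECTS).index("genotype:sex")
    bands = res.bands[row]
    inside = (percents >= 30.0) & (percents <= 40.0)
    frac_nonblue_inside = float((bands[inside] != "blue").mean())
    frac_blue_outside = float((bands[~inside] == "blue").mean())
    return {
        "interaction_frac_nonblue_inside_window": frac_nonblue_inside,
        "interaction_frac_blue_outside_window": frac_blue_outside,
        "window_percent": [30.0, 40.0],
    }


def _csv_digest(run_dir: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(run_dir).glob("*.csv")) + sorted(
            Path(run_dir).glob("*.json")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def determinism_check(seed: int = 0, base_dir=None) -> dict:
    """Run the demo pipeline twice; numeric outputs must be byte-identical."""
    import tempfile

    from .cli import RunConfig, run_pipeline

    with tempfile.TemporaryDirectory(dir=base_dir) as tmp:
        d1 = run_pipeline(RunConfig(seed=seed), Path(tmp) / "run1")
        d2 = run_pipeline(RunConfig(seed=seed), Path(tmp) / "run2")
        h1, h2 = _csv_digest(d1), _csv_digest(d2)
    return {"identical": bool(h1 == h2), "digest": h1}


def band_rule_check() -> dict:
    """Exact half-open binning of the four-colour significance rule."""
    cases = {0.0009: "red", 0.001: "yellow", 0.0099: "yellow", 0.01: "green",
             0.049: "green", 0.05: "blue", 0.5: "blue", 0.0: "red",
             1.0: "blue"}
    ok = all(statmap.significance_bands(p) == b for p, b in cases.items())
    return {"boundary_cases_ok": bool(ok), "n_cases": len(cases)}
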