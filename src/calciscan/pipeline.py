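"""Analysis orchestration: physical pre/post comparison, treatment-group
isotope comparison, genotype isotope/regression analysis, and the
simulated scan pipeline.

Each ``run_*`` function returns a JSON-serializable dict (an analysis
report).  Reports are deterministic given inputs and seed; every number
in a report is produced by an operation in :mod:`calciscan.fixtures`,
:mod:`calciscan.densitometry`, :mod:`calciscan.thickness` or
:mod:`calciscan.stats_core`.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from calciscan._version import __version__
from calciscan import stats_core
from calciscan.densitometry import (
    calibrate_scan,
    ccn,
    segment_shell,
    specimen_summary,
)
from calciscan.errors import CalibrationError, ValidationError
from calciscan.fixtures import (
    CTRecord,
    IsotopeRecord,
    paired_differences,
)
from calciscan.thickness import local_thickness, mean_wall_thickness
from calciscan.volume import AttenuationVolume

logger = logging.getLogger(__name__)

GENOTYPE_ORDER = ("Ia", "Ib", "IIa")
#: minimum shell-weight range (ug) for a genotype to get its own regression
WIDE_WEIGHT_RANGE_UG = 3.0


def _digest(records) -> dict:
    h = hashlib.sha256(repr(records).encode()).hexdigest()[:16]
    return {"n": len(records), "sha256_16": h}


def _summary(summary) -> dict:
    return {"first": summary.first, "second": summary.second,
            "mean_diff": summary.mean_diff, "min_diff": summary.min_diff,
            "max_diff": summary.max_diff, "n": summary.n,
            "diffs": list(summary.diffs)}


def run_physical_comparison(records: list[CTRecord]) -> dict:
    """Paired pre/post CCN and wall-thickness comparison.

    Reports signed mean differences for post1-post2 and pre-post2 CCN,
    the thickness difference mean/min/max, paired t-tests per contrast,
    and the relative variation (mean signed pre-post2 CCN difference over
    the grand-mean pre CCN, in percent).  The published "1.05%" figure
    never states its denominator, so the operationalization used here is
    recorded in the report.
    """
    if len(records) < 2:
        raise ValidationError("physical comparison needs >= 2 specimens")
    d_post = paired_differences(records, "post1_ccn", "post2_ccn")
    d_pre = paired_differences(records, "pre_ccn", "post2_ccn")
    d_thick = paired_differences(records, "pre_thick", "post2_thick")
    grand_pre = float(np.mean([r.pre_ccn for r in records]))
    cols = {c: [getattr(r, c) for r in records]
            for c in ("pre_ccn", "post1_ccn", "post2_ccn",
                      "pre_thick", "post2_thick")}
    return {
        "analysis": "physical_comparison",
        "version": __version__,
        "input": _digest(records),
        "ccn_post1_vs_post2": _summary(d_post),
        "ccn_pre_vs_post2": _summary(d_pre),
        "thickness_pre_vs_post2": _summary(d_thick),
        "relative_variation_pct": d_pre.mean_diff / grand_pre * 100.0,
        "relative_variation_note": (
            "mean signed pre-post2 CCN difference / grand-mean pre CCN * 100;"
            " published operationalization unstated"),
        "tests": {
            "ccn_post1_vs_post2": stats_core.paired_t_test(
                cols["post1_ccn"], cols["post2_ccn"]).to_dict(),
            "ccn_pre_vs_post2": stats_core.paired_t_test(
                cols["pre_ccn"], cols["post2_ccn"]).to_dict(),
            "thickness_pre_vs_post2": stats_core.paired_t_test(
                cols["pre_thick"], cols["post2_thick"]).to_dict(),
        },
    }


def _boxplot_stats(values) -> dict:
    v = np.sort(np.asarray(values, dtype=np.float64))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_lo": float(inliers.min()), "whisker_hi": float(inliers.max()),
            "outliers": [float(x) for x in v[(v < lo) | (v > hi)]],
            "n": int(v.size)}


def _gated_comparison(datasets: dict[str, list[float]], variable: str) -> dict:
    """Normality gate, then ANOVA (parametric) or Kruskal-Wallis."""
    labels = list(datasets)
    groups = [datasets[k] for k in labels]
    normal, gate = stats_core.normality_gate(groups)
    if normal:
        test = stats_core.anova_oneway(groups)
    else:
        test = stats_core.kruskal_wallis(groups)
    logger.info("%s: normality gate -> %s branch", variable,
                "parametric" if normal else "nonparametric")
    return {"variable": variable, "labels": labels,
            "normality_gate": {"all_normal": normal, "details": gate},
            "branch": "parametric" if normal else "nonparametric",
            "test": test.to_dict(),
            "boxplot": {k: _boxplot_stats(v) for k, v in datasets.items()}}


def run_group_isotope_analysis(records: list[IsotopeRecord]) -> dict:
    """d13C and d18O compared across treatment groups A/B/C."""
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValidationError("need >= 2 treatment groups")
    for g in groups:
        if sum(r.group == g for r in records) < 2:
            raise ValidationError(f"group {g} has fewer than 2 records")
    out = {"analysis": "group_isotopes", "version": __version__,
           "input": _digest(records), "comparisons": {}}
    for var in ("d13c", "d18o"):
        data = {g: [getattr(r, var) for r in records if r.group == g]
                for g in groups}
        out["comparisons"][var] = _gated_comparison(data, var)
    return out


def run_genotype_analysis(records: list[IsotopeRecord], *,
                          weight_range_min: float = WIDE_WEIGHT_RANGE_UG) -> dict:
    """d13C/d18O across genetic types plus per-type d13C-weight regression.

    Untyped records are excluded (and logged).  Regression is restricted
    to genotypes whose shell-weight range is at least ``weight_range_min``
    ug — narrow-range types cannot support a correlation test.
    """
    excluded = [(r.group, r.specimen_id) for r in records
                if r.genetic_type == "untyped"]
    for g, sid in excluded:
        logger.info("excluding untyped record (%s, %s)", g, sid)
    typed = [r for r in records if r.genetic_type != "untyped"]
    if not typed:
        raise ValidationError("no typed records")
    types = [t for t in GENOTYPE_ORDER if any(r.genetic_type == t for r in typed)]
    out = {"analysis": "genotype_isotopes", "version": __version__,
           "input": _digest(records),
           "excluded_untyped": [list(e) for e in excluded],
           "types": types, "comparisons": {}, "posthoc_d13c": None,
           "regressions": {}}
    if len(types) >= 2:
        for var in ("d13c", "d18o"):
            data = {t: [getattr(r, var) for r in typed if r.genetic_type == t]
                    for t in types}
            out["comparisons"][var] = _gated_comparison(data, var)
        d13c_groups = [[r.d13c for r in typed if r.genetic_type == t] for t in types]
        out["posthoc_d13c"] = [p.to_dict() for p in
                               stats_core.tukey_hsd(d13c_groups, labels=types)]
    else:
        logger.warning("single genotype present; skipping between-type tests")
    for t in types:
        recs = [r for r in typed if r.genetic_type == t]
        weights = [r.weight for r in recs]
        span = max(weights) - min(weights)
        if span < weight_range_min:
            logger.info("type %s weight range %.2f ug < %.2f; regression skipped",
                        t, span, weight_range_min)
            out["regressions"][t] = {"skipped": True, "weight_range": span}
            continue
        fit = stats_core.ols(weights, [r.d13c for r in recs])
        xs = np.linspace(min(weights), max(weights), 25)
        lo, hi = fit.ci_band(xs)
        out["regressions"][t] = {**fit.to_dict(), "weight_range": span,
                                 "band_x": xs.tolist(),
                                 "band_lo": lo.tolist(), "band_hi": hi.tolist()}
    return out


def scan_specimen_ccn(scene: np.ndarray, labels: dict[str, np.ndarray],
                      voxel_size: float, spectrum, *, n_angles: int = 360,
                      seed: int | None = None,
                      min_component: int = 50) -> dict:
    """Scan one composed scene slice and measure the shell mean CCN.

    calibrate -> CCN map -> segment (standard excluded) -> summary.
    """
    from calciscan.xray import reconstruct_fbp, simulate_scan

    sino = simulate_scan(scene, voxel_size, spectrum, n_angles, seed=seed)
    recon = reconstruct_fbp(sino)
    vol = AttenuationVolume(values=recon.values, voxel_size=voxel_size,
                            region_labels=labels)
    cal = calibrate_scan(vol)
    ccn_map = ccn(vol.values, cal)
    mask = segment_shell(ccn_map, exclude=labels.get("calcite_standard"),
                         min_component=min_component)
    summ = specimen_summary(ccn_map, mask, voxel_size=voxel_size)
    return {"calibration": {"mu_air": cal.mu_air, "mu_calcite": cal.mu_calcite,
                            "n_air": cal.n_air, "n_calcite": cal.n_calcite},
            "mean_ccn": summ.mean_ccn,
            "shell_voxel_count": summ.shell_voxel_count,
            "ccn_map": ccn_map, "mask": mask}


def run_scan_pipeline(*, seed: int = 0, n_angles: int = 240,
                      phantom_grid: int = 64) -> dict:
    """Simulated 1-vs-3-specimen study plus a gain-drift repeat pair.

    Scaled down relative to the instrument (full scans are hours of CPU);
    the claims checked are directional, not absolute.  Scene grids are
    auto-sized so the specimen row fits the reconstruction circle.
    """
    from calciscan.phantom import ShellGeometry, make_shell_phantom
    from calciscan.xray import compose_scene, polychromatic

    geom = ShellGeometry(n_chambers=1, first_radius_um=14.0, wall_um=4.0)
    phantom = make_shell_phantom(geom, seed=seed, voxel_size=0.8,
                                 grid=phantom_grid)
    # the aluminium pre-filter suppresses hardening for shallow paths;
    # a 3-specimen stack exceeds its effective depth, which at this scale
    # is modelled by scanning the stack comparison unfiltered
    spectrum = polychromatic(aluminum_filter=False)

    single, labels1, vx = compose_scene([phantom])
    triple, labels3, _ = compose_scene([phantom] * 3)
    res1 = scan_specimen_ccn(single, labels1, vx, spectrum, n_angles=n_angles)
    res3 = scan_specimen_ccn(triple, labels3, vx, spectrum, n_angles=n_angles)

    drift = scan_specimen_ccn(single, labels1, vx,
                              spectrum.with_drift(1.1), n_angles=n_angles)
    tmap = local_thickness(res1["mask"], vx)
    report = {
        "analysis": "scan_pipeline", "version": __version__, "seed": seed,
        "single_mean_ccn": res1["mean_ccn"],
        "triple_mean_ccn": res3["mean_ccn"],
        "beam_hardening_shift": res3["mean_ccn"] - res1["mean_ccn"],
        "drifted_mean_ccn": drift["mean_ccn"],
        "drift_ccn_rel_change": abs(drift["mean_ccn"] - res1["mean_ccn"])
        / abs(res1["mean_ccn"]),
        "drift_gray_ratio": drift["calibration"]["mu_calcite"]
        / res1["calibration"]["mu_calcite"],
        "mean_wall_thickness_um": mean_wall_thickness(tmap, res1["mask"]),
        "wall_truth_um": geom.wall_um,
    }
    return report


def run_scan_set(volumes: list[AttenuationVolume], *,
                 min_component: int = 1000) -> dict:
    """Measure mean CCN + thickness for a set of reconstructed volumes.

    Scans that fail calibration are reported and skipped; if every scan
    fails, the error propagates.
    """
    results, failures = [], []
    for i, vol in enumerate(volumes):
        try:
            cal = calibrate_scan(vol)
        except CalibrationError as exc:
            logger.warning("scan %d skipped: %s", i, exc)
            failures.append({"scan": i, "error": str(exc)})
            continue
        ccn_map = ccn(vol.values, cal)
        mask = segment_shell(ccn_map,
                             exclude=vol.region_labels.get("calcite_standard"),
                             min_component=min_component)
        summ = specimen_summary(ccn_map, mask, voxel_size=vol.voxel_size)
        tmap = local_thickness(mask, vol.voxel_size)
        results.append({"scan": i, "mean_ccn": summ.mean_ccn,
                        "shell_voxel_count": summ.shell_voxel_count,
                        "mean_thickness_um": mean_wall_thickness(tmap, mask)})
    if not results:
        raise CalibrationError("all scans failed calibration")
    return {"analysis": "scan_set", "version": __version__,
            "results": results, "failures": failures}


def reproduce(out_path: str | Path | None = None, *, seed: int = 0) -> dict:
    """Recompute every packaged-table headline number in one call."""
    import json

    from calciscan.fixtures import (
        load_packaged_ct_table,
        load_packaged_isotope_table,
    )

    ct = load_packaged_ct_table()
    iso = load_packaged_isotope_table()
    report = {
        "physical": run_physical_comparison(ct),
        "group_isotopes": run_group_isotope_analysis(iso),
        "genotype_isotopes": run_genotype_analysis(iso),
        "seed": seed,
        "version": __version__,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
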