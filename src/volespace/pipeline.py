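"""End-to-end synthetic study: generator -> telemetry -> behavior ->
space use -> habitat -> linkage battery.

``run_world`` builds a multi-site study with known ground truth (latent
behavioral types and movement parameters per vole), runs every analysis
stage on the generated raw records, and returns all intermediate tables
plus the final mixed-model battery.  The defaults mirror the field
design: five sites with 55-trap grids, ~13 voles tested per site
(~65 total), seven voles radio-tracked on each of the three
highest-density sites (21 tracked) for 4 days at a 20-min cadence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, habitat, space_use, telemetry
from .inference import run_battery
from .simulate import (
    EffectConfig,
    SignalNoiseModel,
    SiteConfig,
    calibration_scans,
    make_site,
    simulate_behavior_tests,
    simulate_captures,
    simulate_movement,
    simulate_signals,
    simulate_voles,
)

SIGN_ANCHORS = {
    "exploration": list(behavior.EXPLORATION_ANCHORS),
    "boldness": list(behavior.BOLDNESS_ANCHORS),
}

ASSAY_VARIABLES = (
    "latency_trap_s",
    "latency_head_s",
    "latency_body_s",
    "latency_middle_s",
    "sections_entered",
    "middle_crossings",
    "jumps",
    "activity_prop",
)

EXCLUDE_FROM_PCA = ("latency_trap_s",)  # the discarded emergence variable


@dataclass
class WorldConfig:
    n_sites: int = 5
    n_tracked_sites: int = 3
    voles_per_site: int = 13
    tracked_per_site: int = 7
    site: SiteConfig = field(default_factory=SiteConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: SignalNoiseModel = field(default_factory=SignalNoiseModel)
    icc_bold: float = 0.453
    icc_expl: float = 0.217
    rounds: int = 3
    tracking_days: float = 4.0
    cadence_min: float = 20.0
    p_capture: float = 0.55
    trap_nights: int = 8
    ud_resolution_m: float = 1.0
    repeatability_alpha: float = 0.05


@dataclass
class BehaviorScoring:
    scores: pd.DataFrame              # individual_id x {exploration, boldness}
    repeatability: pd.DataFrame       # per-variable R and p
    kept_variables: list
    suitability: dict
    pca: "behavior.PCAResult"


def behavioral_scores(
    tests: pd.DataFrame,
    alpha: float = 0.05,
    exclude: tuple = EXCLUDE_FROM_PCA,
    latency_mode: str = "negate",
) -> BehaviorScoring:
    """Score the assay table into per-individual behavioral types.

    Steps: per-variable repeatability screen (variables whose
    between-individual variance is not detectably nonzero are dropped, as
    is the trap-emergence latency), latency inversion, PCA suitability
    diagnostics, oblimin PCA with eigenvalue > 1 retention, and
    mixed-model conditional modes per individual and component.
    """
    rep_rows = []
    for var in ASSAY_VARIABLES:
        r = behavior.repeatability(tests[var], tests["individual_id"], n_boot=0)
        rep_rows.append({"variable": var, "R": r.R, "p": r.p})
    rep = pd.DataFrame(rep_rows)

    kept = [
        v
        for v in ASSAY_VARIABLES
        if v not in exclude
        and float(rep.loc[rep["variable"] == v, "p"].iloc[0]) < alpha
    ]
    if len(kept) < 2:
        raise ValueError("fewer than 2 repeatable variables; cannot run PCA")

    inv = behavior.invert_latencies(tests, mode=latency_mode)
    suit = behavior.pca_suitability(inv[kept])
    pca = behavior.pca_oblimin(inv[kept], sign_anchors=SIGN_ANCHORS)
    scores = behavior.blup_scores(pca.scores, inv["test_day"], inv["individual_id"])
    return BehaviorScoring(
        scores=scores,
        repeatability=rep,
        kept_variables=kept,
        suitability=suit,
        pca=pca,
    )


@dataclass
class WorldResult:
    config: WorldConfig
    seed: int
    sites: list
    voles: list
    tests: pd.DataFrame
    scoring: BehaviorScoring
    captures: pd.DataFrame
    fixes: pd.DataFrame
    metrics: pd.DataFrame
    battery: pd.DataFrame


def _track_site(site, tracked, config: WorldConfig, seed: int):
    """Telemetry chain for one site: signals -> calibration -> fixes."""
    known, cal_scans = calibration_scans(site, config.noise, seed=seed)
    calibration = telemetry.fit_calibration(known, cal_scans, site.antenna_geometry)
    fixes = []
    for vole in tracked:
        traj = simulate_movement(
            vole, days=config.tracking_days, cadence_min=config.cadence_min, seed=seed
        )
        scans = simulate_signals(traj, site, config.noise, seed=seed)
        fx = telemetry.localize_scans(scans, calibration, site.antenna_geometry)
        fx = telemetry.filter_outliers(fx)
        fixes.append(fx)
    return calibration, pd.concat(fixes, ignore_index=True)


def run_world(config: WorldConfig | None = None, seed: int = 0) -> WorldResult:
    """Generate one synthetic study and run the full analysis chain."""
    config = config or WorldConfig()
    sites, all_voles = [], []
    for k in range(config.n_sites):
        site = make_site(config.site, seed=seed, site_id=f"S{k + 1}")
        sites.append(site)
        all_voles.append(
            simulate_voles(site, config.voles_per_site, config.effects, seed=seed)
        )

    tests = simulate_behavior_tests(
        [v for vs in all_voles for v in vs],
        icc_bold=config.icc_bold,
        icc_expl=config.icc_expl,
        rounds=config.rounds,
        seed=seed,
    )
    scoring = behavioral_scores(tests, alpha=config.repeatability_alpha)

    metric_rows, fix_tables = [], []
    for k in range(config.n_tracked_sites):
        site, voles = sites[k], all_voles[k]
        captures = simulate_captures(
            voles, site, p_capture=config.p_capture, nights=config.trap_nights, seed=seed
        )
        mtp = space_use.mean_trapping_point(captures)

        counts = captures.groupby("individual_id").size()
        order = sorted(
            voles, key=lambda v: (-counts.get(v.individual_id, 0), v.individual_id)
        )
        tracked = order[: config.tracked_per_site]

        _, fixes = _track_site(site, tracked, config, seed)
        fix_tables.append(fixes)
        retained = fixes[fixes["qc_flag"] == "ok"]

        rasters = habitat.raster_for_site(site, resolution=config.ud_resolution_m)

        ranges = {}
        for vole in tracked:
            xy = retained.loc[
                retained["individual_id"] == vole.individual_id, ["x", "y"]
            ].to_numpy(float)
            ud = space_use.kde_ud(
                xy, resolution=config.ud_resolution_m, individual_id=vole.individual_id
            )
            ranges[vole.individual_id] = {
                "xy": xy,
                95: space_use.isopleth(ud, space_use.HOME_RANGE_LEVEL),
                50: space_use.isopleth(ud, space_use.CORE_AREA_LEVEL),
            }

        for vole in tracked:
            vid = vole.individual_id
            own = ranges[vid]
            others95 = [ranges[o][95] for o in ranges if o != vid]
            others50 = [ranges[o][50] for o in ranges if o != vid]
            pts = mtp.drop(index=vid, errors="ignore")[["x", "y"]].to_numpy(float)
            row = {
                "individual_id": vid,
                "site": site.site_id,
                "sex": vole.sex,
                "boldness_true": vole.boldness_true,
                "exploration_true": vole.exploration_true,
                "range_scale_true_m": vole.range_scale_m,
                "n_fixes": len(own["xy"]),
                "home_range_area_m2": own[95].area_m2,
                "core_area_m2": own[50].area_m2,
                "total_distance_m": space_use.total_distance(own["xy"]),
                "overlap_95": space_use.overlap_fraction(own[95], others95),
                "overlap_50": space_use.overlap_fraction(own[50], others50),
                "n_trap_centers_95": space_use.count_points_in_range(pts, own[95]),
                "n_trap_centers_50": space_use.count_points_in_range(pts, own[50]),
            }
            for layer, label in (
                ("max_height_cm", "veg_height"),
                ("ground_cover_pct", "ground_cover"),
            ):
                vals = habitat.extract_at_fixes(rasters[layer], own["xy"])
                means = habitat.range_means(
                    vals, own["xy"], {95: own[95], 50: own[50]}
                )
                row[f"{label}_95"] = means[95]
                row[f"{label}_50"] = means[50]
            metric_rows.append(row)

    captures_all = pd.concat(
        [
            simulate_captures(
                all_voles[k],
                sites[k],
                p_capture=config.p_capture,
                nights=config.trap_nights,
                seed=seed,
            )
            for k in range(config.n_sites)
        ],
        ignore_index=True,
    )

    metrics = pd.DataFrame(metric_rows).merge(
        scoring.scores.reset_index(), on="individual_id", how="left"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        battery = run_battery(metrics)

    return WorldResult(
        config=config,
        seed=seed,
        sites=sites,
        voles=[v for vs in all_voles for v in vs],
        tests=tests,
        scoring=scoring,
        captures=captures_all,
        fixes=pd.concat(fix_tables, ignore_index=True),
        metrics=metrics,
        battery=battery,
    )
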