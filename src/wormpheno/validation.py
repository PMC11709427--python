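"""End-to-end calibration experiments on synthetic data with known truth.

Each function generates data with the study's replicate structure (three
independent tracking days; three wells per group per day at screen scale,
24 wells per day at confirmation scale), runs the corresponding pipeline
stage, and measures how well the known planted structure is recovered:
type-I error of the day-blocked permutation test under day batch effects,
Monte-Carlo vs exhaustive p-value agreement, planted-effect recovery, the
screen funnel (hit precision/recall, side-effect counts), and cluster /
phenospace geometry.  These are the quantitative checks behind both the
acceptance suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import fingerprint as fpm
from . import screen as scr
from .features import WindowSpec, skeleton_curvature, window_frames
from .stats import (StatsConfig, benjamini_yekutieli, block_permutation_ttest,
                    compare_groups)
from .synthetic_data import (EffectSpec, ExperimentDesign, feature_names,
                             generate_feature_experiment,
                             generate_screen_experiment,
                             make_screen_compound_specs)

__all__ = [
    "null_type_one_error", "mc_vs_exhaustive_agreement", "by_oracle_max_diff",
    "planted_effect_recovery", "screen_funnel", "side_effect_calibration",
    "two_cluster_recovery", "phenospace_axis_alignment", "geometry_checks",
]


def null_type_one_error(n_features: int = 10_000, seed: int = 0,
                        day_sd_factor: float = 2.0) -> dict:
    """Per-feature rejection rate at alpha=0.05 on null data with day effects.

    Day-level batch shifts have SD ``day_sd_factor`` times the well noise SD;
    no group differences are planted, so rejections are pure type-I errors.
    Also reports the BY rejection count at q=0.05 over all features.
    """
    design = ExperimentDesign(n_features_per_period=n_features,
                              periods=("prestim",), seed=seed)
    tables, meta, _ = generate_feature_experiment(
        design, EffectSpec(day_sd=day_sd_factor, noise_sd=1.0))
    res = compare_groups(tables["prestim"], meta, "mut_DMSO", "N2_DMSO",
                         StatsConfig(rng_seed=seed))
    p = res.table["p"].to_numpy()
    return {
        "rejection_rate_alpha05": float((p < 0.05).mean()),
        "n_by_rejections": res.n_significant,
        "n_features": int(len(p)),
        "exhaustive": res.exhaustive,
    }


def mc_vs_exhaustive_agreement(n_instances: int = 50, n_perm: int = 2000,
                               seed: int = 0) -> dict:
    """Monte-Carlo vs exhaustive p on 2 days x (2+2) wells (36 arrangements).

    Returns the fraction of random instances whose Monte-Carlo p falls
    within three binomial standard errors of the exact p, and the largest
    deviation in SE units.
    """
    rng = np.random.default_rng(seed)
    days = np.array([1, 1, 2, 2])
    within = 0
    worst = 0.0
    for i in range(n_instances):
        x = rng.normal(rng.uniform(0, 2), 1.0, 4)
        y = rng.normal(0.0, 1.0, 4)
        _, p_ex = block_permutation_ttest(
            x, y, days, days, StatsConfig(exhaustive_threshold=100))
        _, p_mc = block_permutation_ttest(
            x, y, days, days,
            StatsConfig(n_permutations=n_perm, exhaustive_threshold=1,
                        rng_seed=seed * 1000 + i))
        se = math.sqrt(max(p_ex * (1 - p_ex), 1e-12) / n_perm)
        dev = abs(p_mc - p_ex) / se if se > 0 else 0.0
        worst = max(worst, dev)
        # +1-corrected estimator adds at most ~1/(R+1) of bias
        within += abs(p_mc - p_ex) <= 3 * se + 1.5 / n_perm
    return {"fraction_within_3se": within / n_instances,
            "max_abs_deviation_se_units": worst,
            "n_instances": n_instances}


def by_oracle_max_diff(max_m: int = 1000, seed: int = 0) -> dict:
    """Max |adjusted - independent step-up formula| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for m in (1, 4, 37, 200, max_m):
        p = rng.uniform(size=m) ** 2
        adj, _ = benjamini_yekutieli(p)
        c = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        raw = p[order] * c * m / np.arange(1, m + 1)
        oracle = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
        back = np.empty(m)
        back[order] = oracle
        worst = max(worst, float(np.max(np.abs(adj - back))))
    return {"max_abs_diff": worst, "max_m": max_m}


def planted_effect_recovery(n_seeds: int = 20, n_features: int = 1000,
                            n_planted: int = 100, d: float = 3.0,
                            seed: int = 0) -> dict:
    """Recovery of planted effects (d=3 on 100 of 1000 features, 9 wells/group).

    Returns the median sensitivity (planted features recovered after BY) and
    median count of false positives over independent replicate experiments.
    """
    sens, fps = [], []
    planted = {f"ft{j:04d}": d for j in range(n_planted)}
    for s in range(n_seeds):
        design = ExperimentDesign(n_features_per_period=n_features,
                                  periods=("prestim",), seed=seed * 1000 + s)
        tables, meta, _ = generate_feature_experiment(
            design, {"mut_DMSO": EffectSpec(effect_sizes=planted)})
        res = compare_groups(tables["prestim"], meta, "mut_DMSO", "N2_DMSO",
                             StatsConfig(rng_seed=s))
        sig = set(res.significant_features)
        truth = set(planted)
        tp = len(sig & truth)
        sens.append(tp / n_planted)
        fps.append(len(sig - truth))
    return {"median_sensitivity": float(np.median(sens)),
            "median_false_positives": float(np.median(fps)),
            "n_seeds": n_seeds}


def _one_screen(seed: int, n_compounds: int, n_full: int, n_partial: int,
                n_features: int, d: float) -> tuple[scr.ScreenResult, dict]:
    design = ExperimentDesign(groups=("N2_DMSO", "mut_DMSO"),
                              n_features_per_period=n_features, seed=seed)
    names = feature_names(n_features, core_first=True)
    disease = EffectSpec(effect_sizes={"curvature_mean": -d, "speed_mean": -d,
                                       "fraction_paused": d})
    specs = make_screen_compound_specs(n_compounds, n_full=n_full,
                                       n_partial=n_partial, n_toxic=0,
                                       seed=seed)
    tables, meta, truth = generate_screen_experiment(design, disease, specs,
                                                     names=names)
    cfg = scr.ScreenConfig(stats=StatsConfig(rng_seed=seed))
    return scr.call_hits(tables, meta, cfg), truth.compound_categories


def screen_funnel(n_seeds: int = 10, n_compounds: int = 50, n_full: int = 3,
                  n_partial: int = 5, d: float = 3.0, seed: int = 0) -> dict:
    """Hit precision/recall for planted full rescuers at screen scale.

    Full rescuers are the positive class; a hit called on any other planted
    category (partial or inert) counts against precision.  Median over
    independent screens.
    """
    precisions, recalls = [], []
    for s in range(n_seeds):
        res, cats = _one_screen(seed * 100 + s, n_compounds, n_full,
                                n_partial, n_features=20, d=d)
        hits = {h.split("_", 1)[1] for h in res.hits}
        full = {c for c, cat in cats.items() if cat == "full"}
        tp = len(hits & full)
        precisions.append(tp / len(hits) if hits else 1.0)
        recalls.append(tp / len(full))
    return {"median_precision": float(np.median(precisions)),
            "median_recall": float(np.median(recalls)),
            "n_seeds": n_seeds}


def side_effect_calibration(n_features: int = 400, n_disease: int = 100,
                            n_side_effects: int = 200, d: float = 3.0,
                            n_inert: int = 3, wells_per_day: int = 24,
                            seed: int = 0) -> dict:
    """Side-effect counting at confirmation scale (24 wells/day x 3 days).

    One toxic compound (full core rescue plus ``n_side_effects`` planted
    off-target period-features at d=3) and ``n_inert`` inert compounds are
    screened; reports the toxic compound's recovered count and the worst
    inert leakage as a fraction of non-disease features.
    """
    design = ExperimentDesign(groups=("N2_DMSO", "mut_DMSO"),
                              wells_per_group_per_day=wells_per_day,
                              n_features_per_period=n_features, seed=seed)
    names = feature_names(n_features, core_first=True)
    disease_sizes = {"curvature_mean": -d, "speed_mean": -d,
                     "fraction_paused": d}
    disease_sizes.update({f"ft{j:04d}": d for j in range(3, 3 + n_disease)})
    pool = [f"{n}@{p}" for n in names[3 + n_disease:] for p in design.periods]
    specs = make_screen_compound_specs(
        1 + n_inert, n_full=0, n_partial=0, n_toxic=1,
        n_side_effect_features=n_side_effects, available_features=pool,
        seed=seed)
    tables, meta, truth = generate_screen_experiment(
        design, EffectSpec(effect_sizes=disease_sizes), specs, names=names)
    cfg = scr.ScreenConfig(stats=StatsConfig(rng_seed=seed))
    toxic = [c for c, cat in truth.compound_categories.items()
             if cat == "toxic"][0]
    inerts = [c for c, cat in truth.compound_categories.items()
              if cat == "inert"]
    compounds = [f"mut_{c}" for c in [toxic] + inerts]
    report = scr.count_side_effects(tables, meta, compounds, cfg)
    se = report.table
    n_non_disease = 3 * n_features - len(report.disease_features)
    leak = [se.loc[f"mut_{c}", "side_effect_count"] / n_non_disease
            for c in inerts]
    planted_set = set(truth.side_effects[toxic])
    found = set(report.features[f"mut_{toxic}"])
    return {
        "toxic_planted": n_side_effects,
        "toxic_recovered_planted": len(found & planted_set),
        "toxic_total_count": int(se.loc[f"mut_{toxic}", "side_effect_count"]),
        "toxic_false_extra": len(found - planted_set),
        "max_inert_leakage_fraction": float(max(leak)),
        "n_disease_features_detected": len(report.disease_features),
    }


def two_cluster_recovery(n_strains: int = 8, d: float = 3.0,
                         seed: int = 0) -> dict:
    """Adjusted Rand index of a k=2 tree cut against a planted partition."""
    groups = tuple(f"s{i}" for i in range(n_strains))
    half = n_strains // 2
    design = ExperimentDesign(groups=groups, n_features_per_period=40,
                              seed=seed)
    effects = {g: EffectSpec(effect_sizes={f"ft{j:04d}": d
                                           for j in range(10)})
               for g in groups[:half]}
    tables, meta, _ = generate_feature_experiment(design, effects)
    z = fpm.z_normalise(fpm.build_fingerprint(tables, meta, level="strain"))
    res = fpm.hierarchical_cluster(z)
    cut = res.cut(2)
    planted = [1 if g in groups[:half] else 0 for g in res.labels]
    found = [cut[g] for g in res.labels]
    return {"adjusted_rand_index": float(adjusted_rand_score(planted, found))}


def phenospace_axis_alignment(seed: int = 0) -> dict:
    """Common-axis alignment of blue-light trajectories for shifted strains.

    Plants period-restricted blue-light shifts of increasing magnitude on
    half the strains and measures (a) the minimum pairwise |cosine| between
    their prestim-to-bluelight displacement directions and (b) the
    correlation between displacement along the shared axis and planted size.
    """
    groups = tuple(f"s{i}" for i in range(6))
    design = ExperimentDesign(groups=groups, n_features_per_period=30,
                              seed=seed)
    shifted = groups[:3]
    sizes = {}
    effects = {}
    for i, g in enumerate(shifted):
        dd = 3.0 + 2.0 * i
        sizes[g] = dd
        effects[g] = EffectSpec(effect_sizes={f"ft{j:04d}@bluelight": dd
                                              for j in range(20)},
                                day_sd=0.05)
    tables, meta, _ = generate_feature_experiment(design, effects)
    proj = fpm.pca_phenospace(tables, meta, n_components=2)
    disp = {}
    for g in groups:
        tr = proj.trajectory(g)
        disp[g] = tr.loc["bluelight", ["pc1", "pc2"]].to_numpy(float) - \
            tr.loc["prestim", ["pc1", "pc2"]].to_numpy(float)
    units = [disp[g] / np.linalg.norm(disp[g]) for g in shifted]
    min_cos = min(abs(float(units[0] @ u)) for u in units[1:])
    axis = np.mean(units, axis=0)
    axis /= np.linalg.norm(axis)
    proj_shift = [abs(float(disp[g] @ axis)) for g in shifted]
    r = float(np.corrcoef(proj_shift, [sizes[g] for g in shifted])[0, 1])
    return {"min_pairwise_abs_cosine": min_cos,
            "displacement_effect_correlation": r}


def geometry_checks() -> dict:
    """Closed-form feature-analytics checks (curvature, windows)."""
    r = 500.0
    th = np.linspace(0, np.pi / 2, 49)
    pts = r * np.stack([np.cos(th), np.sin(th)], axis=1)
    _, mean_abs = skeleton_curvature(pts)
    frames = window_frames(60.0, WindowSpec(), frame_rate=25.0)
    return {
        "circle_curvature_rel_error_pct": float(
            abs(mean_abs * r - 1.0) * 100.0),
        "window_frames_pulse60": frames,
    }
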