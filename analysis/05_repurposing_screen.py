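#!/usr/bin/env python
"""Run the full synthetic drug-repurposing funnel: screen, confirm, side effects.

Stage 1 simulates a 50-compound screen against a disease model with a strong
core-triplet phenotype (blue-light curvature and speed down, pausing up;
d=3) at screen replication (3 days x 3 wells) and calls hits: compounds
significantly different from disease-vehicle controls on all three core
features with every effect directed toward wild-type.  Stage 2 re-tests the
hits at confirmation replication (3 days x 24 wells) and counts side
effects — features that do not separate untreated mutants from wild-type
but do separate drug-treated mutants from wild-type — flagging compounds
above the 1000-feature threshold (scaled here to the synthetic manifest).

Usage: python analysis/05_repurposing_screen.py [--seed 0] [--out results/screen]
"""

import argparse
from pathlib import Path

import pandas as pd

from wormpheno import io as wio
from wormpheno import screen as scr
from wormpheno.stats import StatsConfig
from wormpheno.synthetic_data import (EffectSpec, ExperimentDesign,
                                      feature_names,
                                      generate_screen_experiment,
                                      make_screen_compound_specs)

N_FEATURES = 100
D_GAP = 3.0


def simulate(seed: int, wells_per_day: int, specs, names):
    design = ExperimentDesign(groups=("N2_DMSO", "mut_DMSO"),
                              wells_per_group_per_day=wells_per_day,
                              n_features_per_period=N_FEATURES, seed=seed)
    disease = EffectSpec(effect_sizes={
        "curvature_mean": -D_GAP, "speed_mean": -D_GAP,
        "fraction_paused": D_GAP,
        **{f"ft{j:04d}": 2.0 for j in range(3, 23)}})
    return generate_screen_experiment(design, disease, specs, names=names)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/screen"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    names = feature_names(N_FEATURES, core_first=True)
    pool = [f"{n}@{p}" for n in names[30:]
            for p in ("prestim", "bluelight", "poststim")]
    specs = make_screen_compound_specs(
        50, n_full=3, n_partial=5, n_toxic=1, n_side_effect_features=60,
        available_features=pool, seed=args.seed)

    # stage 1: screen scale
    tables, meta, truth = simulate(args.seed, 3, specs, names)
    cfg = scr.ScreenConfig(side_effect_threshold=50,
                           stats=StatsConfig(rng_seed=args.seed))
    initial = scr.call_hits(tables, meta, cfg)
    coords = scr.phenospace_coords(tables, meta, cfg)
    initial.table.to_csv(args.out / "screen_hits.csv")
    coords.to_csv(args.out / "phenospace_coords.csv")

    cats = {f"mut_{c}": cat for c, cat in truth.compound_categories.items()}
    hit_cats = [cats[h] for h in initial.hits]
    print(f"initial screen: {len(initial.hits)} hits of "
          f"{len(initial.table)} compounds")
    print("  hit categories:", {c: hit_cats.count(c)
                                for c in sorted(set(hit_cats))})

    # stage 2: confirmation scale with side-effect counting
    conf_tables, conf_meta, _ = simulate(args.seed + 1, 24, specs, names)
    conf = scr.confirmation_screen(initial, conf_tables, conf_meta, cfg)
    conf.to_csv(args.out / "confirmation.csv")
    n_conf = int(conf["confirmed"].sum())
    flagged = conf.index[conf["above_threshold"]]
    print(f"confirmation: {n_conf} of {len(conf)} hits reproduced")
    print("side-effect counts:")
    print(conf[["confirmed", "side_effect_count", "above_threshold"]]
          .to_string())
    if len(flagged):
        print("flagged above side-effect threshold:",
              ", ".join(f"{c} ({cats[c]})" for c in flagged))
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
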