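#!/usr/bin/env python
"""Simulate a disease-model strain panel with known planted phenotypes.

Generates an eight-strain panel (wild-type reference plus seven mutants) at
the standard replicate scale — three independent tracking days with three
wells per strain per day — over three recording periods.  Five mutants carry
planted effects of varying breadth and size (including one blue-light-only
responder and one "fainter-like" strain shifted on the core triplet); two
are phenotypically silent.  Tables, metadata and the ground-truth record are
written for the downstream stages.

Usage: python analysis/01_simulate_panel.py [--seed 0] [--out results/panel]
"""

import argparse
from pathlib import Path

from wormpheno import io as wio
from wormpheno.features import feature_manifest
from wormpheno.synthetic_data import (EffectSpec, ExperimentDesign,
                                      feature_names,
                                      generate_feature_experiment)

N_FEATURES = 64

STRAIN_EFFECTS = {
    # broad strong phenotype (morphology + posture + motion)
    "mutA": {f"ft{j:04d}": 3.0 for j in range(3, 19)},
    # narrow moderate phenotype
    "mutB": {f"ft{j:04d}": 2.0 for j in range(20, 26)},
    # related gene: same features as mutB, same direction (phenolog pair)
    "mutC": {f"ft{j:04d}": 2.2 for j in range(20, 26)},
    # blue-light-only responder
    "mutD": {f"ft{j:04d}@bluelight": 3.0 for j in range(30, 42)},
    # core-triplet phenotype (curvature/speed down, pausing up)
    "mutE": {"curvature_mean": -3.0, "speed_mean": -3.0,
             "fraction_paused": 3.0},
    # phenotypically silent strains
    "mutF": {},
    "mutG": {},
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/panel"))
    args = ap.parse_args()

    groups = ("N2",) + tuple(STRAIN_EFFECTS)
    design = ExperimentDesign(groups=groups, n_features_per_period=N_FEATURES,
                              seed=args.seed)
    names = feature_names(N_FEATURES, core_first=True)
    effects = {g: EffectSpec(effect_sizes=s)
               for g, s in STRAIN_EFFECTS.items() if s}
    tables, meta, truth = generate_feature_experiment(design, effects,
                                                      names=names)
    manifest = feature_manifest(names)
    wio.write_experiment(args.out, tables, meta, truth, manifest)

    n_planted = {g: len(s) for g, s in STRAIN_EFFECTS.items()}
    print(f"panel: {len(groups)} strains x {design.n_days} days x "
          f"{design.wells_per_group_per_day} wells = {len(meta)} wells")
    print(f"features per period: {N_FEATURES} "
          f"(fingerprint length {3 * N_FEATURES})")
    for g, n in n_planted.items():
        print(f"  {g}: {n} planted feature effects")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
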