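# wormpheno

Analysis pipeline for high-throughput behavioural phenotyping of
*C. elegans* disease models and phenotypic drug-repurposing screens, built
around multi-well worm-tracking assays.

Tracking assays of this kind record each plate in three sequential periods —
a 5 min baseline (**prestim**), a 6 min recording with three 10 s blue-light
pulses starting at 60, 160 and 260 s (**bluelight**), and a 5 min recovery
(**poststim**) at 25 frames/s — and reduce each well to a vector of
behavioural features (morphology, posture, motion). `wormpheno` implements
the downstream analytics for such data, plus a synthetic-data generator with
known ground truth so every stage can be validated without tracking
hardware:

- **Feature extraction** (`wormpheno.features`): skeleton arc length and
  body width, tangent-angle curvature (rad/µm), centroid speed and signed
  motion modes (forward / paused / backward), skeleton QC gating
  (700–1300 µm length, 20–200 µm width, inclusive), stimulus-locked 10 s
  windows centred 5 s before and 10 s / 20 s after each pulse start, and
  track-to-well averaging.
- **Statistics** (`wormpheno.stats`): per-feature two-sample *t* tests
  (Welch by default) whose null distribution is built by **block
  permutation** — group labels are reshuffled within, but never between,
  independent tracking days, preserving day-level batch structure. When the
  number of distinct within-day arrangements is small the null is
  enumerated exhaustively and the p-value is exact; otherwise Monte-Carlo
  sampling with the +1-corrected estimator
  p = (1 + #{|t*| ≥ |t|}) / (R + 1) is used. Multiple comparisons are
  controlled with the **Benjamini–Yekutieli** step-up procedure
  (penalty c(m) = Σᵢ 1/i, valid under arbitrary dependence) at a 5% FDR.
- **Fingerprints & phenospace** (`wormpheno.fingerprint`): concatenation of
  the three period vectors into one behavioural fingerprint (2763 features
  per period → 8289 entries; the reduced 256-feature manifest → 768),
  feature-wise Z-normalisation, hierarchical clustering with Newick export,
  and a joint PCA placing each strain's three period means in one shared
  phenospace.
- **Screen inference** (`wormpheno.screen`): hit calling on a core triplet
  (blue-light curvature, speed, fraction paused) — a hit must differ from
  disease-vehicle controls on *all* core features with every effect
  directed toward the wild-type mean — plus confirmation re-testing and
  side-effect counting (features that separate drug-treated mutants, but
  not untreated mutants, from wild-type), with a >1000-feature flag.
- **Synthetic data** (`wormpheno.synthetic_data`): feature tables with
  additive day batch shifts, planted strain/drug effects on a Cohen's-d
  scale, screen layouts with planted compound categories (full / partial /
  inert / toxic rescuers), and 49-point skeleton tracks with an optional
  "fainter" phenotype (pausing after each light pulse ends).

## Worked example

The numbered scripts under `analysis/` run the full chain on synthetic
studies (3 tracking days × 3 wells per group per day; 24 wells per day at
confirmation scale). For the repurposing funnel:

```sh
python analysis/01_simulate_panel.py
python analysis/03_strain_significance.py
python analysis/04_fingerprint_phenospace.py
python analysis/05_repurposing_screen.py
```

`05_repurposing_screen.py` prints:

```
initial screen: 4 hits of 50 compounds
  hit categories: {'full': 3, 'toxic': 1}
confirmation: 4 of 4 hits reproduced
side-effect counts:
             confirmed  side_effect_count  above_threshold
compound
mut_drug001       True                  0            False
mut_drug002       True                  0            False
mut_drug003       True                  0            False
mut_drug009       True                 60             True
flagged above side-effect threshold: mut_drug009 (toxic)
```

All three planted full rescuers are called (the five partial rescuers sit
below the three-core-feature conjunction threshold, and none of the 42
inert compounds is called); the planted toxic compound also rescues the
core phenotype but is exposed by its side-effect count — exactly 60, its
planted number of off-target period-features — and flagged above the
scaled threshold. `03_strain_significance.py` shows the complementary
power story at panel scale: broad planted phenotypes yield large
significant-feature counts against the wild-type reference, while narrow
d=2 phenotypes can vanish under full-fingerprint BY correction — the
motivation for screening on a reduced core-feature set.

A command-line interface wraps the same stages
(`wormpheno simulate|extract|compare|fingerprint|screen ...`); every run
writes a `run_manifest.json` with the config echo and seed.

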