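"""Synthetic experiments with known ground truth.

Three generators mirror the structure of a multi-well worm-tracking study:

* :func:`generate_feature_experiment` — well-level feature tables for a set of
  strain/treatment groups replicated over independent tracking days, with
  additive day-level batch shifts, per-group planted effects and Gaussian
  well-to-well noise.
* :func:`generate_screen_experiment` — a drug-repurposing screen layout:
  wild-type and disease-model vehicle controls plus one group per compound,
  where compounds partially or fully close the mutant–wild-type gap on
  designated rescue features and may shift extra "side-effect" features.
* :func:`generate_skeleton_tracks` — skeleton time series (49-point midlines
  with width profiles at 25 frames/s) following a blue-light stimulus
  schedule, with an optional planted "fainter" phenotype (pausing after each
  light pulse ends).

Every generator is deterministic given its seed and returns a
:class:`GroundTruth` record of all planted structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import PERIODS

__all__ = [
    "ExperimentDesign",
    "EffectSpec",
    "GroundTruth",
    "StimulusSchedule",
    "WormParams",
    "Track",
    "TrackSet",
    "feature_names",
    "generate_feature_experiment",
    "generate_screen_experiment",
    "generate_skeleton_tracks",
    "make_screen_compound_specs",
    "SCREEN_CORE_FEATURES",
]

#: names of the reduced core phenotype used by the repurposing screen:
#: body curvature, centroid speed and fraction of paused worms (all taken
#: during blue-light stimulation downstream).
SCREEN_CORE_FEATURES = ("curvature_mean", "speed_mean", "fraction_paused")


# --------------------------------------------------------------------------- #
# designs and effect specifications
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate structure of a tracking experiment.

    The default mirrors the screening layout: three independent tracking days
    with three wells per group per day (nine well replicates per group).
    """

    n_days: int = 3
    wells_per_group_per_day: int = 3
    groups: tuple[str, ...] = ("N2_DMSO", "mut_DMSO")
    n_features_per_period: int = 10
    periods: tuple[str, ...] = PERIODS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.wells_per_group_per_day < 1:
            raise ValueError("n_days and wells_per_group_per_day must be positive")
        if self.n_features_per_period < 1:
            raise ValueError("n_features_per_period must be positive")
        if len(self.groups) < 1:
            raise ValueError("at least one group required")

    @property
    def n_wells(self) -> int:
        """Total wells = n_days x wells_per_group_per_day x |groups|."""
        return self.n_days * self.wells_per_group_per_day * len(self.groups)


@dataclass(frozen=True)
class EffectSpec:
    """Planted statistical structure for one group (or one compound).

    ``effect_sizes`` maps feature names to standardised shifts (Cohen's-d
    scale, in units of ``noise_sd``).  A name may carry an ``@period`` suffix
    (e.g. ``"ft003@bluelight"``) to restrict the shift to one recording
    period; bare names shift the feature in every period.  ``day_sd`` is the
    SD of the additive day-level batch shift shared by all wells of a day;
    ``noise_sd`` is the within-well residual SD.  ``rescue_fraction`` and
    ``side_effect_features`` are only used by the screen generator.
    """

    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    day_sd: float = 0.3
    noise_sd: float = 1.0
    rescue_fraction: float = 0.0
    side_effect_features: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.day_sd < 0 or self.noise_sd < 0:
            raise ValueError("day_sd and noise_sd must be non-negative")
        if not 0.0 <= self.rescue_fraction <= 1.5:
            # >1 models overshoot past wild-type; cap generously
            raise ValueError("rescue_fraction must lie in [0, 1.5]")

    @property
    def category(self) -> str:
        """Compound category implied by the planted parameters (screen generator)."""
        if self.side_effect_features:
            return "toxic"
        if self.rescue_fraction >= 1.0:
            return "full"
        if self.rescue_fraction > 0.0:
            return "partial"
        return "inert"


@dataclass
class GroundTruth:
    """Record of everything the generator planted.

    ``group_effects`` maps group -> {period-qualified feature -> signed shift
    in raw units}; ``compound_categories`` and ``side_effects`` are filled by
    the screen generator only.
    """

    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    compound_categories: dict[str, str] = field(default_factory=dict)
    side_effects: dict[str, list[str]] = field(default_factory=dict)
    noise_sd: float = 1.0
    day_sd: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def feature_names(n: int, core_first: bool = False) -> list[str]:
    """Default feature manifest of ``n`` names.

    With ``core_first`` the first three names are the screen core triplet
    (curvature, speed, fraction paused); the remainder are ``ftNNNN``.
    """
    names: list[str] = []
    if core_first:
        names.extend(SCREEN_CORE_FEATURES[: min(3, n)])
    names.extend(f"ft{i:04d}" for i in range(len(names), n))
    return names[:n]


def _split_feature_key(key: str, periods: Sequence[str]) -> tuple[str, str | None]:
    """Split ``"name@period"`` into (name, period); bare names -> (name, None)."""
    if "@" in key:
        name, period = key.rsplit("@", 1)
        if period not in periods:
            raise ValueError(f"unknown period {period!r} in effect key {key!r}")
        return name, period
    return key, None


def _validate_effects(effects: Mapping[str, EffectSpec], names: Sequence[str],
                      periods: Sequence[str]) -> None:
    known = set(names)
    for group, spec in effects.items():
        for key in list(spec.effect_sizes) + list(spec.side_effect_features):
            name, _ = _split_feature_key(key, periods)
            if name not in known:
                raise ValueError(
                    f"effect for group {group!r} names unknown feature {name!r}"
                )


# --------------------------------------------------------------------------- #
# feature-table generation
# --------------------------------------------------------------------------- #

def _make_metadata(design: ExperimentDesign,
                   drug_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for day in range(1, design.n_days + 1):
        for group in design.groups:
            for rep in range(1, design.wells_per_group_per_day + 1):
                rows.append({
                    "well_id": f"{group}_d{day}r{rep}",
                    "group": group,
                    "strain": group.split("_")[0],
                    "drug": (drug_of or {}).get(group, group.split("_")[-1]),
                    "dose_uM": 100.0,
                    "day": day,
                    "bad_well": False,
                })
    meta = pd.DataFrame(rows)
    return meta


def generate_feature_experiment(
    design: ExperimentDesign,
    effects: Mapping[str, EffectSpec] | EffectSpec | None = None,
    *,
    names: Sequence[str] | None = None,
    drug_of: Mapping[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate per-period feature tables plus metadata and ground truth.

    Each well value is ``group shift + day shift + noise``: day shifts are
    drawn once per (day, feature, period) and shared by every well of that
    day across all groups (the batch structure that motivates day-blocked
    permutation testing); noise is i.i.d. Gaussian.  ``effects`` maps group
    labels to :class:`EffectSpec`; groups without an entry are baseline.  A
    single :class:`EffectSpec` may be passed to set shared ``day_sd`` /
    ``noise_sd`` with no planted group differences.
    """
    if effects is None:
        effects = {}
    if isinstance(effects, EffectSpec):
        base = effects
        effects = {}
    else:
        specs = list(effects.values())
        base = specs[0] if specs else EffectSpec()
    for g in effects:
        if g not in design.groups:
            raise ValueError(f"effects reference unknown group {g!r}")
    names = list(names) if names is not None else feature_names(design.n_features_per_period)
    if len(names) != design.n_features_per_period:
        raise ValueError("names length must equal n_features_per_period")
    _validate_effects(effects, names, design.periods)

    day_sd, noise_sd = base.day_sd, base.noise_sd
    rng = np.random.default_rng(design.seed)
    meta = _make_metadata(design, drug_of)
    n_wells, n_feat = len(meta), len(names)
    name_idx = {n: i for i, n in enumerate(names)}

    # raw-unit shift per (group, period, feature)
    shift = {g: {p: np.zeros(n_feat) for p in design.periods} for g in design.groups}
    truth = GroundTruth(noise_sd=noise_sd, day_sd=day_sd)
    for group, spec in effects.items():
        truth.group_effects[group] = {}
        for key, d in spec.effect_sizes.items():
            name, period = _split_feature_key(key, design.periods)
            periods = [period] if period else list(design.periods)
            for p in periods:
                shift[group][p][name_idx[name]] += d * noise_sd
                truth.group_effects[group][f"{name}@{p}"] = d * noise_sd

    day_idx = meta["day"].to_numpy() - 1
    group_arr = meta["group"].to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    for period in design.periods:
        day_shift = rng.normal(0.0, day_sd, size=(design.n_days, n_feat)) if day_sd > 0 \
            else np.zeros((design.n_days, n_feat))
        noise = rng.normal(0.0, noise_sd, size=(n_wells, n_feat)) if noise_sd > 0 \
            else np.zeros((n_wells, n_feat))
        values = day_shift[day_idx] + noise
        for g in design.groups:
            values[group_arr == g] += shift[g][period]
        tables[period] = pd.DataFrame(values, index=meta["well_id"], columns=names)
    return tables, meta, truth


# --------------------------------------------------------------------------- #
# screen generation
# --------------------------------------------------------------------------- #

def make_screen_compound_specs(
    n_compounds: int,
    *,
    n_full: int = 3,
    n_partial: int = 5,
    n_toxic: int = 0,
    n_side_effect_features: int = 200,
    side_effect_size: float = 3.0,
    partial_rescue_fraction: float = 0.25,
    available_features: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, EffectSpec]:
    """Standard compound mix for a synthetic screen.

    Categories are assigned in order: full rescuers, partial rescuers
    (rescue_fraction 0.25 — a genuine but sub-threshold improvement), toxic
    compounds (full rescue plus ``n_side_effect_features`` off-target shifts),
    then inert compounds.  Side-effect features are sampled without
    replacement from ``available_features``.
    """
    if n_full + n_partial + n_toxic > n_compounds:
        raise ValueError("category counts exceed n_compounds")
    rng = np.random.default_rng(seed)
    specs: dict[str, EffectSpec] = {}
    pool = list(available_features or [])
    for i in range(n_compounds):
        name = f"drug{i + 1:03d}"
        if i < n_full:
            specs[name] = EffectSpec(rescue_fraction=1.0)
        elif i < n_full + n_partial:
            specs[name] = EffectSpec(rescue_fraction=partial_rescue_fraction)
        elif i < n_full + n_partial + n_toxic:
            if len(pool) < n_side_effect_features:
                raise ValueError("not enough available_features for side effects")
            chosen = rng.choice(len(pool), size=n_side_effect_features, replace=False)
            specs[name] = EffectSpec(
                rescue_fraction=1.0,
                side_effect_features={pool[j]: side_effect_size for j in chosen},
            )
        else:
            specs[name] = EffectSpec()
    return specs


def generate_screen_experiment(
    design: ExperimentDesign,
    disease_effects: EffectSpec,
    compound_specs: Mapping[str, EffectSpec],
    *,
    wt_group: str = "N2_DMSO",
    disease_group: str = "mut_DMSO",
    disease_strain: str = "mut",
    rescue_features: Sequence[str] = SCREEN_CORE_FEATURES,
    names: Sequence[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate a full screen: controls plus one mutant+compound group each.

    ``design.groups`` supplies the control groups (wild-type vehicle and
    disease-model vehicle); each compound adds a group ``{strain}_{name}``
    with the same day/replicate structure.  Compound wells carry the disease
    shifts with ``rescue_fraction`` of the mutant–wild-type gap removed on
    ``rescue_features`` (every period), plus any side-effect shifts.
    """
    if wt_group not in design.groups or disease_group not in design.groups:
        raise ValueError("design.groups must contain both control groups")
    if not compound_specs:
        warnings.warn("zero compounds: screen experiment contains controls only")
    names = list(names) if names is not None else feature_names(
        design.n_features_per_period, core_first=True)

    compound_groups = {c: f"{disease_strain}_{c}" for c in compound_specs}
    full = ExperimentDesign(
        n_days=design.n_days,
        wells_per_group_per_day=design.wells_per_group_per_day,
        groups=tuple(design.groups) + tuple(compound_groups.values()),
        n_features_per_period=design.n_features_per_period,
        periods=design.periods,
        seed=design.seed,
    )
    rescue_set = set(rescue_features)
    effects: dict[str, EffectSpec] = {disease_group: disease_effects}
    truth = GroundTruth(noise_sd=disease_effects.noise_sd, day_sd=disease_effects.day_sd)
    for comp, spec in compound_specs.items():
        sizes: dict[str, float] = {}
        for key, d in disease_effects.effect_sizes.items():
            base_name, _ = _split_feature_key(key, design.periods)
            if base_name in rescue_set:
                residual = d * (1.0 - spec.rescue_fraction)
                if residual != 0.0:
                    sizes[key] = residual
            else:
                sizes[key] = d
        for key, d in spec.side_effect_features.items():
            sizes[key] = sizes.get(key, 0.0) + d
        effects[compound_groups[comp]] = EffectSpec(
            effect_sizes=sizes,
            day_sd=disease_effects.day_sd,
            noise_sd=disease_effects.noise_sd,
        )
        truth.compound_categories[comp] = spec.category
        truth.side_effects[comp] = sorted(spec.side_effect_features)

    drug_of = {wt_group: "DMSO", disease_group: "DMSO"}
    drug_of.update({g: c for c, g in compound_groups.items()})
    tables, meta, inner_truth = generate_feature_experiment(
        full, effects, names=names, drug_of=drug_of)
    truth.group_effects = inner_truth.group_effects
    return tables, meta, truth


# --------------------------------------------------------------------------- #
# skeleton tracks
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class StimulusSchedule:
    """Recording timeline: three periods with blue-light pulses in the middle one."""

    frame_rate: float = 25.0
    period_durations: tuple[float, float, float] = (300.0, 360.0, 300.0)
    pulse_starts: tuple[float, ...] = (60.0, 160.0, 260.0)
    pulse_duration: float = 10.0
    periods: tuple[str, ...] = PERIODS

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        blue = self.period_durations[1]
        for t0 in self.pulse_starts:
            if not (0.0 <= t0 and t0 + self.pulse_duration <= blue):
                raise ValueError("pulses must lie entirely within the bluelight period")

    @property
    def total_duration(self) -> float:
        return float(sum(self.period_durations))

    def period_of(self, t: np.ndarray) -> np.ndarray:
        """Period label for each time (seconds from recording start)."""
        edges = np.cumsum(self.period_durations)
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(self.periods) - 1)
        return np.asarray(self.periods)[idx]

    def period_start(self, period: str) -> float:
        i = self.periods.index(period)
        return float(sum(self.period_durations[:i]))


@dataclass(frozen=True)
class WormParams:
    """Kinematic parameters of a simulated worm.

    Lengths in micrometres, speed in µm/s, undulation amplitude in radians of
    tangent angle, frequency in Hz.  ``pause_prob`` gives the per-period
    probability (per second) of entering a ~1 s pause; ``faint_prob`` is the
    probability of pausing throughout the 10 s window that follows each
    blue-light pulse (the "fainter" phenotype of NALCN-pathway mutants).
    """

    length_um: float = 1000.0
    width_um: float = 100.0
    n_points: int = 49
    speed_um_s: float = 300.0
    undulation_amplitude: float = 0.6
    undulation_waves: float = 1.5
    undulation_freq_hz: float = 0.5
    pause_prob: Mapping[str, float] = field(default_factory=dict)
    faint_prob: float = 0.0
    faint_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("worm length and width must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")


@dataclass
class Track:
    """One worm's skeleton time series: coords (T, P, 2) µm, widths (T, P) µm."""

    coords: np.ndarray
    widths: np.ndarray
    times: np.ndarray
    modes: np.ndarray  # ground-truth per-frame mode: "forward" | "paused"


@dataclass
class TrackSet:
    tracks: list[Track]
    schedule: StimulusSchedule
    params: WormParams


def _width_profile(params: WormParams) -> np.ndarray:
    # tapered profile, maximal at midbody
    s = np.linspace(0.0, 1.0, params.n_points)
    return params.width_um * np.sqrt(np.clip(np.sin(np.pi * s), 1e-3, None))


def generate_skeleton_tracks(
    schedule: StimulusSchedule,
    params: WormParams,
    *,
    n_tracks: int = 1,
    seed: int = 0,
    duration_s: float | None = None,
) -> TrackSet:
    """Simulate skeleton tracks following the stimulus schedule.

    The midline is built from a sinusoidal tangent-angle profile integrated
    with fixed segment length, so the arc length equals ``length_um`` exactly
    at every frame.  The head (point 0) leads; while moving, the centroid
    translates at ``speed_um_s`` along the heading.  Paused frames freeze
    both translation and the undulation phase.
    """
    rng = np.random.default_rng(seed)
    T_total = duration_s if duration_s is not None else schedule.total_duration
    dt = 1.0 / schedule.frame_rate
    n_frames = int(round(T_total * schedule.frame_rate))
    times = np.arange(n_frames) * dt
    period_labels = schedule.period_of(times)
    widths_row = _width_profile(params)

    blue_start = schedule.period_start("bluelight") if "bluelight" in schedule.periods else 0.0
    pulse_ends = np.array([blue_start + t0 + schedule.pulse_duration
                           for t0 in schedule.pulse_starts])

    tracks: list[Track] = []
    seg = params.length_um / (params.n_points - 1)
    s_frac = np.arange(params.n_points) / (params.n_points - 1)
    for _ in range(n_tracks):
        heading = rng.uniform(0.0, 2 * np.pi)
        pos = rng.uniform(0.0, 1000.0, size=2)

        # per-frame motion mode
        modes = np.full(n_frames, "forward", dtype=object)
        for period in schedule.periods:
            p = params.pause_prob.get(period, 0.0)
            if p <= 0:
                continue
            in_period = period_labels == period
            # ~1 s pauses triggered at per-second rate p
            pause_len = int(round(schedule.frame_rate))
            starts = np.flatnonzero(in_period & (rng.random(n_frames) < p * dt))
            for s0 in starts:
                modes[s0:s0 + pause_len] = "paused"
        if params.faint_prob > 0:
            for pe in pulse_ends:
                if rng.random() < params.faint_prob:
                    f0 = int(round(pe * schedule.frame_rate))
                    f1 = int(round((pe + params.faint_duration_s) * schedule.frame_rate))
                    modes[f0:f1] = "paused"

        moving = modes == "forward"
        phase = np.cumsum(np.where(moving, 2 * np.pi * params.undulation_freq_hz * dt, 0.0))
        step = np.where(moving, params.speed_um_s * dt, 0.0)
        disp = np.stack([np.cumsum(step * np.cos(heading)),
                         np.cumsum(step * np.sin(heading))], axis=1)
        centres = pos + disp

        # tangent angles (frames x points); head first, body extends backwards
        theta = heading + np.pi + params.undulation_amplitude * np.sin(
            2 * np.pi * params.undulation_waves * s_frac[None, :-1] - phase[:, None])
        dxy = seg * np.stack([np.cos(theta), np.sin(theta)], axis=2)
        coords = np.concatenate(
            [np.zeros((n_frames, 1, 2)), np.cumsum(dxy, axis=1)], axis=1)
        coords = coords - coords.mean(axis=1, keepdims=True) + centres[:, None, :]
        widths = np.broadcast_to(widths_row, (n_frames, params.n_points)).copy()
        tracks.append(Track(coords=coords, widths=widths, times=times.copy(),
                            modes=modes))
    return TrackSet(tracks=tracks, schedule=schedule, params=params)
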