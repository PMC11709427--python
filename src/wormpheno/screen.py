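"""Drug-repurposing screen inference: hit calling, confirmation, side effects.

A hit is a compound whose treated disease-model wells differ significantly
from disease-model vehicle controls on *every* core feature (by default the
blue-light curvature / speed / fraction-paused triplet) with each effect
directed toward the wild-type control mean.  Significance uses the
day-blocked permutation t-test with BY correction across the core features
within each compound.  The confirmation stage re-runs hit calling at higher
replication and adds side-effect counting: a side effect is a feature that
does not distinguish untreated disease models from wild-type but does
distinguish drug-treated disease models from wild-type; compounds with more
than ``side_effect_threshold`` (default 1000) such features are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import StatsConfig, benjamini_yekutieli, \
    block_permutation_ttest_matrix, compare_groups
from .synthetic_data import SCREEN_CORE_FEATURES

__all__ = ["ScreenConfig", "ScreenResult", "call_hits", "count_side_effects",
           "phenospace_coords", "confirmation_screen"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-level settings.

    ``core_features`` are taken from the ``core_period`` table;
    ``side_effect_threshold`` partitions compounds by their side-effect
    count.  ``wt_group`` and ``disease_group`` are the vehicle controls.
    """

    core_features: tuple[str, ...] = SCREEN_CORE_FEATURES
    core_period: str = "bluelight"
    hit_alpha: float = 0.05
    side_effect_threshold: int = 1000
    stats: StatsConfig = field(default_factory=StatsConfig)
    wt_group: str = "N2_DMSO"
    disease_group: str = "mut_DMSO"
    min_wells_per_compound: int = 2

    def __post_init__(self) -> None:
        if not self.core_features:
            raise ValueError("core_features must be non-empty")
        if self.side_effect_threshold <= 0:
            raise ValueError("side_effect_threshold must be positive")


@dataclass
class ScreenResult:
    """Per-compound hit table plus bookkeeping.

    ``table`` has one row per compound with, for each core feature ``f``:
    ``{f}_p``, ``{f}_p_adjusted``, ``{f}_toward_wt``; plus ``hit``,
    ``n_wells`` and the 3-D core phenospace coordinates ``coord_{f}``.
    """

    table: pd.DataFrame
    config: ScreenConfig
    skipped: list[str] = field(default_factory=list)

    @property
    def hits(self) -> list[str]:
        return list(self.table.index[self.table["hit"]])


def _core_table(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                cfg: ScreenConfig) -> pd.DataFrame:
    tab = tables[cfg.core_period] if isinstance(tables, Mapping) else tables
    missing = [f for f in cfg.core_features if f not in tab.columns]
    if missing:
        raise ValueError(f"core features missing from table: {missing}")
    return tab


def _compounds(metadata: pd.DataFrame, cfg: ScreenConfig) -> list[str]:
    groups = [g for g in metadata["group"].unique()
              if g not in (cfg.wt_group, cfg.disease_group)]
    return sorted(groups)


def call_hits(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
              metadata: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()
              ) -> ScreenResult:
    """Core-feature hit calling against the disease-vehicle control.

    For each compound and core feature, a day-blocked permutation t-test of
    compound wells vs disease-vehicle wells is BY-corrected across the core
    features within the compound; the direction criterion requires
    ``sign(mean_drug − mean_diseaseVehicle) == sign(mean_WT − mean_diseaseVehicle)``
    (an exactly zero gap counts as not-toward-wild-type).  ``hit`` is the
    conjunction over all core features of significance and direction.
    """
    meta = metadata[~metadata["bad_well"].astype(bool)]
    for ctrl in (cfg.wt_group, cfg.disease_group):
        if (meta["group"] == ctrl).sum() == 0:
            raise ValueError(f"missing control group {ctrl!r}")
    core = _core_table(tables, cfg)[list(cfg.core_features)]
    by_well = meta.set_index("well_id")

    def group_rows(g: str) -> pd.DataFrame:
        wells = by_well.index[by_well["group"] == g].intersection(core.index)
        return core.loc[wells]

    wt_mean = group_rows(cfg.wt_group).mean()
    dis_rows = group_rows(cfg.disease_group)
    dis_mean = dis_rows.mean()
    dis_days = by_well.loc[dis_rows.index, "day"].to_numpy()
    wt_dir = np.sign(wt_mean - dis_mean)

    records, skipped = [], []
    for comp in _compounds(meta, cfg):
        rows = group_rows(comp)
        if rows.shape[0] < cfg.min_wells_per_compound:
            skipped.append(comp)
            log.warning("compound %s skipped: %d wells", comp, rows.shape[0])
            continue
        X = np.concatenate([rows.to_numpy(float), dis_rows.to_numpy(float)])
        in_a = np.concatenate([np.ones(rows.shape[0], bool),
                               np.zeros(dis_rows.shape[0], bool)])
        days = np.concatenate([by_well.loc[rows.index, "day"].to_numpy(),
                               dis_days])
        res = block_permutation_ttest_matrix(X, in_a, days, cfg.stats)
        adjusted, reject = benjamini_yekutieli(res.p, cfg.stats.fdr_q)
        drug_mean = rows.mean()
        toward = (np.sign(drug_mean - dis_mean) == wt_dir) & (wt_dir != 0)
        rec: dict = {"compound": comp, "n_wells": rows.shape[0]}
        hit = True
        for i, f in enumerate(cfg.core_features):
            rec[f"{f}_p"] = res.p[i]
            rec[f"{f}_p_adjusted"] = adjusted[i]
            rec[f"{f}_toward_wt"] = bool(toward[f])
            rec[f"{f}_significant"] = bool(reject[i])
            hit &= bool(reject[i]) and bool(toward[f])
            rec[f"coord_{f}"] = float(drug_mean[f])
        rec["hit"] = hit
        records.append(rec)
    table = pd.DataFrame(records).set_index("compound") if records else \
        pd.DataFrame(columns=["hit"])
    return ScreenResult(table=table, config=cfg, skipped=skipped)


def phenospace_coords(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                      metadata: pd.DataFrame,
                      cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """3-D core-feature coordinates: per-group mean over wells.

    Controls are included, so the disease-vehicle and wild-type "stars" and
    every compound live in the same space.
    """
    meta = metadata[~metadata["bad_well"].astype(bool)]
    core = _core_table(tables, cfg)[list(cfg.core_features)]
    key = meta.set_index("well_id")["group"]
    usable = core.index.intersection(key.index)
    coords = core.loc[usable].groupby(key.loc[usable]).mean()
    coords.index.name = "group"
    return coords


@dataclass
class SideEffectReport:
    """Per-compound side-effect counts plus the feature sets behind them."""

    table: pd.DataFrame                 # side_effect_count, above_threshold
    disease_features: list[str]         # the set D (WT vs disease vehicle)
    features: dict[str, list[str]]      # compound -> side-effect features

    def __iter__(self):  # allows `table, disease = count_side_effects(...)`
        return iter((self.table, self.disease_features))


def count_side_effects(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                       metadata: pd.DataFrame,
                       compounds: Sequence[str] | None = None,
                       cfg: ScreenConfig = ScreenConfig()
                       ) -> SideEffectReport:
    """Side-effect counts over the full feature set.

    The disease feature set D holds features significant between wild-type
    and disease-model vehicle wells (BY over all features).  For each
    compound, side effects are features *outside* D that are significant
    between wild-type and drug-treated disease wells.
    """
    meta = metadata[~metadata["bad_well"].astype(bool)]
    if compounds is None:
        compounds = _compounds(meta, cfg)
    base = compare_groups(tables, meta, cfg.wt_group, cfg.disease_group,
                          cfg.stats)
    disease_set = set(base.significant_features)
    records = []
    features: dict[str, list[str]] = {}
    for comp in compounds:
        if (meta["group"] == comp).sum() == 0:
            records.append({"compound": comp, "side_effect_count": np.nan,
                            "above_threshold": False, "tested": False})
            continue
        res = compare_groups(tables, meta, cfg.wt_group, comp, cfg.stats)
        side = [f for f in res.significant_features if f not in disease_set]
        features[comp] = side
        records.append({
            "compound": comp,
            "side_effect_count": len(side),
            "above_threshold": len(side) > cfg.side_effect_threshold,
            "tested": True,
        })
    table = pd.DataFrame(records).set_index("compound")
    return SideEffectReport(table=table, disease_features=sorted(disease_set),
                            features=features)


def confirmation_screen(initial: ScreenResult,
                        tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                        metadata: pd.DataFrame,
                        cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Re-test initial hits at confirmation scale and attach side effects.

    Only compounds flagged as hits in ``initial`` are considered; compounds
    absent from the confirmation data are reported untested.  Returns one
    row per initial hit with ``confirmed``, ``side_effect_count`` and
    ``above_threshold``.
    """
    cfg = cfg or initial.config
    meta = metadata[~metadata["bad_well"].astype(bool)]
    present = set(meta["group"])
    selected = [c for c in initial.hits]
    conf = call_hits(tables, meta, cfg)
    side, _ = count_side_effects(
        tables, meta, [c for c in selected if c in present], cfg)
    records = []
    for comp in selected:
        if comp not in present:
            records.append({"compound": comp, "tested": False,
                            "confirmed": False, "side_effect_count": np.nan,
                            "above_threshold": False})
            continue
        confirmed = bool(conf.table.loc[comp, "hit"]) if comp in conf.table.index \
            else False
        records.append({
            "compound": comp,
            "tested": True,
            "confirmed": confirmed,
            "side_effect_count": side.loc[comp, "side_effect_count"],
            "above_threshold": bool(side.loc[comp, "above_threshold"]),
        })
    return pd.DataFrame(records).set_index("compound")
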