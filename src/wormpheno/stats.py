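"""Day-blocked permutation t-tests and Benjamini-Yekutieli FDR control.

Well replicates in a tracking experiment come in day blocks: wells recorded
on the same day share plate, food and environment, so only wells within a
day are exchangeable under the null.  The permutation null is therefore
built by re-assigning group labels uniformly at random among the wells of
each day, preserving the per-day label counts — labels are shuffled within,
never between, independent tracking days.  When the number of distinct
within-day arrangements is small the null is enumerated exhaustively and the
p-value is exact; otherwise Monte-Carlo sampling with the +1-corrected
estimator is used.  Per-feature p-values for one comparison are corrected
with the Benjamini-Yekutieli step-up procedure (valid under arbitrary
dependence) at a 5% false-discovery rate.

The permutation machinery is fully vectorised over features: a single set of
label re-assignments is applied to the whole wells-by-features matrix, which
both matches the joint-permutation convention (one permutation stream per
comparison) and keeps 10,000-permutation runs over thousands of features
fast.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "PermutationTest",
    "StatsResult",
    "block_permutation_ttest",
    "block_permutation_ttest_matrix",
    "benjamini_yekutieli",
    "compare_groups",
    "n_block_arrangements",
    "block_permutation_matrix",
]

_TIE_TOL = 1e-9  # relative tolerance when counting |t_perm| >= |t_obs|


@dataclass(frozen=True)
class StatsConfig:
    """Settings for one two-group comparison.

    ``n_permutations`` defaults to 10,000; ``exhaustive_threshold`` switches
    to exact enumeration when the number of distinct within-day label
    arrangements does not exceed it.  ``equal_var=False`` selects the Welch
    t statistic (robust default for unequal well counts).
    """

    n_permutations: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    rng_seed: int = 0
    exhaustive_threshold: int = 10_000
    equal_var: bool = False
    max_undefined_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PermutationTest:
    """Result of one (possibly multi-feature) block permutation test."""

    t_obs: np.ndarray
    p: np.ndarray
    n_used: int
    exhaustive: bool
    undefined: np.ndarray  # True where pooled variance was zero


def n_block_arrangements(days: np.ndarray, in_a: np.ndarray) -> int:
    """Number of distinct within-day group-label arrangements."""
    total = 1
    for d in np.unique(days):
        sel = days == d
        total *= math.comb(int(sel.sum()), int(in_a[sel].sum()))
    return total


def block_permutation_matrix(days: np.ndarray, in_a: np.ndarray,
                             cfg: StatsConfig) -> tuple[np.ndarray, bool]:
    """Boolean (R, n_wells) matrix of group-A assignments under the block null.

    Every row preserves the observed per-day group-A counts; no assignment
    ever moves a well across days.  Exhaustive when the arrangement count is
    within ``cfg.exhaustive_threshold`` (rows then enumerate all arrangements,
    including the observed one); otherwise ``cfg.n_permutations`` random rows.
    """
    days = np.asarray(days)
    in_a = np.asarray(in_a, bool)
    n = len(days)
    day_ids = np.unique(days)
    for d in day_ids:
        sel = days == d
        if in_a[sel].all() or not in_a[sel].any():
            warnings.warn(f"day {d!r} has all wells in one group: "
                          "it contributes no permutation freedom")
    total = n_block_arrangements(days, in_a)
    if total == 1:
        warnings.warn("only one within-day arrangement exists: "
                      "the permutation test has no freedom")
    if total <= cfg.exhaustive_threshold:
        per_day_choices = []
        for d in day_ids:
            idx = np.flatnonzero(days == d)
            k = int(in_a[idx].sum())
            per_day_choices.append([np.asarray(c, int)
                                    for c in itertools.combinations(idx, k)])
        rows = np.zeros((total, n), dtype=bool)
        for r, combo in enumerate(itertools.product(*per_day_choices)):
            for c in combo:
                rows[r, c] = True
        return rows, True
    rng = np.random.default_rng(cfg.rng_seed)
    rows = np.zeros((cfg.n_permutations, n), dtype=bool)
    for d in day_ids:
        idx = np.flatnonzero(days == d)
        k = int(in_a[idx].sum())
        u = rng.random((cfg.n_permutations, len(idx)))
        order = np.argsort(u, axis=1)[:, :k]
        rows[np.arange(cfg.n_permutations)[:, None], idx[order]] = True
    return rows, False


def _t_from_sums(sum_a, sq_a, n_a, sum_b, sq_b, n_b, equal_var):
    """t statistics from per-group sums/sums-of-squares (vectorised)."""
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = (sq_a - n_a * mean_a ** 2) / max(n_a - 1, 1)
    var_b = (sq_b - n_b * mean_b ** 2) / max(n_b - 1, 1)
    var_a = np.clip(var_a, 0.0, None)
    var_b = np.clip(var_b, 0.0, None)
    if equal_var:
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        denom = np.sqrt(var_a / n_a + var_b / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return t, denom


def block_permutation_ttest_matrix(
    X: np.ndarray,
    in_a: np.ndarray,
    days: np.ndarray,
    cfg: StatsConfig = StatsConfig(),
    *,
    feature_chunk: int = 2048,
) -> PermutationTest:
    """Day-blocked permutation t-tests for all columns of ``X`` jointly.

    ``X`` is (n_wells, n_features) with pooled wells of both groups;
    ``in_a`` flags group-A membership; ``days`` holds per-well day labels.
    The observed two-sample t statistic (Welch by default) is compared to
    the null distribution obtained by re-labelling wells within days.  The
    two-sided p is the exact tail fraction under exhaustive enumeration, or
    ``(1 + #{|t*| >= |t|}) / (R + 1)`` under Monte-Carlo sampling.  Features
    with zero pooled variance are flagged undefined (p = NaN).
    """
    X = np.atleast_2d(np.asarray(X, float))
    in_a = np.asarray(in_a, bool)
    days = np.asarray(days)
    if X.shape[0] != in_a.size or in_a.size != days.size:
        raise ValueError("X rows, group flags and day labels must align")
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    P, exhaustive = block_permutation_matrix(days, in_a, cfg)
    Pf = P.astype(np.float64)
    R = P.shape[0]
    m = X.shape[1]
    t_obs = np.empty(m)
    p = np.empty(m)
    undefined = np.zeros(m, dtype=bool)
    obs = in_a.astype(np.float64)

    for c0 in range(0, m, feature_chunk):
        sl = slice(c0, min(c0 + feature_chunk, m))
        Xc = X[:, sl]
        X2c = Xc ** 2
        tot, tot2 = Xc.sum(axis=0), X2c.sum(axis=0)
        t0, denom0 = _t_from_sums(obs @ Xc, obs @ X2c, n_a,
                                  tot - obs @ Xc, tot2 - obs @ X2c, n_b,
                                  cfg.equal_var)
        sum_a = Pf @ Xc
        sq_a = Pf @ X2c
        t_perm, _ = _t_from_sums(sum_a, sq_a, n_a, tot - sum_a, tot2 - sq_a,
                                 n_b, cfg.equal_var)
        bad = ~np.isfinite(t0)
        abs_t0 = np.abs(np.where(bad, np.inf, t0))
        thresh = abs_t0 * (1.0 - _TIE_TOL) - _TIE_TOL
        count = (np.abs(np.where(np.isfinite(t_perm), t_perm, 0.0))
                 >= thresh[None, :]).sum(axis=0)
        if exhaustive:
            pc = count / R
        else:
            pc = (1.0 + count) / (R + 1.0)
        pc = np.where(bad, np.nan, np.clip(pc, 0.0, 1.0))
        t_obs[sl] = np.where(bad, np.nan, t0)
        p[sl] = pc
        undefined[sl] = bad
    return PermutationTest(t_obs=t_obs, p=p, n_used=R, exhaustive=exhaustive,
                           undefined=undefined)


def block_permutation_ttest(x: Sequence[float], y: Sequence[float],
                            days_x: Sequence, days_y: Sequence,
                            cfg: StatsConfig = StatsConfig()
                            ) -> tuple[float, float]:
    """Single-feature convenience wrapper: returns (t_obs, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.concatenate([x, y])[:, None]
    in_a = np.concatenate([np.ones(len(x), bool), np.zeros(len(y), bool)])
    days = np.concatenate([np.asarray(days_x), np.asarray(days_y)])
    res = block_permutation_ttest_matrix(X, in_a, days, cfg)
    return float(res.t_obs[0]), float(res.p[0])


def benjamini_yekutieli(p_values: Sequence[float], q: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray]:
    """BY step-up adjusted p-values and rejection mask at FDR level ``q``.

    Adjusted p_(i) = min_{j>=i} min(1, c(m)·m·p_(j)/j) with the harmonic
    penalty c(m)=Σ_{i<=m} 1/i; valid under arbitrary dependence between
    tests.  NaN entries (undefined features) are excluded from m and
    returned as NaN / not rejected.
    """
    p = np.asarray(p_values, float)
    adjusted = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return adjusted, reject
    _, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_by")
    adjusted[ok] = adj
    reject[ok] = adj < q
    return adjusted, reject


@dataclass
class StatsResult:
    """Per-feature results of one two-group comparison."""

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_permutations_used: int
    exhaustive: bool
    n_excluded: int = 0

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _stack_periods(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                   wells: pd.Index) -> tuple[np.ndarray, list[str]]:
    if isinstance(tables, pd.DataFrame):
        tables = {"all": tables}
    mats, names = [], []
    for period, tab in tables.items():
        sub = tab.loc[wells]
        mats.append(sub.to_numpy(float))
        tag = "" if period == "all" else f"@{period}"
        names.extend(f"{c}{tag}" for c in sub.columns)
    return np.concatenate(mats, axis=1), names


def compare_groups(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                   metadata: pd.DataFrame, group_a: str, group_b: str,
                   cfg: StatsConfig = StatsConfig()) -> StatsResult:
    """Per-feature block permutation tests of group A vs group B, BY-corrected.

    ``tables`` maps recording periods to wells-by-features tables (or a
    single table); features from all periods are tested jointly with one
    permutation stream, and BY is applied across the full tested feature set
    of the comparison.  Bad wells are excluded up front.  A feature
    undefined in more than half the wells of either group is excluded
    (logged in ``n_excluded``); remaining NaNs exclude the feature as well.
    """
    meta = metadata[~metadata["bad_well"].astype(bool)]
    sel = meta[meta["group"].isin([group_a, group_b])]
    if (sel["group"] == group_a).sum() == 0 or (sel["group"] == group_b).sum() == 0:
        raise ValueError(f"groups {group_a!r}/{group_b!r} have no usable wells")
    wells = pd.Index(sel["well_id"])
    X, names = _stack_periods(tables, wells)
    in_a = (sel["group"] == group_a).to_numpy()
    days = sel["day"].to_numpy()

    # exclude features with too much missingness in either group
    nan_frac_a = np.isnan(X[in_a]).mean(axis=0)
    nan_frac_b = np.isnan(X[~in_a]).mean(axis=0)
    keep = (nan_frac_a <= cfg.max_undefined_fraction) & \
           (nan_frac_b <= cfg.max_undefined_fraction) & \
           ~np.isnan(X).any(axis=0)
    n_excluded = int((~keep).sum())

    res = block_permutation_ttest_matrix(X[:, keep], in_a, days, cfg)
    adjusted, reject = benjamini_yekutieli(res.p, cfg.fdr_q)

    mean_a = X[in_a].mean(axis=0)
    mean_b = X[~in_a].mean(axis=0)
    table = pd.DataFrame(index=pd.Index(names, name="feature"))
    table["t"] = np.nan
    table["p"] = np.nan
    table["p_adjusted"] = np.nan
    table["significant"] = False
    table["tested"] = keep
    table.loc[keep, "t"] = res.t_obs
    table.loc[keep, "p"] = res.p
    table.loc[keep, "p_adjusted"] = adjusted
    table.loc[keep, "significant"] = reject
    table["direction"] = np.sign(mean_a - mean_b)
    table["n_a"] = int(in_a.sum())
    table["n_b"] = int((~in_a).sum())
    return StatsResult(table=table, group_a=group_a, group_b=group_b,
                       n_permutations_used=res.n_used,
                       exhaustive=res.exhaustive, n_excluded=n_excluded)
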