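"""Multi-period behavioural fingerprints, clustering and PCA phenospace.

A fingerprint concatenates a strain's (or well's) feature vectors over the
three recording periods in fixed order (prestim, bluelight, poststim); a
period barcode records which period each entry came from.  With the full
2763-feature manifest the fingerprint has 8289 entries; with the reduced
256-feature manifest, 768.  Fingerprints are Z-normalised feature-wise
before hierarchical clustering, and a single PCA fitted jointly on all
strain-by-period rows places the three period vectors of each strain in one
shared phenospace so stimulus-response trajectories can be read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA

from . import PERIODS

__all__ = [
    "Fingerprint",
    "ClusterResult",
    "PhenospaceProjection",
    "build_fingerprint",
    "z_normalise",
    "hierarchical_cluster",
    "linkage_to_newick",
    "pca_phenospace",
]

log = logging.getLogger(__name__)


@dataclass
class Fingerprint:
    """Entities-by-concatenated-features matrix with a period barcode."""

    values: pd.DataFrame
    periods: np.ndarray  # barcode: period label per column
    level: str = "strain"
    normalised: bool = False
    zero_variance_features: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)


def build_fingerprint(tables: Mapping[str, pd.DataFrame],
                      metadata: pd.DataFrame | None = None,
                      level: str = "strain",
                      period_order: Sequence[str] = PERIODS) -> Fingerprint:
    """Concatenate per-period tables into fingerprints.

    ``tables`` maps period name to a wells-by-features table; the
    concatenation order is fixed by ``period_order``.  At ``level="well"``
    each well keeps its own fingerprint; at ``level="strain"`` wells are
    averaged per group using ``metadata`` (bad wells dropped first).  Well
    sets are outer-joined across periods; wells missing from a period get
    NaN entries.  Period tables must share one column manifest.
    """
    missing = [p for p in period_order if p not in tables]
    if missing:
        raise ValueError(f"tables missing periods: {missing}")
    manifests = {p: tuple(tables[p].columns) for p in period_order}
    ref = manifests[period_order[0]]
    bad = [p for p, m in manifests.items() if m != ref]
    if bad:
        raise ValueError(
            f"period tables disagree on the feature manifest: {bad} vs "
            f"{period_order[0]}")

    all_wells = pd.Index(sorted(set().union(*(tables[p].index for p in period_order))))
    blocks, barcode, names = [], [], []
    for p in period_order:
        blk = tables[p].reindex(all_wells)
        blocks.append(blk)
        barcode.extend([p] * blk.shape[1])
        names.extend(f"{c}@{p}" for c in blk.columns)
    wide = pd.concat(blocks, axis=1)
    wide.columns = names

    if level == "well":
        values = wide
    elif level == "strain":
        if metadata is None:
            raise ValueError("strain-level fingerprints need metadata")
        meta = metadata[~metadata["bad_well"].astype(bool)]
        key = meta.set_index("well_id")["group"]
        usable = wide.index.intersection(key.index)
        values = wide.loc[usable].groupby(key.loc[usable]).mean()
        values.index.name = "group"
    else:
        raise ValueError("level must be 'strain' or 'well'")
    return Fingerprint(values=values, periods=np.asarray(barcode), level=level)


def z_normalise(fp: Fingerprint) -> Fingerprint:
    """Z-score each feature column across entities (sample SD, ddof=1).

    Zero-variance columns are set to 0 and recorded in
    ``zero_variance_features``.
    """
    if fp.values.shape[0] < 2:
        raise ValueError("z-normalisation needs >= 2 entities")
    mean = fp.values.mean(axis=0)
    sd = fp.values.std(axis=0, ddof=1)
    flagged = list(fp.values.columns[(sd == 0) | sd.isna()])
    safe = sd.replace(0.0, np.nan)
    z = (fp.values - mean) / safe
    z[z.columns[(sd == 0)]] = 0.0
    if flagged:
        log.info("z_normalise: %d zero-variance features set to 0", len(flagged))
    return Fingerprint(values=z, periods=fp.periods.copy(), level=fp.level,
                       normalised=True, zero_variance_features=flagged)


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy 4-column merge table
    labels: list[str]            # entity labels in input order
    leaf_order: list[str]        # dendrogram leaf order, left to right
    cophenetic: np.ndarray       # condensed cophenetic distance matrix

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster assignment at ``k`` clusters."""
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def hierarchical_cluster(fp: Fingerprint, metric: str = "euclidean",
                         method: str = "average") -> ClusterResult:
    """Agglomerative clustering of fingerprints (Euclidean/average default).

    Entities are sorted by label before linkage so the result is invariant
    to input order; undefined entries must be imputed or dropped first.
    """
    if fp.values.isna().any().any():
        raise ValueError("fingerprints contain undefined entries; impute or "
                         "drop them before clustering (e.g. per-feature mean)")
    if fp.values.shape[0] < 2:
        raise ValueError("clustering needs >= 2 entities")
    ordered = fp.values.sort_index()
    labels = list(ordered.index)
    Z = sch.linkage(ordered.to_numpy(), method=method, metric=metric)
    leaves = sch.leaves_list(Z)
    coph = sch.cophenet(Z)
    return ClusterResult(linkage=Z, labels=labels,
                         leaf_order=[labels[i] for i in leaves],
                         cophenetic=coph)


def linkage_to_newick(result: ClusterResult) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths."""
    tree = sch.to_tree(result.linkage)

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


@dataclass
class PhenospaceProjection:
    """Joint PCA of strain-by-period mean fingerprints.

    ``coords`` holds one row per (strain, period) with the projected mean
    coordinates and the standard error of the mean over that strain's wells
    (columns ``pc{i}`` and ``pc{i}_sem``).
    """

    coords: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    feature_names: list[str]

    def trajectory(self, strain: str) -> pd.DataFrame:
        """Per-period coordinates of one strain in period order."""
        sub = self.coords[self.coords["group"] == strain]
        return sub.set_index("period").loc[[p for p in PERIODS
                                            if p in set(sub["period"])]]


def pca_phenospace(tables: Mapping[str, pd.DataFrame], metadata: pd.DataFrame,
                   n_components: int = 2,
                   period_order: Sequence[str] = PERIODS
                   ) -> PhenospaceProjection:
    """PCA phenospace with per-strain, per-period trajectories.

    Strain-by-period mean feature vectors (bad wells excluded) are
    Z-normalised over the pooled rows and decomposed with a single PCA, so
    the three recording periods share one set of axes.  Individual wells are
    projected onto those axes to give the SEM of each (strain, period) mean.
    """
    meta = metadata[~metadata["bad_well"].astype(bool)]
    key = meta.set_index("well_id")["group"]

    rows, row_keys, well_rows, well_keys = [], [], [], []
    for period in period_order:
        tab = tables[period]
        usable = tab.index.intersection(key.index)
        sub = tab.loc[usable]
        grouped = sub.groupby(key.loc[usable]).mean()
        for g in grouped.index:
            rows.append(grouped.loc[g].to_numpy(float))
            row_keys.append((g, period))
        for w in sub.index:
            well_rows.append(sub.loc[w].to_numpy(float))
            well_keys.append((key.loc[w], period))
    M = np.vstack(rows)
    mean, sd = M.mean(axis=0), M.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Mz = (M - mean) / sd_safe

    rank = min(Mz.shape)
    if n_components > rank:
        log.warning("n_components=%d exceeds rank %d; truncating",
                    n_components, rank)
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(Mz)

    W = (np.vstack(well_rows) - mean) / sd_safe
    well_proj = pca.transform(W)

    records = []
    for (g, period), xy in zip(row_keys, proj):
        sel = [i for i, k in enumerate(well_keys) if k == (g, period)]
        wp = well_proj[sel]
        sem = wp.std(axis=0, ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 \
            else np.zeros(n_components)
        rec = {"group": g, "period": period}
        for i in range(n_components):
            rec[f"pc{i + 1}"] = float(xy[i])
            rec[f"pc{i + 1}_sem"] = float(sem[i])
        records.append(rec)
    first_table = tables[period_order[0]]
    return PhenospaceProjection(
        coords=pd.DataFrame(records),
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        feature_names=list(first_table.columns),
    )
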