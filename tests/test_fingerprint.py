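"""Fingerprint construction, Z-normalisation, clustering, PCA phenospace."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from wormpheno import fingerprint as fpm
from wormpheno.synthetic_data import (EffectSpec, ExperimentDesign,
                                      generate_feature_experiment)


def toy_tables(values_by_entity, periods=("prestim", "bluelight", "poststim")):
    """Per-period tables with identical values in every period."""
    idx = pd.Index(list(values_by_entity), name="well_id")
    df = pd.DataFrame([values_by_entity[e] for e in idx], index=idx)
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    return {p: df.copy() for p in periods}


def toy_meta(entities):
    return pd.DataFrame({"well_id": entities, "group": entities,
                         "day": 1, "bad_well": False})


class TestBuildFingerprint:
    @pytest.mark.parametrize("k,expected", [(2763, 8289), (256, 768), (7, 21)])
    def test_concatenated_length(self, k, expected):
        tabs = {p: pd.DataFrame(np.zeros((2, k)),
                                index=pd.Index(["w1", "w2"], name="well_id"),
                                columns=[f"f{i}" for i in range(k)])
                for p in ("prestim", "bluelight", "poststim")}
        fp = fpm.build_fingerprint(tabs, level="well")
        assert fp.length == expected
        assert len(fp.periods) == expected

    def test_period_order_and_barcode(self):
        tabs = toy_tables({"a": [1.0], "b": [2.0]})
        tabs["bluelight"] += 10
        fp = fpm.build_fingerprint(tabs, level="well")
        assert list(fp.periods) == ["prestim", "bluelight", "poststim"]
        assert fp.values.loc["a"].tolist() == [1.0, 11.0, 1.0]

    def test_concatenation_preserves_values(self, small_experiment):
        tables, meta, _ = small_experiment
        fp = fpm.build_fingerprint(tables, meta, level="well")
        some_well = tables["poststim"].index[3]
        np.testing.assert_array_equal(
            fp.values.loc[some_well, fp.periods == "poststim"].to_numpy(),
            tables["poststim"].loc[some_well].to_numpy())

    def test_strain_level_is_well_mean(self, small_experiment):
        tables, meta, _ = small_experiment
        fp = fpm.build_fingerprint(tables, meta, level="strain")
        grp = meta.set_index("well_id")["group"]
        expected = tables["prestim"].groupby(grp).mean()
        np.testing.assert_allclose(
            fp.values.loc["N2_DMSO", fp.periods == "prestim"],
            expected.loc["N2_DMSO"])

    def test_mismatched_manifests_rejected(self):
        tabs = toy_tables({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        tabs["poststim"] = tabs["poststim"].rename(columns={"f1": "other"})
        with pytest.raises(ValueError, match="manifest"):
            fpm.build_fingerprint(tabs, level="well")

    def test_outer_join_marks_missing_wells(self):
        tabs = toy_tables({"a": [1.0], "b": [2.0]})
        tabs["bluelight"] = tabs["bluelight"].drop(index="b")
        fp = fpm.build_fingerprint(tabs, level="well")
        assert np.isnan(fp.values.loc["b", "f0@bluelight"])


class TestZNormalise:
    def test_two_point_column_sample_sd(self):
        tabs = toy_tables({"a": [1.0], "b": [3.0]})
        fp = fpm.build_fingerprint(tabs, level="well")
        z = fpm.z_normalise(fp)
        np.testing.assert_allclose(z.values.loc["a"], -1 / np.sqrt(2))
        np.testing.assert_allclose(z.values.loc["b"], 1 / np.sqrt(2))

    def test_constant_column_zeroed_and_flagged(self):
        tabs = toy_tables({"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]})
        z = fpm.z_normalise(fpm.build_fingerprint(tabs, level="well"))
        assert (z.values["f0@prestim"] == 0).all()
        assert "f0@prestim" in z.zero_variance_features

    def test_columns_standardised(self, small_experiment):
        tables, meta, _ = small_experiment
        z = fpm.z_normalise(fpm.build_fingerprint(tables, meta, level="well"))
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0,
                                   atol=1e-12)

    def test_single_entity_rejected(self):
        tabs = toy_tables({"a": [1.0]})
        with pytest.raises(ValueError, match="2 entities"):
            fpm.z_normalise(fpm.build_fingerprint(tabs, level="well"))


class TestClustering:
    def test_close_pair_merges_first(self):
        tabs = toy_tables({"a": [0.0], "b": [1.0], "c": [10.0]})
        fp = fpm.build_fingerprint(tabs, level="well")
        res = fpm.hierarchical_cluster(fp)
        cut = res.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_duplicate_entity_merges_at_zero(self):
        tabs = toy_tables({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        res = fpm.hierarchical_cluster(fpm.build_fingerprint(tabs, level="well"))
        assert res.linkage[0, 2] == 0.0

    def test_input_order_invariance(self):
        tabs1 = toy_tables({"a": [0.0], "b": [1.0], "c": [10.0]})
        tabs2 = {p: t.iloc[::-1] for p, t in tabs1.items()}
        r1 = fpm.hierarchical_cluster(fpm.build_fingerprint(tabs1, level="well"))
        r2 = fpm.hierarchical_cluster(fpm.build_fingerprint(tabs2, level="well"))
        assert r1.leaf_order == r2.leaf_order
        np.testing.assert_array_equal(r1.linkage, r2.linkage)

    def test_undefined_entries_rejected(self):
        tabs = toy_tables({"a": [0.0], "b": [1.0], "c": [10.0]})
        tabs["prestim"].iloc[0, 0] = np.nan
        fp = fpm.build_fingerprint(tabs, level="well")
        with pytest.raises(ValueError, match="impute"):
            fpm.hierarchical_cluster(fp)

    def test_planted_two_cluster_partition_recovered(self):
        groups = tuple(f"s{i}" for i in range(8))
        design = ExperimentDesign(groups=groups, n_features_per_period=40,
                                  seed=21)
        effects = {g: EffectSpec(effect_sizes={f"ft{j:04d}": 3.0
                                               for j in range(10)})
                   for g in groups[:4]}
        tables, meta, _ = generate_feature_experiment(design, effects)
        z = fpm.z_normalise(fpm.build_fingerprint(tables, meta, level="strain"))
        res = fpm.hierarchical_cluster(z)
        cut = res.cut(2)
        planted = [1 if g in groups[:4] else 0 for g in res.labels]
        found = [cut[g] for g in res.labels]
        assert adjusted_rand_score(planted, found) == 1.0

    def test_newick_roundtrip_parses(self):
        tabs = toy_tables({"a": [0.0], "b": [1.0], "c": [10.0]})
        res = fpm.hierarchical_cluster(fpm.build_fingerprint(tabs, level="well"))
        nwk = fpm.linkage_to_newick(res)
        assert nwk.endswith(";")
        for label in ("a", "b", "c"):
            assert label in nwk


class TestPhenospace:
    def test_line_data_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-1, 1, 12)
        base = pd.DataFrame({"f0": t, "f1": 2 * t, "f2": -t},
                            index=pd.Index([f"w{i}" for i in range(12)],
                                           name="well_id"))
        tabs = {p: base.copy() for p in ("prestim", "bluelight", "poststim")}
        meta = toy_meta(list(base.index))
        proj = fpm.pca_phenospace(tabs, meta, n_components=2)
        assert proj.explained_variance_ratio[0] > 0.999

    def test_identical_periods_identical_coordinates(self, small_experiment):
        tables, meta, _ = small_experiment
        tabs = {p: tables["prestim"] for p in tables}
        proj = fpm.pca_phenospace(tabs, meta, n_components=2)
        tr = proj.trajectory("N2_DMSO")
        np.testing.assert_allclose(tr["pc1"], tr["pc1"].iloc[0], atol=1e-9)
        np.testing.assert_allclose(tr["pc2"], tr["pc2"].iloc[0], atol=1e-9)

    def test_explained_variance_monotone_sums_below_one(self, small_experiment):
        tables, meta, _ = small_experiment
        proj = fpm.pca_phenospace(tables, meta, n_components=3)
        evr = proj.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_bluelight_shift_displaces_trajectories(self):
        """Light-responsive strains move along a shared axis in phenospace."""
        groups = tuple(f"s{i}" for i in range(6))
        design = ExperimentDesign(groups=groups, n_features_per_period=30,
                                  seed=33)
        shifted = groups[:3]
        effects = {}
        sizes_by_group = {}
        for i, g in enumerate(shifted):
            d = 2.0 + 2.0 * i  # varying planted magnitude
            sizes_by_group[g] = d
            # low day_sd isolates the planted stimulus response from batch drift
            effects[g] = EffectSpec(effect_sizes={
                f"ft{j:04d}@bluelight": d for j in range(10)}, day_sd=0.05)
        tables, meta, _ = generate_feature_experiment(design, effects)
        proj = fpm.pca_phenospace(tables, meta, n_components=2)
        disp = {}
        for g in groups:
            tr = proj.trajectory(g)
            vec = tr.loc["bluelight", ["pc1", "pc2"]].to_numpy(float) - \
                tr.loc["prestim", ["pc1", "pc2"]].to_numpy(float)
            disp[g] = vec
        # shifted strains displace along a common direction ...
        units = [disp[g] / np.linalg.norm(disp[g]) for g in shifted]
        assert min(abs(units[0] @ u) for u in units[1:]) > 0.9
        # ... along which they move further than unshifted strains ...
        axis = np.mean(units, axis=0)
        axis /= np.linalg.norm(axis)
        proj_shifted = [abs(disp[g] @ axis) for g in shifted]
        proj_null = [abs(disp[g] @ axis) for g in groups[3:]]
        assert min(proj_shifted) > max(proj_null)
        # ... with magnitude tracking the planted effect size
        r = np.corrcoef(proj_shifted,
                        [sizes_by_group[g] for g in shifted])[0, 1]
        assert r > 0.9
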