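"""Pooling, version checking, QC screening, feature selection, embeddings."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ciliametry.explorer import (
    check_version_consistency,
    discriminate,
    embed,
    pool_groups,
    qc_screen,
    select_features,
)
from ciliametry.io_formats import CiliaTable, RunMetadata, write_cilia_table


def write_group(folder, n_tables=3, n_records=10, version="v0.1.7", length=3.0):
    folder.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(abs(hash(folder.name)) % 2 ** 31)
    for i in range(n_tables):
        df = pd.DataFrame({
            "id": np.arange(1, n_records + 1),
            "cilia_length_um": rng.normal(length, 0.4, n_records),
            "volume_um3": rng.normal(0.5, 0.05, n_records),
            "n_branches": np.ones(n_records, dtype=int),
        })
        table = CiliaTable(data=df, metadata=RunMetadata(tool_version=version))
        write_cilia_table(table, folder / f"rep_{i}.tsv")
    return folder


class TestPooling:
    def test_counts_and_group_labels(self, tmp_path):
        a = write_group(tmp_path / "24h_starved", 3, 10)
        b = write_group(tmp_path / "72h_starved", 3, 10)
        ds = pool_groups([a, b])
        assert ds.n_records() == 60
        assert ds.group_labels == ["24h_starved", "72h_starved"]
        pooled = ds.pooled()
        assert set(pooled["group"]) == {"24h_starved", "72h_starved"}
        assert len(pooled) == 60

    def test_duplicate_folder_rejected(self, tmp_path):
        a = write_group(tmp_path / "a")
        with pytest.raises(ValueError, match="twice"):
            pool_groups([a, a])

    def test_empty_folder_is_an_error(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(ValueError, match="no readable tables"):
            pool_groups([empty])

    def test_missing_folder_named_in_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope"):
            pool_groups([tmp_path / "nope"])


class TestVersionConsistency:
    def test_uniform_versions_consistent(self, tmp_path):
        ds = pool_groups([write_group(tmp_path / "a"), write_group(tmp_path / "b")])
        ok, msg = check_version_consistency(ds)
        assert ok and "v0.1.7" in msg

    def test_mismatch_warns_and_lists_both(self, tmp_path):
        a = write_group(tmp_path / "a", version="v0.1.7")
        b = write_group(tmp_path / "b", version="v0.1.6")
        ds = pool_groups([a, b])
        with pytest.warns(UserWarning, match="bias"):
            ok, msg = check_version_consistency(ds)
        assert not ok
        assert "v0.1.6" in msg and "v0.1.7" in msg

    def test_missing_version_warns_but_stays_consistent(self, tmp_path):
        a = write_group(tmp_path / "a")
        (a / "rep_0.meta.txt").unlink()
        ds = pool_groups([a])
        with pytest.warns(UserWarning, match="no tool version"):
            ok, msg = check_version_consistency(ds)
        assert ok
        assert "unknown" in msg


class TestQCScreen:
    def test_identical_values_no_flags(self, tmp_path):
        folder = tmp_path / "g"
        folder.mkdir()
        df = pd.DataFrame({"id": [1, 2, 3, 4, 5],
                           "cilia_length_um": [3.0] * 5,
                           "n_branches": [1] * 5})
        write_cilia_table(CiliaTable(data=df, metadata=RunMetadata("v1")),
                          folder / "r.tsv")
        report = qc_screen(pool_groups([folder]))
        assert report.flags == []

    def test_planted_length_outlier_flagged(self, tmp_path):
        folder = tmp_path / "g"
        folder.mkdir()
        lengths = [3.0, 3.1, 2.9, 3.05, 2.95, 30.0]  # 10x the median
        df = pd.DataFrame({"id": range(1, 7), "cilia_length_um": lengths})
        write_cilia_table(CiliaTable(data=df, metadata=RunMetadata("v1")),
                          folder / "r.tsv")
        report = qc_screen(pool_groups([folder]))
        flagged = [(f.cilium_id, f.measurement) for f in report.flags]
        assert (6, "cilia_length_um") in flagged

    def test_highly_branched_record_flagged(self, tmp_path):
        folder = tmp_path / "g"
        folder.mkdir()
        df = pd.DataFrame({"id": [1, 2], "n_branches": [1, 15]})
        write_cilia_table(CiliaTable(data=df, metadata=RunMetadata("v1")),
                          folder / "r.tsv")
        report = qc_screen(pool_groups([folder]))
        assert any(f.cilium_id == 2 and "branched" in f.reason
                   for f in report.flags)

    def test_small_group_fences_skipped_with_notice(self, tmp_path):
        folder = tmp_path / "tiny"
        folder.mkdir()
        df = pd.DataFrame({"id": [1, 2], "cilia_length_um": [1.0, 99.0]})
        write_cilia_table(CiliaTable(data=df, metadata=RunMetadata("v1")),
                          folder / "r.tsv")
        report = qc_screen(pool_groups([folder]))
        assert any("fences skipped" in n for n in report.notices)
        assert not any(f.measurement == "cilia_length_um" and "fence" in f.reason
                       for f in report.flags)

    def test_report_roundtrips_to_text(self, tmp_path):
        folder = write_group(tmp_path / "g")
        report = qc_screen(pool_groups([folder]))
        text = report.to_text()
        for fl in report.flags:
            assert f"id={fl.cilium_id}" in text


class TestFeatureSelection:
    def test_exclusion_rules_on_constructed_table(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "id": np.arange(20),
            "x": rng.normal(size=20),
            "volume_voxels": rng.integers(10, 100, 20),
            "volume_um3": rng.normal(0.5, 0.1, 20),
            "cilia_length_um": rng.normal(3, 0.5, 20),
        })
        features, excluded = select_features(df)
        assert list(features.columns) == ["volume_um3", "cilia_length_um"]
        assert set(excluded) == {"id", "x", "volume_voxels"}

    def test_threshold_and_constant_columns_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "channel_a_threshold": rng.normal(size=20),
            "flat": np.full(20, 7.0),
            "a": rng.normal(size=20),
            "b": rng.normal(size=20),
        })
        features, excluded = select_features(df)
        assert set(excluded) == {"channel_a_threshold", "flat"}
        np.testing.assert_allclose(features.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(features.std(ddof=0), 1, rtol=1e-12)

    def test_fewer_than_two_features_raises(self):
        df = pd.DataFrame({"id": [1, 2], "a": [0.1, 0.2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            select_features(df)


def separated_groups(n=60, shift=5.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(2 * n, 4))
    base[n:, :3] += shift  # planted effect on 3 of 4 features
    features = pd.DataFrame(base, columns=["f1", "f2", "f3", "f4"])
    features = (features - features.mean()) / features.std(ddof=0)
    labels = np.array(["a"] * n + ["b"] * n)
    return features, labels


class TestEmbedding:
    def test_pca_separates_planted_groups(self):
        features, labels = separated_groups()
        coords, info = embed(features, "pca", seed=0)
        ca = coords[labels == "a"]
        cb = coords[labels == "b"]
        between = np.linalg.norm(ca.mean(0) - cb.mean(0))
        within = max(ca.std(0).max(), cb.std(0).max())
        assert between > within
        assert sum(info["explained_variance_ratio"]) <= 1.0

    def test_pca_sign_convention_deterministic(self):
        features, _ = separated_groups(seed=3)
        c1, i1 = embed(features, "pca", seed=0)
        c2, i2 = embed(features, "pca", seed=99)  # seed irrelevant for PCA
        np.testing.assert_allclose(c1, c2)
        for comp in i1["components"]:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_identical_records_graceful_error(self):
        df = pd.DataFrame(np.zeros((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="identical"):
            embed(df, "pca")

    def test_umap_same_seed_same_coordinates(self):
        features, _ = separated_groups(n=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1, _ = embed(features, "umap", seed=42, n_neighbors=10)
            c2, _ = embed(features, "umap", seed=42, n_neighbors=10)
        np.testing.assert_allclose(c1, c2)

    def test_umap_n_neighbors_auto_reduced(self):
        features, _ = separated_groups(n=5)
        with pytest.warns(UserWarning, match="reducing"):
            coords, info = embed(features, "umap", seed=1, n_neighbors=50)
        assert info["n_neighbors"] == 9


class TestDiscriminate:
    def test_planted_effect_feature_ranked_first(self):
        rng = np.random.default_rng(5)
        n = 80
        df = pd.DataFrame({
            "cilia_length_um": np.r_[rng.normal(0, 1, n), rng.normal(3, 1, n)],
            "volume_um3": rng.normal(0, 1, 2 * n),
            "max_span_um": rng.normal(0, 1, 2 * n),
        })
        df = (df - df.mean()) / df.std(ddof=0)
        labels = ["a"] * n + ["b"] * n
        table = discriminate(df, labels)
        assert table.index[0] == "cilia_length_um"

    def test_identical_groups_near_zero_separation(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        df = (df - df.mean()) / df.std(ddof=0)
        labels = ["a"] * 100 + ["b"] * 100
        table = discriminate(df, labels)
        # no real separation: all coefficients comparable, none dominant
        assert table["max_abs_coefficient"].max() < 10

    def test_three_groups_two_axes(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(90, 4)), columns=list("abcd"))
        labels = ["g1"] * 30 + ["g2"] * 30 + ["g3"] * 30
        table = discriminate(df, labels)
        assert {"LD1", "LD2"} <= set(table.columns)
        assert "LD3" not in table.columns

    def test_single_group_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="2 groups"):
            discriminate(df, ["a"] * 10)
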