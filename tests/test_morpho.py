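"""Morphometrics, QC filtering and mosaic-label demultiplexing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from organomorph import morpho
from organomorph.synthgen import _ball_mask, _orthonormal_basis, \
    _rasterize_ellipsoid

ISO = morpho.ISO_VOXEL_UM


def ellipsoid_instance(axes_um, basis=None, spacing=(ISO, ISO, ISO),
                       pad_um=6.0):
    spacing = np.asarray(spacing, float)
    extent = (np.max(axes_um) + pad_um) * 2
    shape = tuple(int(np.ceil(extent / s)) for s in spacing)
    centre = np.array(shape) * spacing / 2
    out = np.zeros(shape, dtype=np.uint16)
    basis = np.eye(3) if basis is None else basis
    _rasterize_ellipsoid(out, spacing, centre, axes_um, basis, 1)
    return out


class TestExtractFeatures:
    def test_ball_is_round(self):
        inst = ellipsoid_instance((10 * ISO,) * 3)
        table = morpho.extract_features(
            inst, np.full(inst.shape, 100.0), (ISO,) * 3
        )
        row = table.iloc[0]
        assert abs(row.axis_ratio - 1.0) <= 0.05
        assert abs(row.sphericity - 1.0) <= 0.1

    def test_prolate_axis_ratio(self):
        inst = ellipsoid_instance((20 * ISO, 5 * ISO, 5 * ISO))
        table = morpho.extract_features(
            inst, np.full(inst.shape, 100.0), (ISO,) * 3
        )
        ratio = table.iloc[0].axis_major_um / table.iloc[0].axis_minor_um
        assert abs(ratio - 4.0) / 4.0 <= 0.10

    def test_small_objects_dropped_and_empty_ok(self):
        inst = np.zeros((20, 20, 20), dtype=np.uint16)
        inst[5:10, 5:10, 5:9] = 1  # 100 voxels at iso scale
        inst[12:14, 12:14, 12:14] = 2  # 8 voxels: below threshold
        table = morpho.extract_features(
            inst, np.full(inst.shape, 50.0), (ISO,) * 3
        )
        assert set(table.structure_id) == {1}
        empty = morpho.extract_features(
            np.zeros((8, 8, 8), dtype=np.uint16), np.zeros((8, 8, 8)),
            (ISO,) * 3,
        )
        assert empty.empty

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            morpho.extract_features(
                np.zeros((4, 4, 4), dtype=np.uint16), np.zeros((4, 4, 5)),
                (1, 1, 1),
            )

    def test_axis_ratio_rotation_robust(self):
        axes = (12.0, 4.0, 4.0)
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(3):
            v = rng.standard_normal(3)
            basis = _orthonormal_basis(v / np.linalg.norm(v), rng)
            inst = ellipsoid_instance(axes, basis)
            tab = morpho.extract_features(
                inst, np.full(inst.shape, 80.0), (ISO,) * 3
            )
            ratios.append(tab.iloc[0].axis_ratio)
        assert (max(ratios) - min(ratios)) / np.mean(ratios) < 0.10


class TestQCFilter:
    def make_row(self, **overrides):
        row = {
            "structure_id": 1, "frame": 0, "channel": "gfp",
            "volume_voxels": 150, "volume_um3": 50.0,
            "surface_area_um2": 70.0, "axis_major_um": 5.0,
            "axis_minor_um": 4.0, "axis_ratio": 0.8, "sphericity": 0.9,
            "solidity": 0.9, "intensity_mean": 60.0, "intensity_max": 120.0,
            "intensity_sd": 5.0,
        }
        row.update(overrides)
        return row

    @pytest.mark.parametrize(
        "overrides,kept",
        [
            ({"volume_voxels": 150, "intensity_max": 19.0}, False),
            ({"volume_voxels": 99, "intensity_max": 200.0}, False),
            ({"volume_voxels": 150, "intensity_max": 20.0}, True),
            ({"volume_voxels": 100, "intensity_max": 20.0}, True),
            ({"sphericity": np.nan}, False),
        ],
    )
    def test_strict_boundaries(self, overrides, kept):
        table = pd.DataFrame([self.make_row(**overrides)])
        out = morpho.qc_filter(table)
        assert (len(out) == 1) == kept

    def test_never_increases_rows(self, qc_features):
        assert len(morpho.qc_filter(qc_features)) <= len(qc_features)


class TestDemux:
    def test_holdout_accuracy_on_separable_scene(self, demux_model):
        assert demux_model.test_accuracy >= 0.90

    def test_grid_search_deterministic(self, qc_features, demux_model):
        small = {"n_estimators": [50], "max_depth": [5, 10]}
        m1 = morpho.train_demux(qc_features, seed=0, grid=small)
        m2 = morpho.train_demux(qc_features, seed=0, grid=small)
        pd.testing.assert_frame_equal(m1.grid_results, m2.grid_results)

    def test_permuted_labels_give_chance_accuracy(self, qc_features):
        rng = np.random.default_rng(0)
        # balance classes so chance level is 1/6
        n = qc_features["label"].value_counts().min()
        bal = qc_features.groupby("label").head(n).reset_index(drop=True)
        accs = []
        for rep in range(3):
            perm = bal.copy()
            perm["label"] = rng.permutation(perm["label"].to_numpy())
            m = morpho.train_demux(
                perm, seed=rep, test_fraction=0.25,
                grid={"n_estimators": [50], "max_depth": [10]},
            )
            accs.append(m.test_accuracy)
        assert abs(np.mean(accs) - 1 / 6) <= 0.1

    def test_too_few_examples_rejected(self, qc_features):
        broken = qc_features[
            (qc_features.label != "actin") | (qc_features.frame == 0)
        ]
        broken = pd.concat(
            [broken[broken.label != "actin"],
             broken[broken.label == "actin"].iloc[:1]]
        )
        with pytest.raises(ValueError):
            morpho.train_demux(broken)

    def test_crossval_confusion_conserves_counts(self, qc_features,
                                                 demux_model):
        conf, precision, classes = morpho.crossval_confusion(
            qc_features, demux_model, seed=0
        )
        totals = qc_features["label"].value_counts()
        for i, cls in enumerate(classes):
            assert conf[i].sum() == totals[cls]
        # per-marker precision equals TP/(TP+FP) on the faulty-free matrix
        keep = [i for i, c in enumerate(classes) if c != "faulty"]
        sub = conf[np.ix_(keep, keep)]
        for j, cls in enumerate([classes[i] for i in keep]):
            expected = sub[j, j] / sub[:, j].sum()
            assert precision[cls] == pytest.approx(expected)

    def test_crossval_requires_k_members(self, qc_features, demux_model):
        few = pd.concat(
            [qc_features[qc_features.label != "faulty"],
             qc_features[qc_features.label == "faulty"].iloc[:3]]
        )
        with pytest.raises(ValueError):
            morpho.crossval_confusion(few, demux_model, k=5)


class TestDemuxPredict:
    def constant_model(self, table, label):
        X = table[["volume_um3"]].to_numpy()
        forest = RandomForestClassifier(n_estimators=5, random_state=0)
        forest.fit(X, [label] * len(table))
        return morpho.DemuxModel(
            forest=forest, feature_columns=["volume_um3"],
            labels=morpho.LABELS, grid_results=pd.DataFrame(),
            best_params={}, test_accuracy=1.0,
        )

    def base_table(self, channel):
        return pd.DataFrame(
            [{"structure_id": i, "channel": channel, "volume_um3": 100.0}
             for i in range(3)]
        )

    def test_wrong_channel_predictions_removed(self):
        table = self.base_table("gfp")
        model = self.constant_model(table, "lamin")  # RFP-only label
        out = morpho.demux_predict(model, table)
        assert out.empty

    def test_right_channel_predictions_kept(self):
        table = self.base_table("rfp")
        model = self.constant_model(table, "tubulin")
        out = morpho.demux_predict(model, table)
        assert len(out) == 3
        assert set(out.predicted_label) == {"tubulin"}

    def test_all_faulty_gives_empty_demux(self, caplog):
        table = self.base_table("gfp")
        model = self.constant_model(table, "faulty")
        with caplog.at_level("WARNING"):
            out = morpho.demux_predict(model, table)
        assert set(out.predicted_label) == {"faulty"}
        assert "faulty" in caplog.text

    def test_schema_mismatch_errors(self):
        table = self.base_table("gfp")
        model = self.constant_model(table, "actin")
        with pytest.raises(ValueError):
            morpho.demux_predict(model, table.drop(columns=["volume_um3"]))


def test_demux_accuracy_monotone_in_noise():
    """More intensity noise never helps the demultiplexer (weak check)."""
    from organomorph import synthgen

    accs = []
    for noise in (2.0, 60.0):
        scene = synthgen.generate_scene(
            synthgen.demux_scene_params(seed=8, n_per_class=12, n_faulty=8,
                                        n_frames=2, noise_sd=noise)
        )
        table = morpho.qc_filter(morpho.extract_scene_features(scene))
        m = morpho.train_demux(
            table, seed=0, grid={"n_estimators": [50], "max_depth": [10]}
        )
        accs.append(m.test_accuracy)
    assert accs[1] <= accs[0] + 0.05
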