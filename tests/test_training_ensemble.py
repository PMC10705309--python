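import numpy as np
import pytest

from rfseg.datasetbuild import split_patients
from rfseg.ensemble import (EnsembleSpec, compute_weights, rfsplus_run,
                            RFSPlusConfig, select_top3, union_combine)
from rfseg.labelspace import LabelVolume
from rfseg.phantom import PhantomPatient
from rfseg.training import (CandidateScore, LeakageError, TrainConfig,
                            evaluate_candidate, fit_normalizer, train_candidate)
from rfseg.unet import TrainedModel, UNetConfig, build_unet


def _micro_unet(approach="multi_label"):
    out, head = {"multi_class": (4, "softmax"), "multi_label": (3, "sigmoid"),
                 "binary": (1, "sigmoid")}[approach]
    return UNetConfig(dims=2, in_channels=4, out_channels=out, depth=2,
                      base_channels=2, head=head)


@pytest.fixture(scope="module")
def split6(small_cohort):
    return split_patients([p.patient_id for p in small_cohort], seed=3)


class TestTrainCandidate:
    def test_loss_decreases_and_log_is_complete(self, small_cohort, split6):
        tc = TrainConfig(epochs=3, batch_size=8, learning_rate=1e-2, seed=0,
                         augmentation=False)
        model = train_candidate(small_cohort, split6, "multi_label", "zscore",
                                _micro_unet(), tc)
        assert len(model.training_log) == 3
        assert model.training_log[-1]["train_loss"] < model.training_log[0]["train_loss"]
        assert "val_loss" in model.training_log[0]

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_same_seed_reproduces_training_log(self, small_cohort, split6):
        tc = TrainConfig(epochs=1, batch_size=8, learning_rate=1e-2, seed=5,
                         augmentation=True)
        log_a = train_candidate(small_cohort, split6, "binary", "zscore",
                                _micro_unet("binary"), tc, region="wt").training_log
        log_b = train_candidate(small_cohort, split6, "binary", "zscore",
                                _micro_unet("binary"), tc, region="wt").training_log
        assert log_a == log_b


@pytest.fixture(scope="module")
def silent_model():
    """Untrained net biased to predict no tumor anywhere."""
    cfg = _micro_unet("binary")
    net = build_unet(cfg, seed=0)
    net.final.bias.value[...] = -30.0
    net.final.weight.value[...] = 0.0
    return TrainedModel(config=cfg, approach="binary",
                        normalization_id="zscore", network=net, region="tc")


class TestEvaluateCandidate:
    def test_all_zero_prediction_scores_zero_on_tumor(self, small_cohort, silent_model):
        norm = fit_normalizer("zscore", small_cohort[:4])
        score = evaluate_candidate(silent_model, small_cohort[4:], "tc", norm)
        assert score.region_dsc["tc"] == 0.0

    def test_all_zero_prediction_scores_one_without_tumor(self, small_cohort, silent_model):
        p = small_cohort[5]
        healthy = PhantomPatient(
            patient_id="healthy", volume=p.volume,
            labels=LabelVolume(values=np.zeros_like(p.labels.values)),
            scanner_id=p.scanner_id)
        norm = fit_normalizer("zscore", small_cohort[:4])
        score = evaluate_candidate(silent_model, [healthy], "tc", norm)
        assert score.region_dsc["tc"] == 1.0  # empty-vs-empty convention

    def test_evaluation_is_pure(self, small_cohort, silent_model):
        norm = fit_normalizer("zscore", small_cohort[:4])
        a = evaluate_candidate(silent_model, small_cohort[4:], "tc", norm)
        b = evaluate_candidate(silent_model, small_cohort[4:], "tc", norm)
        assert a.region_dsc == b.region_dsc

    def test_empty_patient_list_rejected(self, small_cohort, silent_model):
        norm = fit_normalizer("zscore", small_cohort[:4])
        with pytest.raises(ValueError):
            evaluate_candidate(silent_model, [], "tc", norm)

    def test_normalization_leakage_guard(self, small_cohort, split6):
        """Nyul state fitted on evaluation patients must be refused."""
        leaky = fit_normalizer("nyul", small_cohort)  # includes test patients
        tc = TrainConfig(epochs=1, batch_size=8, learning_rate=1e-2, seed=0,
                         augmentation=False)
        model = train_candidate(small_cohort, split6, "binary", leaky,
                                _micro_unet("binary"), tc, region="tc")
        by_id = {p.patient_id: p for p in small_cohort}
        test_patients = [by_id[i] for i in split6.test_ids]
        with pytest.raises(LeakageError):
            evaluate_candidate(model, test_patients, "tc", leaky)


def _score(norm, approach, tc_dsc):
    return CandidateScore(candidate_id=f"{norm}/{approach}", approach=approach,
                          normalization_id=norm, region_dsc={"tc": tc_dsc})


class TestSelection:
    def test_grid_worked_example(self):
        """Published 2D grid TC scores pick Z-score/multi-class,
        Z-score/binary and Nyul/binary, in that order."""
        scores = [
            _score("nyul", "multi_class", 79.53),
            _score("nyul", "multi_label", 88.78),
            _score("nyul", "binary", 89.42),
            _score("zscore", "multi_class", 89.71),
            _score("zscore", "multi_label", 87.27),
            _score("zscore", "binary", 89.48),
        ]
        assert select_top3(scores, "tc") == [
            "zscore/multi_class", "zscore/binary", "nyul/binary"]

    def test_tie_break_uses_fixed_candidate_order(self):
        scores = [_score(n, a, 0.5) for n in ("zscore", "nyul")
                  for a in ("multi_class", "multi_label", "binary")]
        assert select_top3(scores, "tc") == [
            "zscore/multi_class", "nyul/multi_class", "zscore/multi_label"]

    def test_exactly_three_candidates(self):
        scores = [_score("zscore", a, s) for a, s in
                  [("multi_class", 0.2), ("multi_label", 0.9), ("binary", 0.5)]]
        assert select_top3(scores, "tc") == [
            "zscore/multi_label", "zscore/binary", "zscore/multi_class"]

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_top3([_score("zscore", "binary", 0.5)], "tc")


class TestWeights:
    def test_equal_scores_give_thirds(self):
        np.testing.assert_allclose(compute_weights([0.8, 0.8, 0.8]), 1 / 3)

    def test_published_tc_scores(self):
        w = compute_weights([89.71, 89.48, 89.42])
        np.testing.assert_allclose(w, [0.33398, 0.33312, 0.33290], atol=5e-6)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_forced_arithmetic(self):
        np.testing.assert_allclose(compute_weights([1, 1, 2]), [0.25, 0.25, 0.5])

    def test_scale_invariance(self):
        np.testing.assert_allclose(compute_weights([0.7, 0.8, 0.9]),
                                   compute_weights([70, 80, 90]), atol=1e-12)

    def test_nonpositive_scores_need_explicit_fallback(self):
        with pytest.raises(ValueError):
            compute_weights([0.0, 0.5, 0.5])
        np.testing.assert_allclose(compute_weights([0.0, 0.5, 0.5], equal=True), 1 / 3)


class TestEnsembleCombiners:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            EnsembleSpec(region="tc", members=("a", "a", "b"),
                         weights=(0.4, 0.3, 0.3))
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleSpec(region="tc", members=("a", "b", "c"),
                         weights=(0.5, 0.4, 0.3))

    def test_spec_json_round_trip(self, tmp_path):
        spec = EnsembleSpec(region="wt", members=("a", "b", "c"),
                            weights=(0.5, 0.25, 0.25), threshold=0.5)
        spec.to_json(tmp_path / "spec.json")
        assert EnsembleSpec.from_json(tmp_path / "spec.json") == spec

    def test_union_is_superset_or(self, rng):
        masks = [rng.random((4, 4, 4)) < 0.3 for _ in range(3)]
        out = union_combine(masks)
        for m in masks:
            assert np.all(out >= m)
        disjoint = [np.zeros((2, 2, 2), bool) for _ in range(3)]
        for i, m in enumerate(disjoint):
            m.ravel()[i] = True
        assert union_combine(disjoint).sum() == 3
        assert np.array_equal(union_combine([masks[0]] * 3), masks[0])
        with pytest.raises(ValueError, match="grid"):
            union_combine([np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool)])

    def test_weighted_mean_thresholding(self, monkeypatch, small_cohort):
        """Voxel probabilities (0.9, 0.2, 0.2) at equal weights average to
        0.4333 < 0.5 and fall to background."""
        import rfseg.ensemble as ens

        shape = small_cohort[0].volume.shape
        fixed = {"zscore/multi_class": 0.9, "zscore/multi_label": 0.2,
                 "zscore/binary": 0.2}

        def fake_predict(model, patient, normalizer, regions):
            cid = f"{model.normalization_id}/{model.approach}"
            return {r: np.full(shape, fixed[cid]) for r in regions}

        monkeypatch.setattr(ens, "predict_regions", fake_predict)
        members = {}
        for approach in ("multi_class", "multi_label", "binary"):
            cfg = _micro_unet(approach)
            members[f"zscore/{approach}"] = TrainedModel(
                config=cfg, approach=approach, normalization_id="zscore",
                network=build_unet(cfg, seed=0))
        spec = EnsembleSpec(region="tc", members=tuple(members),
                            weights=(1 / 3, 1 / 3, 1 / 3))
        mask = ens.ensemble_predict(spec, members, small_cohort[0],
                                    {"zscore": fit_normalizer("zscore", [])})
        assert not mask.any()
        # degenerate weights reduce to the single member's mask
        spec1 = EnsembleSpec(region="tc", members=tuple(members), weights=(1.0, 0.0, 0.0))
        mask1 = ens.ensemble_predict(spec1, members, small_cohort[0],
                                     {"zscore": fit_normalizer("zscore", [])})
        assert mask1.all()  # member 1 predicts 0.9 everywhere


@pytest.fixture(scope="module")
def micro_config():
    # one epoch exercises the plumbing, not learning quality, so weights
    # use the explicit equal-weight mode (candidates may still score 0)
    return RFSPlusConfig(
        approaches=("multi_class", "multi_label", "binary"),
        normalizations=("zscore",),
        variant="2d", unet_depth=2, unet_base_channels=2,
        train=TrainConfig(epochs=1, batch_size=8, learning_rate=1e-2,
                          seed=2, augmentation=False),
        split_seed=3, equal_weights=True)


class TestEndToEndMicro:
    def test_rfsplus_produces_valid_spec_and_is_reproducible(self, small_cohort,
                                                             micro_config):
        a = rfsplus_run(small_cohort, "tc", micro_config)
        assert len(set(a.spec.members)) == 3
        assert sum(a.spec.weights) == pytest.approx(1.0, abs=1e-9)
        assert set(a.member_dsc) == set(a.spec.members)
        b = rfsplus_run(small_cohort, "tc", micro_config)
        assert a.spec == b.spec
        assert a.report.dsc == b.report.dsc

    def test_artifacts_persisted(self, small_cohort, micro_config, tmp_path):
        rfsplus_run(small_cohort, "tc", micro_config, out_dir=tmp_path)
        assert (tmp_path / "ensemble_spec.json").exists()
        assert (tmp_path / "candidate_scores.csv").exists()
        assert (tmp_path / "ensemble_metrics.csv").exists()
        import pandas as pd
        table = pd.read_csv(tmp_path / "candidate_scores.csv")
        assert len(table) == 3  # one row per approach x normalization
        assert {"et", "tc", "wt"} <= set(table.columns)
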