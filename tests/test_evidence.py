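import dataclasses

import numpy as np
import pytest

from featloop import decoding, evidence, synth, tuning
from featloop.data_model import EnsembleSpec


def _results(W, ids=None):
    W = np.asarray(W, dtype=float)
    return decoding.DecoderResults(
        class_orientations=(0.0, 45.0, 90.0, 135.0),
        weights=W,
        intercepts=np.arange(4.0),  # nonzero on purpose: projections must ignore them
        feature_neuron_ids=list(range(W.shape[1])) if ids is None else ids,
        sparsity_penalty=1.0,
    )


class TestEvidenceProjection:
    def test_zero_vector_zero_evidence(self):
        res = _results(np.random.default_rng(0).normal(size=(4, 6)))
        np.testing.assert_array_equal(evidence.evidence_projection(res, np.zeros(6)), 0.0)

    def test_unit_vector_picks_weight_column(self):
        W = np.random.default_rng(1).normal(size=(4, 6))
        res = _results(W)
        x = np.zeros(6)
        x[2] = 1.0
        np.testing.assert_allclose(evidence.evidence_projection(res, x), W[:, 2])

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(2)
        W, x = rng.normal(size=(4, 8)), rng.normal(size=8)
        res = _results(W)
        want = [sum(W[c, j] * x[j] for j in range(8)) for c in range(4)]
        np.testing.assert_allclose(evidence.evidence_projection(res, x), want)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(4, 5))
        x, y = rng.normal(size=5), rng.normal(size=5)
        res = _results(W)
        lhs = evidence.evidence_projection(res, 2.0 * x + 0.5 * y)
        rhs = 2.0 * evidence.evidence_projection(res, x) + 0.5 * evidence.evidence_projection(res, y)
        np.testing.assert_allclose(lhs, rhs)

    def test_feature_mismatch(self):
        res = _results(np.zeros((4, 5)))
        with pytest.raises(ValueError, match="feature mismatch"):
            evidence.evidence_projection(res, np.zeros(4))


class TestEvidenceByOffset:
    def test_one_hot_cotuned_class(self):
        curve = evidence.evidence_by_offset([3.0, 0.0, 0.0, 0.0], ensemble_pref=0.0)
        assert curve[0.0] == 3.0 and curve[45.0] == 0.0 and curve[90.0] == 0.0

    def test_flanking_classes_averaged(self):
        # classes at 45 deg offset from a 90-deg ensemble are 45 and 135
        curve = evidence.evidence_by_offset([0.0, 2.0, 0.0, 4.0], ensemble_pref=90.0)
        assert curve[45.0] == pytest.approx(3.0)

    def test_trial_average_first(self):
        ev = np.array([[1.0, 0.0, 0.0, 0.0], [3.0, 0.0, 0.0, 0.0]])
        curve = evidence.evidence_by_offset(ev, ensemble_pref=0.0)
        assert curve[0.0] == pytest.approx(2.0)


class TestExplainingAway:
    def test_on_equals_off_index_zero(self):
        rng = np.random.default_rng(4)
        ev = rng.normal(size=(8, 4))
        vis = np.array([0.0, 45.0, 90.0, 135.0] * 2)
        table = evidence.explaining_away(ev, vis, ev, vis, ensemble_pref=0.0)
        # the OFF reference is a per-orientation mean, so the index vanishes
        # in per-orientation average when ON and OFF trials coincide
        by_vis = table.groupby("vis_orientation")
        np.testing.assert_allclose(by_vis["explaining_away_index"].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(by_vis["correct_evidence_change"].mean(), 0.0, atol=1e-12)

    def test_hand_built_flank_scaling(self):
        # ON = OFF with flanking-class evidence halved -> index = 0.5 * OFF_flank
        ev_off = np.tile([2.0, 4.0, 6.0, 8.0], (4, 1))
        vis = np.zeros(4)  # stimulus 0 deg; flanks are classes 45 and 135
        ev_on = ev_off.copy()
        ev_on[:, [1, 3]] *= 0.5
        table = evidence.explaining_away(ev_on, vis, ev_off, vis, ensemble_pref=0.0)
        off_flank = (4.0 + 8.0) / 2
        np.testing.assert_allclose(table["explaining_away_index"], 0.5 * off_flank)
        np.testing.assert_allclose(table["correct_evidence_change"], 0.0)
        assert (table["alignment"] == "aligned").all()

    def test_alignment_binning(self):
        ev = np.ones((4, 4))
        vis = np.array([0.0, 45.0, 90.0, 135.0])
        table = evidence.explaining_away(ev, vis, ev, vis, ensemble_pref=0.0)
        by_vis = table.set_index("vis_orientation")["alignment"]
        assert by_vis[0.0] == "aligned" and by_vis[90.0] == "misaligned"
        assert by_vis[45.0] == "boundary" and by_vis[135.0] == "boundary"


class TestNormalizeTuningCurves:
    def test_positive_off_curve(self):
        out = evidence.normalize_tuning_curves([[2.0, 1.0, 0.5, 1.0]], [[2.0, 1.0, 0.5, 1.0]])
        np.testing.assert_allclose(out.off[0], [1.0, 0.5, 0.25, 0.5])
        assert out.offset_applied[0] == 0.0

    def test_negative_minimum_offset_corrected(self):
        out = evidence.normalize_tuning_curves([[3.0, -1.0, 0.0, 1.0]], [[0.0, 0.0, 0.0, 0.0]])
        assert out.offset_applied[0] == 1.0
        np.testing.assert_allclose(out.off[0], [1.0, 0.0, 0.25, 0.5])
        np.testing.assert_allclose(out.on[0], [0.25, 0.25, 0.25, 0.25])

    def test_on_equals_off_peaks_at_one(self):
        R = [[0.5, 2.0, 1.0, -0.5]]
        out = evidence.normalize_tuning_curves(R, R)
        assert out.off[0].max() == pytest.approx(1.0)
        assert out.on[0].max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.on[0], out.off[0])

    def test_idempotent_on_normalized_nonnegative(self):
        R = [[1.0, 0.4, 0.2, 0.4]]
        once = evidence.normalize_tuning_curves(R, R)
        twice = evidence.normalize_tuning_curves(once.off, once.on)
        np.testing.assert_allclose(twice.off, once.off)
        assert twice.offset_applied[0] == 0.0

    def test_flat_at_zero_excluded(self):
        with pytest.warns(UserWarning, match="flat-at-zero"):
            out = evidence.normalize_tuning_curves([[0.0, 0.0, 0.0, 0.0]], [[1.0, 1.0, 1.0, 1.0]])
        assert not out.kept[0]
        assert np.isnan(out.off[0]).all()


class TestCosineSimilarity:
    def test_identical_vectors(self):
        assert evidence.cosine_similarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert evidence.cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_hand_computation(self):
        assert evidence.cosine_similarity([1.0, 2.0], [2.0, 1.0]) == pytest.approx(4.0 / 5.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        u, v = rng.normal(size=6), rng.normal(size=6)
        base = evidence.cosine_similarity(u, v)
        for a in (0.1, 7.0):
            assert evidence.cosine_similarity(a * u, v) == pytest.approx(base)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            evidence.cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestPopulationSimilarityRatio:
    def test_on_equals_off_identical_patterns_ratio_one(self):
        v = np.array([1.0, 2.0, 3.0])
        vecs = {t: v for t in (0.0, 45.0, 90.0, 135.0)}
        table = evidence.population_similarity_ratio(vecs, dict(vecs), ensemble_pref=0.0)
        np.testing.assert_allclose(table["ratio"], 1.0)

    def test_identity_reduction_with_on_equal_off(self):
        # ON == OFF: ratio reduces to cos(OFF_theta, OFF_flank)
        rng = np.random.default_rng(6)
        off = {t: rng.normal(size=5) for t in (0.0, 45.0, 90.0, 135.0)}
        table = evidence.population_similarity_ratio(off, off, ensemble_pref=0.0)
        for _, row in table.iterrows():
            t = row["vis_orientation"]
            flanks = [f for f in (0.0, 45.0, 90.0, 135.0)
                      if tuning.angular_difference(f, t) == 45.0]
            want = np.mean([evidence.cosine_similarity(off[t], off[f]) for f in flanks])
            assert row["ratio"] == pytest.approx(want)

    def test_aligned_suppression_lowers_aligned_ratio(self):
        # shared component with flanking stimuli removed from the aligned ON pattern
        base = {0.0: np.array([1.0, 1.0, 0.2, 0.2]),
                45.0: np.array([1.0, 0.2, 1.0, 0.2]),
                90.0: np.array([0.2, 0.2, 1.0, 1.0]),
                135.0: np.array([0.2, 1.0, 0.2, 1.0])}
        on = {t: v.copy() for t, v in base.items()}
        on[0.0] = np.array([0.6, 0.6, 0.0, 0.0])  # strip the flank-shared part
        table = evidence.population_similarity_ratio(on, base, ensemble_pref=0.0)
        ratios = table.set_index("alignment")["ratio"]
        assert ratios["aligned"] < ratios["misaligned"]


@pytest.fixture(scope="module")
def sst_session():
    cfg = synth.SynthConfig(n_pc=200, n_sst=20, n_pv=0, n_trials_per_orientation=20, seed=3)
    neurons, gt = synth.generate_population(cfg)
    sst_ids = [n.neuron_id for n in neurons if n.cell_type == "SST"]
    near0 = [i for i in sst_ids if tuning.angular_difference(gt.theta_pref[i], 0.0) <= 20][:5]
    neurons = [
        dataclasses.replace(n, is_targeted=True) if n.neuron_id in near0 else n
        for n in neurons
    ]
    R = synth._mean_response_matrix(gt, (0.0, 45.0, 90.0, 135.0))
    th, o = tuning.ensemble_tuning(R[near0])
    ens = EnsembleSpec(0, frozenset(near0), th, o)
    sess = synth.simulate_visual_photostim_trials(
        neurons, gt, ens, cfg,
        cell_effect=synth.flank_suppression_kernel(0.4),
        gate="aligned", n_train_per_orientation=20, n_test_per_orientation=10,
    )
    train = np.array([t.train_block for t in sess.trials])
    table = tuning.estimate_tuning(sess, visual_mask=train)
    return sess, ens, table


class TestSubgroupEvidence:
    def test_runs_per_subgroup_with_own_decoder(self, sst_session):
        sess, ens, table = sst_session
        out = evidence.subgroup_evidence(sess, ens, table, penalty=1.0)
        assert set(out) <= {"co_tuned", "anti_tuned"}
        assert len(out) >= 1
        for sub_table in out.values():
            assert {"explaining_away_index", "alignment"} <= set(sub_table.columns)

    def test_full_feature_subgroup_matches_full_run(self, sst_session):
        sess, ens, table = sst_session
        res = decoding.train_decoder(sess, penalty=1.0, seed=0)
        full = evidence.explaining_away_session(sess, res, ens)
        # a subgroup decoder trained on the identical feature set reproduces it
        clone = decoding.OrientationDecoder(
            sess, penalty=1.0, feature_neuron_ids=res.feature_neuron_ids
        ).fit(seed=0)
        again = evidence.explaining_away_session(sess, clone, ens)
        np.testing.assert_allclose(
            again["explaining_away_index"], full["explaining_away_index"], atol=1e-8
        )

    def test_undersized_subgroup_skipped(self, sst_session):
        sess, ens, table = sst_session
        starved = table.copy()
        starved["is_tuned"] = False  # no tuned cells -> both subgroups empty
        with pytest.warns(UserWarning, match="skipped"):
            out = evidence.subgroup_evidence(sess, ens, starved, penalty=1.0)
        assert out == {}


class TestEndToEndEvidenceSign:
    def test_completion_and_suppression_slopes(
        self, ensembled_population, photostim_session, visual_session
    ):
        _, _, ensembles = ensembled_population
        res = decoding.train_decoder(visual_session, penalty=1.0, seed=0)
        slopes = {}
        for ens in ensembles:
            mask = photostim_session.trial_mask(stim_ensemble=ens.ensemble_id, epoch="stim_ON")
            ev = evidence.evidence_projection(res, res.features_from(photostim_session, mask))
            curve = evidence.evidence_by_offset(ev, ens.pref_orientation)
            slopes[ens.ensemble_id] = curve[90.0] - curve[0.0]
        sizes = {e.ensemble_id: e.size for e in ensembles}
        large = [slopes[i] for i in slopes if sizes[i] >= 10]
        small = [slopes[i] for i in slopes if sizes[i] <= 2]
        # completion kernel (large): evidence falls with offset; sparse-suppression: rises
        assert np.mean(large) < 0
        assert np.mean(small) > 0
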