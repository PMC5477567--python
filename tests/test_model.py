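"""End-to-end fuser: blending, per-attribute BPAs, fusion, training."""

import numpy as np
import pytest

from fdmf import (
    EvidenceTriple,
    FDMFModel,
    MassFunction,
    ScoreDataset,
    SyntheticSpec,
    az_score,
    blend_evidence,
    combine_many,
    fit_fdmf,
    generate,
    pignistic,
)
from fdmf.model import _grid_values


def test_blend_exponent_identities(rng):
    for _ in range(100):
        g = EvidenceTriple(*rng.uniform(1e-6, 1.0, 3))
        d = EvidenceTriple(*rng.uniform(1e-6, 1.0, 3))
        assert blend_evidence(g, d, 1.0, 0.0).as_tuple() == g.as_tuple()
        assert blend_evidence(g, d, 0.0, 1.0).as_tuple() == d.as_tuple()


def test_blend_product_example():
    g = EvidenceTriple(0.9, 0.1, 0.1)
    d = EvidenceTriple(0.8, 0.2, 0.2)
    assert blend_evidence(g, d, 1.0, 1.0).as_tuple() == pytest.approx(
        (0.72, 0.02, 0.02)
    )


@pytest.fixture
def fitted(small_dataset):
    return fit_fdmf(small_dataset, grid_step=0.5)


class TestAttributeBPA:
    def test_masses_sum_to_one_over_sweep(self, fitted, rng):
        for x in rng.random(1000):
            m = fitted.attribute_bpa("a1", float(x))
            assert abs(sum(m.as_tuple()) - 1.0) <= 1e-9

    def test_dominant_evidence_at_target_center(self, fitted):
        center = max(
            cl.center for cl in fitted.membership_models["a1"].target_clusters
        )
        m = fitted.attribute_bpa("a1", center)
        assert m.m_target == max(m.as_tuple())

    def test_symmetry_at_uncertainty_centroid(self):
        """Hand-built symmetric model: equal singleton masses at v_uncertain."""
        from fdmf.discriminative import AttributePrototypes
        from fdmf.generative import ClassMembershipModel, ClusterMF

        model = FDMFModel(
            attribute_names=["a"],
            membership_models={
                "a": ClassMembershipModel(
                    [ClusterMF(0.8, 0.1)], [ClusterMF(0.2, 0.1)], 1
                )
            },
            prototypes={"a": AttributePrototypes(0.8, 0.2, 0.5)},
            alpha=1.0,
            beta=1.0,
        )
        m = model.attribute_bpa("a", 0.5)
        assert m.m_target == pytest.approx(m.m_nontarget, abs=1e-9)


class TestFusion:
    def test_single_attribute_fusion_is_attribute_bpa(self, small_dataset):
        ds = small_dataset.subset(["a1"])
        model = fit_fdmf(ds, grid_step=0.5)
        m = model.fuse_sample({"a1": 0.42})
        assert m.as_tuple() == pytest.approx(
            model.attribute_bpa("a1", 0.42).as_tuple(), abs=1e-12
        )

    def test_duplicated_attribute_sharpens_dominant_mass(self, fitted):
        m1 = fitted.attribute_bpa("a1", 0.82)
        fused = combine_many([m1, m1])
        assert m1.m_target == max(m1.as_tuple())
        assert fused.m_target >= m1.m_target

    def test_attribute_permutation_invariance(self, fitted, rng):
        for _ in range(20):
            s = {"a1": rng.random(), "a2": rng.random()}
            a = fitted.fuse_sample(s)
            swapped = FDMFModel(
                attribute_names=["a2", "a1"],
                membership_models=fitted.membership_models,
                prototypes=fitted.prototypes,
                alpha=fitted.alpha,
                beta=fitted.beta,
            )
            b = swapped.fuse_sample(s)
            assert np.abs(np.array(a.as_tuple()) - b.as_tuple()).max() < 1e-12

    def test_missing_attribute_raises(self, fitted):
        with pytest.raises(KeyError, match="a2"):
            fitted.fuse_sample({"a1": 0.5})

    def test_two_stage_fusion_equals_flat(self, rng):
        """Group-then-combine equals flat combination (associativity)."""
        ms = [MassFunction(*rng.dirichlet(np.ones(3))) for _ in range(5)]
        flat = combine_many(ms)
        staged = combine_many(
            [combine_many(ms[:3]), combine_many(ms[3:])]
        )
        assert np.abs(
            np.array(flat.as_tuple()) - staged.as_tuple()
        ).max() < 1e-12

    def test_every_emitted_mass_is_valid(self, fitted, rng):
        scores = rng.random((500, 2))
        fused = fitted.fuse_scores(scores)
        assert (fused >= -1e-12).all()
        assert np.abs(fused.sum(axis=1) - 1.0).max() <= 1e-9


class TestPredict:
    def test_pignistic_decision_values(self, fitted):
        p_t, p_n = pignistic(MassFunction(0.5, 0.3, 0.2))
        assert (p_t, p_n) == pytest.approx((0.6, 0.4))

    def test_tie_goes_to_nontarget(self):
        # total ignorance gives p = 0.5 exactly -> NonTarget by the tie rule
        from fdmf.discriminative import AttributePrototypes
        from fdmf.generative import ClassMembershipModel, ClusterMF

        model = FDMFModel(
            attribute_names=["a"],
            membership_models={
                "a": ClassMembershipModel(
                    [ClusterMF(0.8, 0.1)], [ClusterMF(0.2, 0.1)], 1
                )
            },
            prototypes={"a": AttributePrototypes(0.8, 0.2, 0.5)},
            alpha=0.0,
            beta=0.0,
        )
        label, p = model.predict_sample({"a": 0.9})
        assert p == pytest.approx(0.5)
        assert label == "NonTarget"

    def test_proba_pairs_sum_to_one(self, fitted, rng):
        p = fitted.predict_proba(rng.random((200, 2)))
        assert ((p >= 0) & (p <= 1)).all()


class TestFit:
    def test_grid_values(self):
        assert _grid_values(1.0) == [0.0, 1.0]
        assert _grid_values(0.1) == pytest.approx(np.linspace(0, 1, 11))
        with pytest.raises(ValueError):
            _grid_values(0.0)

    def test_separable_data_reaches_zero_error(self):
        scores = np.array(
            [[0.05], [0.1], [0.15], [0.85], [0.9], [0.95]] * 4
        )
        labels = np.array([0, 0, 0, 1, 1, 1] * 4)
        ds = ScoreDataset(scores, labels, np.zeros(24, dtype=int), ["a"])
        model = fit_fdmf(ds, grid_step=0.5)
        assert model.train_error == 0.0

    def test_refit_is_deterministic(self, small_dataset):
        m1 = fit_fdmf(small_dataset, grid_step=0.25, seed=3)
        m2 = fit_fdmf(small_dataset, grid_step=0.25, seed=3)
        assert (m1.alpha, m1.beta) == (m2.alpha, m2.beta)
        assert m1.to_json() == m2.to_json()

    def test_selected_exponents_beat_corner_candidates(self, small_dataset):
        """Grid minimum is no worse than (1,1), (1,0) and (0,1)."""
        model = fit_fdmf(small_dataset, grid_step=0.5)
        y = small_dataset.labels

        def balanced_error(alpha, beta):
            m = FDMFModel(
                attribute_names=model.attribute_names,
                membership_models=model.membership_models,
                prototypes=model.prototypes,
                alpha=alpha,
                beta=beta,
            )
            pred = m.predict(small_dataset.scores)
            fnr = np.mean(pred[y == 1] == 0)
            fpr = np.mean(pred[y == 0] == 1)
            return (fnr + fpr) / 2

        for corner in ((1, 1), (1, 0), (0, 1)):
            assert model.train_error <= balanced_error(*corner) + 1e-12

    def test_fusion_beats_pure_noise_attribute(self):
        """One informative + one noise attribute: fused Az above the noise Az."""
        rng = np.random.default_rng(5)
        n = 1200
        labels = (rng.random(n) < 0.3).astype(int)
        informative = np.clip(
            np.where(labels == 1, 0.7, 0.3) + rng.normal(0, 0.12, n), 1e-3, 1 - 1e-3
        )
        noise = rng.random(n)
        ds = ScoreDataset(
            np.column_stack([informative, noise]),
            labels,
            (np.arange(n) >= n // 2).astype(int),
            ["info", "noise"],
        )
        model = fit_fdmf(ds, grid_step=0.25)
        fused_az = az_score(model.predict_proba(ds.scores), labels)
        noise_az = az_score(noise, labels)
        assert fused_az > noise_az + 0.1


class TestSerialization:
    def test_round_trip_predictions_bit_exact(self, fitted, rng):
        restored = FDMFModel.from_json(fitted.to_json())
        scores = rng.random((100, 2))
        assert np.array_equal(
            fitted.predict_proba(scores), restored.predict_proba(scores)
        )

    def test_rejects_foreign_payload(self):
        with pytest.raises(ValueError):
            FDMFModel.from_json('{"format": "something-else"}')
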