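"""Contrastive losses against brute-force oracles, batch composition,
augmentations."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

import wavefusion as wf
from wavefusion import nn


def random_batch(rng, n=None):
    """Random unit embeddings with (class, subject) labels."""
    n = n or int(rng.integers(6, 17))
    Z = nn.l2_normalize(rng.standard_normal((n, 5)))
    y1 = rng.integers(0, 2, size=n)
    y2 = rng.integers(1, 4, size=n)
    return Z, y1, y2


def has_valid_anchor(y1, y2):
    for i in range(len(y1)):
        q, nr, na = wf.contrast_sets(i, y1, y2)
        if len(q) and (len(nr) + len(na)):
            return True
    return False


def sac_oracle(Z, y1, y2, tau):
    """Nested-loop transcription of the subject-aware loss definition."""
    total = 0.0
    for i in range(len(Z)):
        q, nr, na = wf.contrast_sets(i, y1, y2)
        s = np.concatenate([nr, na])
        if len(q) == 0 or len(s) == 0:
            continue
        num = np.mean([np.exp(Z[i] @ Z[j] / tau) for j in q])
        den = sum(np.exp(Z[i] @ Z[j] / tau) for j in s)
        total += -np.log(num / den)
    return total


def supcon_oracle(Z, y1, tau):
    """Nested-loop conventional supervised contrastive loss."""
    total = 0.0
    n = len(Z)
    for i in range(n):
        pos = [j for j in range(n) if j != i and y1[j] == y1[i]]
        if not pos:
            continue
        den = sum(np.exp(Z[i] @ Z[j] / tau) for j in range(n) if j != i)
        total += -np.mean(
            [np.log(np.exp(Z[i] @ Z[j] / tau) / den) for j in pos])
    return total


class TestSacLoss:
    def test_matches_oracle_on_200_seeded_batches(self):
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 200:
            Z, y1, y2 = random_batch(rng)
            if not has_valid_anchor(y1, y2):
                continue
            tau = float(rng.uniform(0.1, 1.0))
            got = wf.sac_loss(Z, y1, y2, tau)
            assert abs(got - sac_oracle(Z, y1, y2, tau)) < 1e-6
            checked += 1

    def test_supcon_matches_oracle_on_200_seeded_batches(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 200:
            Z, y1, y2 = random_batch(rng)
            tau = float(rng.uniform(0.1, 1.0))
            got = wf.supcon_loss(Z, y1, tau)
            assert abs(got - supcon_oracle(Z, y1, tau)) < 1e-6
            checked += 1

    def test_closed_form_identical_embeddings(self):
        # all views identical: each anchor contributes log|S|; with
        # |S| = 2 for all four anchors the total is 4 ln 2, independent
        # of tau
        Z = np.tile(np.eye(5)[0], (4, 1))
        y1 = np.array([0, 0, 1, 1])
        y2 = np.ones(4, dtype=int)
        for tau in (0.25, 1.0):
            assert wf.sac_loss(Z, y1, y2, tau) == pytest.approx(
                4 * np.log(2.0), abs=1e-12)

    def test_closed_form_single_negative(self, caplog):
        # orthogonal positive/negative at tau=1: each valid anchor scores
        # -(1 - 0) = -1; the positive-only third view is skipped with a
        # warning
        Z = np.stack([np.eye(3)[0], np.eye(3)[0], np.eye(3)[1]])
        y1 = np.array([0, 0, 1])
        y2 = np.ones(3, dtype=int)
        with caplog.at_level(logging.WARNING, logger="wavefusion.contrastive"):
            loss = wf.sac_loss(Z, y1, y2, tau_sac=1.0)
        assert loss == pytest.approx(-2.0, abs=1e-12)
        assert any("skipped" in r.message for r in caplog.records)

    def test_all_degenerate_batch_raises(self):
        Z = np.eye(4)
        y1 = np.zeros(4, dtype=int)   # no negatives anywhere
        y2 = np.ones(4, dtype=int)
        with pytest.raises(ValueError, match="degenerate"):
            wf.sac_loss(Z, y1, y2)
        with pytest.raises(ValueError, match="degenerate"):
            wf.supcon_loss(Z, np.arange(4))  # every class appears once

    def test_nonpositive_temperature_rejected(self):
        Z, y1, y2 = random_batch(np.random.default_rng(0), 8)
        with pytest.raises(ValueError):
            wf.sac_loss(Z, y1, y2, tau_sac=0.0)
        with pytest.raises(ValueError):
            wf.supcon_loss(Z, y1, tau_sac=-1.0)

    @pytest.mark.parametrize("loss_name", ["sac", "supcon"])
    def test_gradient_matches_finite_differences(self, loss_name):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((8, 4))  # not normalized: pure fn of Z
        y1 = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        y2 = np.array([1, 1, 2, 2, 1, 1, 2, 2])
        tau = 0.5
        if loss_name == "sac":
            _, grad = wf.sac_loss(Z, y1, y2, tau, return_grad=True)
            f = lambda: wf.sac_loss(Z, y1, y2, tau)
        else:
            _, grad = wf.supcon_loss(Z, y1, tau, return_grad=True)
            f = lambda: wf.supcon_loss(Z, y1, tau)
        eps = 1e-6
        flat = Z.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = f()
            flat[i] = orig - eps
            lo = f()
            flat[i] = orig
            fd = (hi - lo) / (2 * eps)
            assert abs(grad.reshape(-1)[i] - fd) < 1e-4


class TestContrastSets:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_property_partition_predicates(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        y1 = rng.integers(0, 2, size=n)
        y2 = rng.integers(1, 5, size=n)
        i = int(rng.integers(0, n))
        q, nr, na = wf.contrast_sets(i, y1, y2)
        groups = [set(q), set(nr), set(na)]
        # pairwise disjoint, anchor excluded
        assert sum(len(g) for g in groups) == len(set().union(*groups))
        assert all(i not in g for g in groups)
        for j in range(n):
            if j == i:
                continue
            in_q = y1[j] == y1[i] and y2[j] == y2[i]
            in_nr = y1[j] != y1[i] and y2[j] != y2[i]
            in_na = y1[j] != y1[i] and y2[j] == y2[i]
            assert (j in groups[0]) == in_q
            assert (j in groups[1]) == in_nr
            assert (j in groups[2]) == in_na
            if y1[j] == y1[i] and y2[j] != y2[i]:
                assert all(j not in g for g in groups)


class TestComposition:
    def test_role_counts_sum_and_exact_case(self):
        spec = wf.BatchCompositionSpec(0.5, 0.0, 0.5, 500)
        assert spec.role_counts() == {"positive": 250, "inter_negative": 0,
                                      "intra_negative": 250}
        for name, fracs in wf.SCHEME_PRESETS.items():
            if fracs is None:
                continue
            counts = wf.BatchCompositionSpec.from_preset(name).role_counts()
            assert sum(counts.values()) == 500

    def test_strict_mode_rejects_fractional_counts(self):
        with pytest.raises(ValueError, match="non-integer"):
            wf.BatchCompositionSpec(0.125, 0.375, 0.5, 500, strict=True)
        # exact fractions pass
        wf.BatchCompositionSpec(0.25, 0.25, 0.5, 500, strict=True)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            wf.BatchCompositionSpec(0.5, 0.5, 0.5, 10)
        with pytest.raises(ValueError, match="batch_size"):
            wf.BatchCompositionSpec(0.5, 0.0, 0.5, 1)
        with pytest.raises(KeyError):
            wf.BatchCompositionSpec.from_preset("supcon")

    def test_compose_batch_respects_role_predicates(self, rng):
        from tests_helpers import big_labeled_dataset
        ds = big_labeled_dataset()
        index = wf.DatasetIndex(ds)
        key = (2, 1)
        for name, fracs in wf.SCHEME_PRESETS.items():
            if fracs is None:
                continue
            spec = wf.BatchCompositionSpec(*fracs, batch_size=40)
            idx = wf.compose_batch(index, key, spec, rng)
            counts = spec.role_counts()
            assert len(idx) == 40
            assert len(np.unique(idx[:counts["positive"]])) == \
                counts["positive"]
            got_pos = idx[:counts["positive"]]
            assert np.all(ds.y2[got_pos] == 2)
            assert np.all(ds.y1[got_pos] == 1)
            rest = idx[counts["positive"]:]
            assert np.all(ds.y1[rest] == 0)
            n_intra = int((ds.y2[rest] == 2).sum())
            n_inter = int((ds.y2[rest] != 2).sum())
            assert n_intra == counts["intra_negative"]
            assert n_inter == counts["inter_negative"]

    def test_compose_batch_deficit_error_names_role(self, rng):
        from tests_helpers import big_labeled_dataset
        ds = big_labeled_dataset(per_class=5)
        index = wf.DatasetIndex(ds)
        spec = wf.BatchCompositionSpec(0.5, 0.0, 0.5, 20)
        with pytest.raises(ValueError, match="positive"):
            wf.compose_batch(index, (1, 0), spec, rng)

    def test_dataset_index_pools(self):
        from tests_helpers import big_labeled_dataset
        ds = big_labeled_dataset()
        index = wf.DatasetIndex(ds)
        assert index.subjects == [1, 2, 3]
        pool = index.pool(1, 0)
        assert np.all(ds.y1[pool] == 0) and np.all(ds.y2[pool] == 1)
        inter = index.inter_pool(1, 0)
        assert np.all(ds.y1[inter] == 0) and np.all(ds.y2[inter] != 1)


class TestAugment:
    def test_identity_config_copies(self, rng):
        cfg = wf.AugmentConfig(0.0, 0.0, 0.0)
        x = rng.random((3, 5, 4))
        out = wf.augment(x, cfg, rng)
        assert np.array_equal(out, x)
        assert out is not x

    def test_dropout_fraction(self):
        cfg = wf.AugmentConfig(0.0, 0.0, 0.4)
        rng = np.random.default_rng(0)
        x = np.ones((50, 50, 4))
        out = wf.augment(x, cfg, rng)
        assert abs((out == 0).mean() - 0.4) < 0.02

    def test_pink_noise_spectral_profile(self):
        rng = np.random.default_rng(0)
        noise = wf.contrastive.pink_noise_tensor((4000, 39, 11), rng)
        var = noise.var(axis=(0, 2))
        assert var[0] > 5 * var[-1]           # 1/f decline across bins
        assert np.mean(var) == pytest.approx(1.0, rel=0.05)  # unit mean power

    def test_config_validation(self):
        with pytest.raises(ValueError):
            wf.AugmentConfig(input_dropout_rate=1.0)
        with pytest.raises(ValueError):
            wf.AugmentConfig(pink_noise_scale=-0.1)

    def test_build_view_batch_structure(self, toy_dataset, rng):
        idx = np.array([0, 3, 7])
        vb = wf.build_view_batch(toy_dataset, idx, wf.AugmentConfig(), rng)
        assert len(vb) == 6
        assert np.array_equal(vb.provenance, np.repeat(idx, 2))
        assert np.array_equal(vb.y1, np.repeat(toy_dataset.y1[idx], 2))
        assert not np.array_equal(vb.views[0], vb.views[1])  # two draws

    def test_view_batch_validation(self, rng):
        X = rng.random((4, 1, 2, 2))
        with pytest.raises(ValueError, match="share their labels"):
            wf.ViewBatch(X, np.array([0, 1, 0, 0]), np.ones(4, dtype=int),
                         np.arange(4))
        with pytest.raises(ValueError, match="2N views"):
            wf.ViewBatch(X[:3], np.zeros(3, dtype=int),
                         np.ones(3, dtype=int), np.arange(3))
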