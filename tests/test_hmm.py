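import numpy as np
import pytest

from pbwtimpute.hmm import (
    HmmParameters,
    PosteriorSet,
    forward_backward,
    impute_target_untyped,
    interpolate_dosage,
    lazy_impute_target,
    rho,
    to_diploid,
)
from pbwtimpute.imp5 import Imp5Store
from pbwtimpute.panels import make_marker_table

import _oracles as oracle


class TestRho:
    def test_zero_gap_is_floored(self):
        p = HmmParameters()
        assert rho(0.0, 8, p) == p.min_rho

    def test_closed_form_value(self):
        # 4 * 20000 * (0.001 cM / 100) / 8 = 0.1
        assert rho(0.001, 8, HmmParameters(ne=20000)) == pytest.approx(
            1 - np.exp(-0.1), rel=1e-12
        )

    def test_monotone_in_gap_and_states(self):
        p = HmmParameters()
        gaps = np.linspace(0, 0.1, 20)
        r = rho(gaps, 8, p)
        assert np.all(np.diff(r) >= 0)
        assert rho(0.01, 100, p) < rho(0.01, 10, p)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HmmParameters(min_rho=0)
        with pytest.raises(ValueError):
            HmmParameters(e_match=0.99, e_mismatch=0.0001)


class TestForwardBackward:
    def test_single_state_posterior_is_one(self, rng):
        t = rng.integers(0, 2, 12).astype(np.uint8)
        h = rng.integers(0, 2, (1, 12)).astype(np.uint8)
        post = forward_backward(t, h, np.arange(12) * 0.01)
        assert np.allclose(post, 1.0)

    def test_identical_states_split_mass_evenly(self, rng):
        t = rng.integers(0, 2, 10).astype(np.uint8)
        h = np.vstack([t, t])
        post = forward_backward(t, h, np.arange(10) * 0.01)
        assert np.allclose(post, 0.5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(10):
            s, m = rng.integers(1, 16), rng.integers(2, 50)
            h = rng.integers(0, 2, (s, m)).astype(np.uint8)
            t = rng.integers(0, 2, m).astype(np.uint8)
            post = forward_backward(t, h, np.sort(rng.random(m)))
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_dense_unscaled_oracle(self, rng):
        worst = 0.0
        for _ in range(30):
            s, m = rng.integers(1, 16), rng.integers(2, 50)
            h = rng.integers(0, 2, (s, m)).astype(np.uint8)
            t = rng.integers(0, 2, m).astype(np.uint8)
            cm = np.sort(rng.random(m))
            got = forward_backward(t, h, cm)
            exp = oracle.dense_forward_backward(t, h, cm)
            worst = max(worst, np.abs(got - exp).max())
        assert worst < 1e-10

    def test_empty_state_list_is_error(self):
        with pytest.raises(ValueError):
            forward_backward(
                np.array([0, 1], dtype=np.uint8),
                np.empty((0, 2), dtype=np.uint8),
                np.array([0.0, 0.01]),
            )


class TestInterpolation:
    def test_endpoint_uses_left_flank_only(self):
        d = interpolate_dosage({1: 0.7, 2: 0.3}, {1: 0.1, 2: 0.9}, 0.0, {2})
        assert d == pytest.approx(0.3)

    def test_all_carriers_gives_total_mass(self):
        d = interpolate_dosage({1: 0.6, 2: 0.4}, {1: 0.5, 2: 0.5}, 0.37, {1, 2})
        assert d == pytest.approx(1.0)

    def test_half_weight_hand_value(self):
        d = interpolate_dosage({1: 1.0}, {2: 1.0}, 0.5, {2})
        assert d == pytest.approx(0.5)

    def test_empty_carriers_is_zero(self):
        assert interpolate_dosage({1: 1.0}, {1: 1.0}, 0.5, set()) == 0.0


class TestToDiploid:
    @pytest.mark.parametrize(
        "p1,p2,ds,gp",
        [
            (0.0, 0.0, 0.0, (1, 0, 0)),
            (1.0, 1.0, 2.0, (0, 0, 1)),
            (0.5, 0.5, 1.0, (0.25, 0.5, 0.25)),
        ],
    )
    def test_values(self, p1, p2, ds, gp):
        got_ds, got_gp = to_diploid(p1, p2)
        assert got_ds == pytest.approx(ds)
        assert got_gp == pytest.approx(np.array(gp))

    def test_gp_sums_to_one(self, rng):
        p1, p2 = rng.random(50), rng.random(50)
        _, gp = to_diploid(p1, p2)
        assert np.allclose(gp.sum(axis=-1), 1.0)


def _random_instance(rng, n=24, t=12, n_u=40):
    """Small reference + target with typed/untyped split and a store."""
    region = 100_000
    pos_all = np.sort(rng.choice(np.arange(1, region), t + n_u, replace=False))
    typed_idx = np.sort(rng.choice(t + n_u, t, replace=False))
    untyped_idx = np.setdiff1d(np.arange(t + n_u), typed_idx)
    ref = rng.integers(0, 2, (n, t + n_u)).astype(np.uint8)
    target = rng.integers(0, 2, t + n_u).astype(np.uint8)
    cm_all = (pos_all - pos_all[0]) * 1e-6
    u_markers = make_marker_table(
        "1", pos_all[untyped_idx], ["A"] * n_u, ["C"] * n_u, cm_all[untyped_idx]
    )
    from pbwtimpute.imp5 import encode_marker

    store = Imp5Store(
        u_markers, [encode_marker(ref[:, u]) for u in untyped_idx], n
    )
    return ref, target, typed_idx, untyped_idx, pos_all, cm_all, store


class TestUntypedImputation:
    def test_vectorized_equals_streamed(self, rng):
        for _ in range(10):
            ref, target, typed_idx, untyped_idx, pos, cm, store = _random_instance(rng)
            post = forward_backward(
                target[typed_idx], ref[:, typed_idx], cm[typed_idx]
            )
            pset = PosteriorSet(
                post, np.arange(ref.shape[0]), pos[typed_idx], cm[typed_idx]
            )
            stream = np.fromiter(
                lazy_impute_target(
                    pset, store.records, store.positions,
                    store.markers["cm"].to_numpy(), lazy=True
                ),
                dtype=float,
            )
            vec = impute_target_untyped(pset, store)
            assert np.allclose(stream, vec, rtol=1e-12, atol=1e-14)

    def test_lazy_fast_path_is_bit_identical(self, rng):
        ref, target, typed_idx, untyped_idx, pos, cm, store = _random_instance(
            rng, n=600, t=8, n_u=30
        )
        # make most untyped markers rare (1-2 carriers) so they are
        # stored sparse and exercise the lazy short-circuit
        from pbwtimpute.imp5 import TAG_SPARSE, encode_marker

        for j, u in enumerate(untyped_idx[:20]):
            col = np.zeros(600, dtype=np.uint8)
            col[rng.choice(600, rng.integers(1, 3), replace=False)] = 1
            store.records[j] = encode_marker(col)
        assert any(r.tag == TAG_SPARSE for r in store.records)
        # restrict states so sparse-record carriers often miss the list
        states = np.arange(40)
        post = forward_backward(target[typed_idx], ref[states][:, typed_idx], cm[typed_idx])
        pset = PosteriorSet(post, states, pos[typed_idx], cm[typed_idx])
        args = (store.records, store.positions, store.markers["cm"].to_numpy())
        on = list(lazy_impute_target(pset, *args, lazy=True))
        off = list(lazy_impute_target(pset, *args, lazy=False))
        assert on == off  # bit-identical, not just close

    def test_out_of_order_stream_is_error(self, rng):
        ref, target, typed_idx, untyped_idx, pos, cm, store = _random_instance(rng)
        post = forward_backward(target[typed_idx], ref[:, typed_idx], cm[typed_idx])
        pset = PosteriorSet(post, np.arange(ref.shape[0]), pos[typed_idx], cm[typed_idx])
        bad_pos = store.positions.copy()
        bad_pos[-1] = 0
        with pytest.raises(ValueError):
            list(
                lazy_impute_target(
                    pset, store.records, bad_pos, store.markers["cm"].to_numpy()
                )
            )

    def test_sparsification_drops_bounded_mass(self, rng):
        """Dosage difference between sparsified and exact interpolation
        is bounded by the posterior mass dropped at the flanks."""
        for _ in range(5):
            ref, target, typed_idx, untyped_idx, pos, cm, store = _random_instance(rng)
            post = forward_backward(target[typed_idx], ref[:, typed_idx], cm[typed_idx])
            common = dict(states=np.arange(ref.shape[0]), typed_pos=pos[typed_idx], typed_cm=cm[typed_idx])
            d_sparse = impute_target_untyped(
                PosteriorSet(post, sparsify=True, **common), store
            )
            d_exact = impute_target_untyped(
                PosteriorSet(post, sparsify=False, **common), store
            )
            keep = PosteriorSet(post, sparsify=True, **common).keep_mask()
            dropped = 1.0 - (post * keep).sum(axis=1)
            iv = np.searchsorted(pos[typed_idx], store.positions)
            lo = np.clip(iv - 1, 0, len(typed_idx) - 1)
            hi = np.clip(iv, 0, len(typed_idx) - 1)
            bound = dropped[lo] + dropped[hi] + 1e-12
            assert np.all(np.abs(d_sparse - d_exact) <= 2 * bound)


def test_full_pipeline_matches_dense_oracle(rng):
    """With every state selected and sparsification off, selection +
    forward-backward + interpolation reproduces an independently coded
    dense Li & Stephens imputation at every marker."""
    from pbwtimpute.engine import impute_panels
    from pbwtimpute.selection import SelectionConfig

    for _ in range(5):
        ref, target, typed_idx, untyped_idx, pos, cm, store = _random_instance(
            rng, n=10, t=10, n_u=25
        )
        t_markers = make_marker_table(
            "1", pos[typed_idx], ["A"] * len(typed_idx), ["C"] * len(typed_idx),
            cm[typed_idx],
        )
        res = impute_panels(
            ref[:, typed_idx],
            t_markers,
            store,
            target[typed_idx][None, :],
            sel_cfg=SelectionConfig(L=2 * ref.shape[0], interval_cm=1e-6),
            sparsify=False,
        )
        expected = oracle.dense_impute(target[typed_idx], ref, typed_idx, cm)
        assert np.allclose(res.dosage_untyped[:, 0], expected[untyped_idx], atol=1e-8)
        assert np.allclose(res.dosage_typed[:, 0], expected[typed_idx], atol=1e-8)
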