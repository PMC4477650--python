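"""3-state Gaussian HMM: EM fitting, Viterbi decoding, state mapping."""

import itertools

import numpy as np
import pytest

from telofret.fret import FretTrace
from telofret.hmm import (
    GaussianHMM,
    fit_hmm,
    hmm_from_json,
    hmm_to_json,
    idealize,
    map_states,
)


def _fret(e, trace_id="t"):
    return FretTrace(trace_id, np.asarray(e, float), 0.1, gamma_hat=1.0)


def _noisy_levels(rng, means, sd, n_segments=60, seg_len=15):
    states = rng.integers(0, len(means), n_segments)
    x = np.concatenate(
        [rng.normal(means[s], sd, seg_len) for s in states]
    )
    return x


# --------------------------------------------------------------------- EM


def test_noiseless_three_level_trace_recovers_exact_means():
    """Zero-noise segments at 0.0/0.25/0.75 are recovered to 1e-6."""
    x = np.concatenate(
        [np.full(60, 0.0), np.full(50, 0.25), np.full(70, 0.75), np.full(40, 0.25)]
    )
    model = GaussianHMM().fit(x)
    assert np.allclose(model.means_, [0.0, 0.25, 0.75], atol=1e-6)


def test_strict_degenerate_contract_restarts_then_errors():
    """Under the restart contract, variance collapse below 1e-6 aborts
    after three re-seeded restarts."""
    x = np.concatenate([np.full(60, 0.0), np.full(50, 0.25), np.full(70, 0.75)])
    with pytest.raises(RuntimeError, match="collapsed"):
        GaussianHMM(on_degenerate="restart", random_state=0).fit(x)


def test_em_log_likelihood_is_monotone(wt_u36_run):
    """The recorded EM log-likelihood never decreases, on random noisy
    data and on the full simulated-dataset fit."""
    rng = np.random.default_rng(7)
    x = _noisy_levels(rng, [0.0, 0.25, 0.75], 0.08)
    model = GaussianHMM(random_state=0).fit(x)
    histories = [model.history_, wt_u36_run.model.history_]
    for h in histories:
        diffs = np.diff(h)
        assert np.all(diffs >= -1e-8 * np.abs(h[:-1]))


def test_init_mean_permutation_gives_same_sorted_model():
    rng = np.random.default_rng(3)
    x = _noisy_levels(rng, [0.0, 0.25, 0.75], 0.05)
    a = GaussianHMM(init_means=(0.0, 0.25, 0.75)).fit(x)
    b = GaussianHMM(init_means=(0.75, 0.0, 0.25)).fit(x)
    assert np.allclose(a.means_, b.means_, atol=1e-6)
    assert np.allclose(a.transmat_, b.transmat_, atol=1e-6)


def test_fitted_states_are_sorted_by_mean(wt_u36_run):
    assert np.all(np.diff(wt_u36_run.model.means_) > 0)
    assert np.allclose(wt_u36_run.model.transmat_.sum(axis=1), 1.0, atol=1e-9)
    assert wt_u36_run.model.startprob_.sum() == pytest.approx(1.0, abs=1e-9)


def test_distinct_init_means_required():
    with pytest.raises(ValueError):
        GaussianHMM(init_means=(0.1, 0.1, 0.5)).fit(np.zeros(10))


# ----------------------------------------------------------------- Viterbi


def _brute_force_path(model, x):
    """Exhaustive most-probable path; ties resolved lexicographically
    (matching the lower-state-index rule)."""
    k = len(model.means_)
    best, best_ll = None, -np.inf
    for path in itertools.product(range(k), repeat=len(x)):
        ll = model.path_log_likelihood(x, np.asarray(path))
        if ll > best_ll + 1e-12:
            best, best_ll = path, ll
    return np.asarray(best)


def test_viterbi_matches_brute_force_enumeration():
    """Viterbi equals exhaustive argmax over all 3^T paths for short traces."""
    rng = np.random.default_rng(11)
    x_train = _noisy_levels(rng, [0.0, 0.25, 0.75], 0.08)
    model = GaussianHMM().fit(x_train)
    for length in (1, 3, 6, 8):
        for _ in range(3):
            x = rng.uniform(-0.1, 0.9, length)
            np.testing.assert_array_equal(
                model.predict(x), _brute_force_path(model, x)
            )


def test_viterbi_path_likelihood_bounded_by_total_likelihood(wt_u36_run):
    model = wt_u36_run.model
    x = wt_u36_run.frets[0].efficiencies[:200]
    path = model.predict(x)
    assert model.path_log_likelihood(x, path) <= model.score(x) + 1e-9


def test_constant_trace_idealizes_to_a_constant_path(wt_u36_run):
    model = wt_u36_run.model
    x = np.full(50, model.means_[2])
    assert np.all(model.predict(x) == 2)


def test_idealize_rejects_empty_trace(wt_u36_run):
    empty = FretTrace("e", np.empty(0), 0.1, gamma_hat=1.0)
    with pytest.raises(ValueError):
        idealize(wt_u36_run.model, empty)


def test_frame_recovery_against_simulator_truth(wt_u36_traces, wt_u36_run):
    """Idealization recovers >= 95% of truth labels away from transitions."""
    from telofret.fret import compute_fret

    model = wt_u36_run.model
    ok = total = 0
    for tr in wt_u36_traces[:60]:
        truth = tr.truth.state_path
        # HMM state order is (unbound, alternative, docked) by mean for U36;
        # truth codes are (unbound=0, docked=1, alternative=2).
        remap = {0: 0, 1: 2, 2: 1}
        expected = np.asarray([remap[int(s)] for s in truth])
        path = model.predict(compute_fret(tr, tr.truth.gamma_true).efficiencies)
        # exclude frames within 1 of a truth transition
        change = np.flatnonzero(np.diff(expected) != 0)
        near = np.zeros(len(expected), dtype=bool)
        for c in change:
            near[max(0, c) : c + 2] = True
        ok += int(np.sum((path == expected) & ~near))
        total += int(np.sum(~near))
    assert ok / total >= 0.95


# ------------------------------------------------------------ state naming


def test_state_mapping_for_both_labelling_schemes(wt_u36_run, wt_u63_run):
    m36 = map_states(wt_u36_run.model, "u36")
    assert m36 == {0: "unbound", 1: "alternative", 2: "docked"}
    m63 = map_states(wt_u63_run.model, "u63")
    assert m63 == {0: "unbound", 1: "docked", 2: "alternative"}


def test_state_mapping_rejects_ambiguous_means():
    model = GaussianHMM()
    model.means_ = np.array([0.0, 0.45, 0.50])
    model.sds_ = np.array([0.05, 0.05, 0.05])
    with pytest.raises(ValueError, match="ambiguous"):
        map_states(model, "u36")


# ------------------------------------------------- independent cross-check


def test_forward_and_viterbi_agree_with_hmmlearn(wt_u36_run):
    """Plugging the fitted parameters into an independent HMM library
    reproduces the forward log-likelihood and the Viterbi path."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    model = wt_u36_run.model
    ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
    ref.startprob_ = model.startprob_.copy()
    ref.transmat_ = model.transmat_.copy()
    ref.means_ = model.means_.reshape(-1, 1).copy()
    ref.covars_ = (model.sds_**2).reshape(-1, 1).copy()
    x = wt_u36_run.frets[0].efficiencies
    assert model.score(x) == pytest.approx(ref.score(x.reshape(-1, 1)), abs=1e-6)
    np.testing.assert_array_equal(
        model.predict(x), ref.predict(x.reshape(-1, 1))
    )


def test_model_json_round_trip(wt_u36_run):
    doc = hmm_to_json(wt_u36_run.model)
    back = hmm_from_json(doc)
    assert np.allclose(back.means_, wt_u36_run.model.means_)
    assert np.allclose(back.transmat_, wt_u36_run.model.transmat_)


def test_sklearn_param_interface():
    model = GaussianHMM(tol=1e-5)
    assert model.get_params()["tol"] == 1e-5
    model.set_params(max_iter=42)
    assert model.max_iter == 42
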