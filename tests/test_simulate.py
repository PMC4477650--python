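"""Synthetic-data generator: kinetic scheme, determinism, gel walks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import telofret as tf
from telofret.simulate import (
    STATE_ALTERNATIVE,
    STATE_DOCKED,
    STATE_UNBOUND,
    ExtensionSimParams,
    simulate_binding_trace,
    simulate_dataset,
    simulate_gel_lane,
)

WT = tf.KINETIC_PRESETS["wt-u36"]


def test_presets_use_100ms_frames_and_resolvable_states():
    for model in tf.KINETIC_PRESETS.values():
        assert model.frame_s == pytest.approx(0.1)
        assert model.resolvable()


def test_invalid_model_names_violated_invariant():
    bad = dataclasses.replace(WT, k_da=-1.0)
    with pytest.raises(ValueError, match="k_da"):
        bad.validate()
    with pytest.raises(ValueError, match="gamma_true"):
        dataclasses.replace(WT, gamma_true=0.0).validate()


def test_zero_rate_model_never_leaves_docked():
    model = dataclasses.replace(
        WT, k_da=0.0, k_ad=0.0, k_off=0.0, bleach_rate_acceptor=0.0,
        bleach_rate_donor=0.0, noise_floor=1.0, noise_shot=0.0,
    )
    tr = simulate_binding_trace(model, 400, seed=3, start_state=STATE_DOCKED)
    path = tr.truth.state_path
    bound = path[path != STATE_UNBOUND]
    assert len(bound) > 0 and np.all(bound == STATE_DOCKED)
    assert len([d for d in tr.truth.dwells]) == 1  # zero transitions
    # every bound frame emits near the docked channel means
    s, e = tr.truth.event
    docked_frames = slice(s + 1, e - 1)  # skip onset blur
    from telofret.fret import compute_fret

    eff = compute_fret(tr, model.gamma_true).efficiencies[docked_frames]
    assert abs(np.median(eff) - 0.75) < 0.01


def test_identical_seeds_give_bitwise_identical_datasets():
    a = simulate_dataset(WT, 5, 200, seed=42)
    b = simulate_dataset(WT, 5, 200, seed=42)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.donor, tb.donor)
        np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
        np.testing.assert_array_equal(ta.truth.state_path, tb.truth.state_path)


def test_empty_or_invalid_requests_rejected():
    with pytest.raises(ValueError):
        simulate_dataset(WT, 0, 100, seed=0)
    with pytest.raises(ValueError):
        simulate_binding_trace(WT, 0, seed=0)


def test_dataset_scale_matches_analysis_floor(wt_u36_traces):
    """>= 150 events pool well over 100 dwell measurements."""
    dwells = [d for tr in wt_u36_traces for d in tr.truth.dwells if not d.censored]
    assert len(dwells) >= 100


def test_truth_docked_dwells_are_exponential():
    """Monte-Carlo dwell mean matches 1/k_da within 5% and the dwell
    distribution passes a KS test against Exp(1/k_da) at alpha = 0.01.

    FRET termination is disabled here: with a competing termination rate
    k_term, fully observed dwells are distributed Exp(k + k_term), not
    Exp(k), so the generator's dwell machinery is validated on its own.
    """
    model = dataclasses.replace(
        WT, k_off=0.0, bleach_rate_acceptor=0.0, bleach_rate_donor=0.0,
        k_on_frame=0.05,
    )
    traces = simulate_dataset(model, 60, 2000, seed=8)
    durations = np.asarray(
        [d.duration_s for tr in traces for d in tr.truth.dwells
         if d.state == STATE_DOCKED and not d.censored]
    )
    tau = 1.0 / WT.k_da
    assert len(durations) >= 1000
    assert abs(durations.mean() - tau) / tau < 0.05
    assert stats.kstest(durations, "expon", args=(0.0, tau)).pvalue > 0.01


def test_summed_intensity_ratio_recovers_gamma_true(wt_u36_traces):
    """Simulator self-consistency: pre-binding over bound summed intensity
    approximates gamma_true trace by trace."""
    ratios = []
    for tr in wt_u36_traces:
        if tr.truth.event is None:
            continue
        s, e = tr.truth.event
        if s < 30 or e - s < 30:
            continue
        total = tr.donor + tr.acceptor
        ratios.append(total[5 : s - 2].mean() / total[s + 2 : e - 2].mean())
    assert len(ratios) > 50
    assert np.median(ratios) == pytest.approx(WT.gamma_true, abs=0.02)


def test_donor_bleach_truncates_trace():
    model = dataclasses.replace(WT, bleach_rate_donor=0.5)  # ~2 s lifetime
    tr = simulate_binding_trace(model, 2000, seed=5)
    assert len(tr) < 2000


# --------------------------------------------------------------- gel lanes


def _params(**kw):
    base = dict(
        name="t", extension_probability=(0.5,) * 9, translocation_success=0.5,
        n_molecules=2000, recovery_control_true=1.0,
    )
    base.update(kw)
    return ExtensionSimParams(**base)


def test_gel_molecule_count_is_conserved():
    primer = tf.PERMUTANT_PRIMERS[2]  # (GGGGTT)3
    lane = simulate_gel_lane(_params(), primer, seed=9)
    assert sum(c for _, c in lane.truth_counts) == 2000


def test_certain_extension_without_translocation_stalls_at_first_repeat():
    primer = tf.PERMUTANT_PRIMERS[2]
    lane = simulate_gel_lane(
        _params(extension_probability=(1.0,) * 9, translocation_success=0.0),
        primer, seed=0, recovery_factor=1.0,
    )
    assert [l for l, _ in lane.bands] == [lane.first_repeat_length]


def test_zero_extension_probability_leaves_no_labeled_bands():
    primer = tf.PERMUTANT_PRIMERS[2]
    lane = simulate_gel_lane(
        _params(extension_probability=(0.0,) * 9), primer, seed=0
    )
    assert lane.bands == ()  # all molecules at +0, which carries no label
    from telofret.gel import compute_nap

    assert compute_nap(lane) == 0.0


def test_zero_duplex_potential_primer_cannot_initiate():
    with pytest.raises(ValueError):
        simulate_gel_lane(_params(), tf.PrimerSpec("polyA", "AAAAAAAA"), seed=0)


def test_extension_params_validation():
    with pytest.raises(ValueError):
        _params(n_molecules=0).validate()
    with pytest.raises(ValueError):
        _params(translocation_success=1.5).validate()
    with pytest.raises(ValueError):
        _params(extension_probability=(0.5,) * 3).validate()
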