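"""Gamma estimation, FRET efficiency, event detection, histograms."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import telofret as tf
from telofret.fret import (
    FRET_RANGE,
    FretTrace,
    build_histogram,
    compute_fret,
    detect_events,
    estimate_gamma,
    fret_ratio_form,
    fret_reciprocal_form,
    process_trace,
)
from telofret.simulate import Trace


def _trace(donor, acceptor, frame_s=0.1):
    return Trace("t", np.asarray(donor, float), np.asarray(acceptor, float), frame_s)


# ------------------------------------------------------------------ gamma


def test_gamma_from_summed_intensities():
    """Pre-binding sums of 1000 against bound sums of 800 give 1.25."""
    donor = np.concatenate([np.full(20, 1000.0), np.full(40, 300.0)])
    acceptor = np.concatenate([np.zeros(20), np.full(40, 500.0)])
    est = estimate_gamma(_trace(donor, acceptor), event=(20, 60))
    assert est.value == pytest.approx(1.25)
    assert not est.fallback


def test_intensity_conserving_trace_has_unit_gamma():
    donor = np.concatenate([np.full(20, 600.0), np.full(40, 100.0)])
    acceptor = np.concatenate([np.zeros(20), np.full(40, 500.0)])
    est = estimate_gamma(_trace(donor, acceptor), event=(20, 60))
    assert est.value == pytest.approx(1.0)


def test_gamma_falls_back_when_prebinding_window_missing():
    donor = np.concatenate([np.full(5, 1000.0), np.full(40, 300.0)])
    acceptor = np.concatenate([np.zeros(5), np.full(40, 500.0)])
    with pytest.warns(UserWarning, match="pre-binding"):
        est = estimate_gamma(_trace(donor, acceptor), event=(5, 45))
    assert est.value == 1.0 and est.fallback


def test_gamma_round_trip_on_simulated_traces(wt_u36_traces):
    """Median per-trace gamma over >= 100 traces recovers gamma_true 1.2."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frets = [process_trace(tr) for tr in wt_u36_traces[:150]]
    gammas = [f.gamma_hat for f in frets if f.events]
    assert len(gammas) >= 100
    assert 1.15 <= np.median(gammas) <= 1.25


# ------------------------------------------------------------- efficiency


def test_fret_formula_hand_values():
    tr = _trace([300.0, 100.0, 0.0], [100.0, 100.0, 400.0])
    e = compute_fret(tr, gamma_hat=1.25).efficiencies
    assert e[0] == pytest.approx(1.0 / (1.0 + 1.25 * 3.0))  # 0.2105...
    e1 = compute_fret(tr, gamma_hat=1.0).efficiencies
    assert e1[1] == pytest.approx(0.5)  # I_D = I_A, gamma = 1
    assert e1[2] == pytest.approx(1.0)  # I_D = 0 limit


@given(
    st.floats(1e-3, 1e6), st.floats(1e-3, 1e6), st.floats(0.1, 10.0)
)
def test_ratio_and_reciprocal_forms_are_identical(donor, acceptor, gamma):
    """The two printed formulas agree to 1e-12 on finite intensities."""
    a = fret_ratio_form(np.array([donor]), np.array([acceptor]), gamma)
    b = fret_reciprocal_form(np.array([donor]), np.array([acceptor]), gamma)
    assert abs(a[0] - b[0]) < 1e-12


@given(st.floats(0.5, 2.0))
def test_efficiency_decreases_with_donor_intensity(gamma):
    donor = np.linspace(1.0, 1000.0, 50)
    e = fret_ratio_form(donor, np.full(50, 300.0), gamma)
    assert np.all(np.diff(e) < 0)


def test_nonpositive_acceptor_is_floored_and_clamped():
    tr = _trace([1000.0, 1000.0], [0.0, -50.0])
    ft = compute_fret(tr, 1.0)
    assert np.all(np.isfinite(ft.efficiencies))
    assert np.all(ft.efficiencies >= FRET_RANGE[0])
    assert np.all(ft.efficiencies <= FRET_RANGE[1])


# ----------------------------------------------------------------- events


def test_no_events_in_flat_zero_trace():
    ft = FretTrace("t", np.zeros(100), 0.1, gamma_hat=1.0)
    assert detect_events(ft) == []


def test_noiseless_step_yields_one_event_with_exact_bounds():
    e = np.zeros(300)
    e[50:150] = 0.75
    assert detect_events(e) == [(50, 150)]


def test_short_blips_below_min_frames_are_ignored():
    e = np.zeros(100)
    e[10:12] = 0.75  # 2 frames < min_frames = 3
    assert detect_events(e, min_frames=3) == []


def test_event_recovery_against_simulator_truth(wt_u36_traces):
    """>= 95% of truth binding events are recovered with boundary error
    <= 2 frames."""
    recovered = total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr in wt_u36_traces:
            truth = tr.truth.event
            if truth is None or truth[1] - truth[0] < 3:
                continue
            total += 1
            ft = process_trace(tr)
            for s, e in ft.events:
                if abs(s - truth[0]) <= 2 and abs(e - truth[1]) <= 2:
                    recovered += 1
                    break
    assert total >= 150
    assert recovered / total >= 0.95


# ------------------------------------------------------------- histograms


def test_single_event_histogram_has_unit_mass_in_one_bin():
    e = np.full(50, 0.75)
    ft = FretTrace("t", e, 0.1, gamma_hat=1.0, events=((0, 50),))
    hist = build_histogram([ft], bin_width=0.05)
    mass = hist.densities * np.diff(hist.bin_edges)
    assert mass.sum() == pytest.approx(1.0, abs=1e-9)
    idx = np.searchsorted(hist.bin_edges, 0.75, side="right") - 1
    assert mass[idx] == pytest.approx(1.0)


def test_histogram_requires_events():
    ft = FretTrace("t", np.zeros(50), 0.1, gamma_hat=1.0)
    with pytest.raises(ValueError):
        build_histogram([ft])


def _mode_density(hist, value):
    idx = np.searchsorted(hist.bin_edges, value, side="right") - 1
    return hist.densities[idx]


def test_wild_type_u36_histogram_modes(wt_u36_run):
    """Pooled wild-type U36 histogram peaks near 0.75 with a smaller
    shoulder near 0.25."""
    hist = build_histogram(wt_u36_run.frets)
    d75, d25 = _mode_density(hist, 0.75), _mode_density(hist, 0.25)
    assert d75 > d25 > 0
    # both are local maxima against the valley between them
    assert d25 > _mode_density(hist, 0.5)
    assert d75 > _mode_density(hist, 0.5)


def test_wild_type_u63_histogram_modes(wt_u63_run):
    """U63 labelling inverts the signal: the 0.50 mode dominates 0.90."""
    hist = build_histogram(wt_u63_run.frets)
    assert _mode_density(hist, 0.50) > _mode_density(hist, 0.90) > 0
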