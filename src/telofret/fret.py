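"""Raw two-channel traces -> gamma-corrected FRET trajectories.

FRET efficiency per frame is E = IA / (IA + gamma * ID), algebraically
identical to the reciprocal form E = 1 / (1 + gamma * ID / IA).  The
correction factor gamma compensates for quantum-yield/detection differences
(including protein-induced donor enhancement) and is estimated per trace as
the ratio of the summed two-channel intensity immediately before binding to
the summed intensity immediately after binding; acceptor bleaching and
enzyme dissociation cannot be distinguished, which rules out the usual
post-bleach gamma estimator.

Binding events are detected as sustained threshold crossings of E, and the
in-event frames of many traces are pooled into density-normalized FRET
histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .simulate import Trace

__all__ = [
    "FretTrace",
    "FretHistogram",
    "GammaEstimate",
    "estimate_gamma",
    "compute_fret",
    "detect_events",
    "process_trace",
    "process_dataset",
    "build_histogram",
    "fret_ratio_form",
    "fret_reciprocal_form",
]

#: FRET values outside this range are excluded from histogram pooling;
#: stored efficiencies are clamped to it so downstream fits see finite data.
FRET_RANGE = (-0.2, 1.2)

DEFAULT_THRESHOLD = 0.12  # midway between the unbound 0.0 and lowest bound 0.25 means, minus noise margin
DEFAULT_MIN_FRAMES = 3
GAMMA_WINDOW = 10  # frames averaged on each side of the binding onset
GAMMA_GUARD = 2  # frames adjacent to the transition excluded (motion blur)


@dataclass(frozen=True)
class GammaEstimate:
    """Per-trace gamma with provenance; ``fallback`` marks traces where the
    pre-binding window was unavailable and gamma defaulted to 1."""

    value: float
    fallback: bool = False
    reason: Optional[str] = None


@dataclass(frozen=True)
class FretTrace:
    """Gamma-corrected efficiency trajectory with detected binding events."""

    trace_id: str
    efficiencies: np.ndarray  # clamped to FRET_RANGE
    frame_s: float
    gamma_hat: float
    events: tuple[tuple[int, int], ...] = ()  # half-open frame intervals
    valid: Optional[np.ndarray] = None  # frames usable for pooling
    gamma_fallback: bool = False

    def __post_init__(self) -> None:
        if self.gamma_hat <= 0:
            raise ValueError("gamma_hat must be > 0")
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(len(self.efficiencies), dtype=bool))
        n = len(self.efficiencies)
        prev_end = 0
        for start, end in self.events:
            if not (0 <= start < end <= n) or start < prev_end:
                raise ValueError("events must be ordered, non-overlapping, in-bounds")
            prev_end = end

    def __len__(self) -> int:
        return len(self.efficiencies)

    def event_frames(self) -> np.ndarray:
        """Pooled in-event efficiencies (valid frames only)."""
        chunks = [
            self.efficiencies[s:e][self.valid[s:e]] for s, e in self.events
        ]
        return np.concatenate(chunks) if chunks else np.empty(0)


@dataclass(frozen=True)
class FretHistogram:
    bin_edges: np.ndarray
    densities: np.ndarray
    n_frames_pooled: int
    n_events: int

    def __post_init__(self) -> None:
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0")
        mass = float(np.sum(self.densities * np.diff(self.bin_edges)))
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"histogram mass {mass} != 1")


def fret_ratio_form(donor: np.ndarray, acceptor: np.ndarray, gamma: float) -> np.ndarray:
    return acceptor / (acceptor + gamma * donor)


def fret_reciprocal_form(donor: np.ndarray, acceptor: np.ndarray, gamma: float) -> np.ndarray:
    return 1.0 / (1.0 + gamma * (donor / acceptor))


def estimate_gamma(
    trace: Trace,
    event: tuple[int, int],
    window: int = GAMMA_WINDOW,
    guard: int = GAMMA_GUARD,
) -> GammaEstimate:
    """Per-trace gamma from summed intensities across the binding onset.

    gamma_hat = mean(ID + IA over the ``window`` frames ending ``guard``
    frames before the onset) / mean(ID + IA over the ``window`` frames
    starting ``guard`` frames after the onset).  Traces without enough
    pre-binding or in-event frames fall back to gamma = 1 with a warning
    record rather than an exception, so batch processing keeps going.
    """
    start, end = event
    total = trace.donor + trace.acceptor
    pre_lo, pre_hi = start - guard - window, start - guard
    post_lo, post_hi = start + guard, start + guard + window
    if pre_lo < 0:
        msg = f"trace {trace.trace_id}: only {start} pre-binding frames (< {window + guard})"
        warnings.warn(msg, stacklevel=2)
        return GammaEstimate(1.0, fallback=True, reason=msg)
    if post_hi > end:
        msg = f"trace {trace.trace_id}: event too short for gamma window ({end - start} frames)"
        warnings.warn(msg, stacklevel=2)
        return GammaEstimate(1.0, fallback=True, reason=msg)
    pre = float(np.mean(total[pre_lo:pre_hi]))
    post = float(np.mean(total[post_lo:post_hi]))
    if pre <= 0 or post <= 0:
        msg = f"trace {trace.trace_id}: non-positive window mean"
        warnings.warn(msg, stacklevel=2)
        return GammaEstimate(1.0, fallback=True, reason=msg)
    return GammaEstimate(pre / post)


def compute_fret(
    trace: Trace,
    gamma_hat: float | GammaEstimate = 1.0,
    events: Sequence[tuple[int, int]] = (),
) -> FretTrace:
    """Per-frame gamma-corrected FRET efficiency.

    Frames with non-positive acceptor counts are evaluated with the acceptor
    floored at machine epsilon (avoiding division blow-ups) and then clamped
    with everything else into ``FRET_RANGE``; frames whose raw value fell
    outside the range are flagged invalid and excluded from histograms.
    """
    fallback = False
    if isinstance(gamma_hat, GammaEstimate):
        fallback = gamma_hat.fallback
        gamma_hat = gamma_hat.value
    if gamma_hat <= 0:
        raise ValueError("gamma_hat must be > 0")
    eps = np.finfo(float).eps
    acceptor = np.maximum(trace.acceptor, eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = fret_ratio_form(trace.donor, acceptor, gamma_hat)
    finite = np.isfinite(raw)
    in_range = finite & (raw >= FRET_RANGE[0]) & (raw <= FRET_RANGE[1])
    clamped = np.clip(np.where(finite, raw, 0.0), *FRET_RANGE)
    return FretTrace(
        trace_id=trace.trace_id,
        efficiencies=clamped,
        frame_s=trace.frame_s,
        gamma_hat=float(gamma_hat),
        events=tuple(events),
        valid=in_range,
        gamma_fallback=fallback,
    )


def detect_events(
    efficiencies: np.ndarray | FretTrace,
    threshold: float = DEFAULT_THRESHOLD,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> list[tuple[int, int]]:
    """Maximal runs of frames with E >= threshold lasting >= min_frames.

    An event ends when E drops back below threshold or at the end of the
    trace (FRET loss by bleach/dissociation or truncation).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    e = efficiencies.efficiencies if isinstance(efficiencies, FretTrace) else np.asarray(efficiencies)
    above = e >= threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False])).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(t)) for s, t in zip(starts, ends) if t - s >= min_frames]


def process_trace(
    trace: Trace,
    threshold: float = DEFAULT_THRESHOLD,
    min_frames: int = DEFAULT_MIN_FRAMES,
    window: int = GAMMA_WINDOW,
    guard: int = GAMMA_GUARD,
) -> FretTrace:
    """Full per-trace pipeline: uncorrected pass to find the binding onset,
    per-trace gamma from the onset, corrected efficiencies, final events."""
    first_pass = compute_fret(trace, 1.0)
    rough_events = detect_events(first_pass, threshold, min_frames)
    if not rough_events:
        return first_pass
    gamma = estimate_gamma(trace, rough_events[0], window=window, guard=guard)
    corrected = compute_fret(trace, gamma)
    events = detect_events(corrected, threshold, min_frames)
    return FretTrace(
        trace_id=corrected.trace_id,
        efficiencies=corrected.efficiencies,
        frame_s=corrected.frame_s,
        gamma_hat=corrected.gamma_hat,
        events=tuple(events),
        valid=corrected.valid,
        gamma_fallback=corrected.gamma_fallback,
    )


def process_dataset(traces: Iterable[Trace], **kwargs) -> list[FretTrace]:
    return [process_trace(t, **kwargs) for t in traces]


def build_histogram(
    frets: Iterable[FretTrace],
    bin_width: float = 0.05,
    fret_range: tuple[float, float] = FRET_RANGE,
) -> FretHistogram:
    """Density-normalized histogram pooling every valid in-event frame."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pooled = []
    n_events = 0
    for ft in frets:
        n_events += len(ft.events)
        pooled.append(ft.event_frames())
    values = np.concatenate(pooled) if pooled else np.empty(0)
    if n_events == 0 or values.size == 0:
        raise ValueError("no binding events to pool into a histogram")
    lo, hi = fret_range
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    densities, edges = np.histogram(values, bins=edges, density=True)
    return FretHistogram(
        bin_edges=edges,
        densities=densities,
        n_frames_pooled=int(values.size),
        n_events=n_events,
    )
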