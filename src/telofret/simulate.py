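"""Seeded synthetic smFRET trajectories and extension-assay gel lanes.

The trace simulator emulates a surface-immobilized donor-labelled telomeric
primer visited by an acceptor-labelled telomerase: a donor-only unbound
baseline, a single binding event during which the bound complex alternates
between a docked and an alternative conformation with exponential dwells,
and termination of the FRET signal by the first of acceptor photobleaching
or enzyme dissociation (experimentally indistinguishable, so they are merged
into one rate).  Donor photobleaching ends the trace entirely.  Transitions
falling inside a camera frame produce occupancy-weighted mixed emission
(motion blur), and each channel carries Gaussian noise with variance
``a + b * mean`` (read noise plus shot noise).

Quantum-yield bookkeeping: the summed detected intensity drops by the factor
``gamma_true`` on binding, so the per-trace estimator
gamma_hat = (pre-binding sum)/(bound sum) recovers ``gamma_true`` and the
corrected efficiency E = IA/(IA + gamma*ID) recovers the state means.

The gel-lane simulator is a generative stand-in for the enzymology behind a
direct primer-extension assay: per-molecule extend/dissociate/translocate
walks over the template register model, with band intensity proportional to
molecule count times incorporated labeled-dG count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .duplex import (
    DEFAULT_TEMPLATE,
    PrimerSpec,
    RegisterResult,
    TemplateSpec,
    annealing_register,
    labeled_dg_count,
    translocate,
)

__all__ = [
    "KineticModel",
    "Trace",
    "TraceTruth",
    "TruthDwell",
    "ExtensionSimParams",
    "GelLane",
    "simulate_binding_trace",
    "simulate_dataset",
    "simulate_gel_lane",
]

# Semantic state codes used in truth labels and idealized paths.
STATE_UNBOUND = 0
STATE_DOCKED = 1
STATE_ALTERNATIVE = 2
STATE_NAMES = {STATE_UNBOUND: "unbound", STATE_DOCKED: "docked", STATE_ALTERNATIVE: "alternative"}


@dataclass(frozen=True)
class KineticModel:
    """Ground-truth kinetic scheme for one labelling/enzyme condition.

    FRET state means are ordered (unbound, docked, alternative); rates are
    per second; ``k_on_frame`` is a per-frame binding probability while
    unbound.  ``state_sds`` are the nominal FRET-domain emission widths the
    intensity noise model produces (used for resolvability checks and HMM
    initialization), not an independent noise source.
    """

    name: str
    state_means: tuple[float, float, float]  # (unbound, docked, alternative)
    state_sds: tuple[float, float, float]
    k_da: float  # docked -> alternative, 1/s
    k_ad: float  # alternative -> docked, 1/s
    k_on_frame: float  # binding probability per frame while unbound
    k_off: float  # enzyme dissociation, 1/s
    bleach_rate_acceptor: float  # 1/s
    bleach_rate_donor: float  # 1/s
    gamma_true: float = 1.2
    frame_s: float = 0.1
    total_intensity: float = 1000.0
    noise_floor: float = 800.0  # a in var = a + b*mean
    noise_shot: float = 2.0  # b in var = a + b*mean

    def validate(self) -> None:
        for attr in ("k_da", "k_ad", "k_off", "bleach_rate_acceptor", "bleach_rate_donor"):
            if getattr(self, attr) < 0:
                raise ValueError(f"KineticModel.{attr} must be >= 0")
        if not 0.0 <= self.k_on_frame <= 1.0:
            raise ValueError("KineticModel.k_on_frame must be a probability in [0, 1]")
        if any(s <= 0 for s in self.state_sds):
            raise ValueError("KineticModel.state_sds must be > 0")
        if self.frame_s <= 0:
            raise ValueError("KineticModel.frame_s must be > 0")
        if self.gamma_true <= 0:
            raise ValueError("KineticModel.gamma_true must be > 0")
        if self.total_intensity <= 0:
            raise ValueError("KineticModel.total_intensity must be > 0")
        if self.noise_floor < 0 or self.noise_shot < 0:
            raise ValueError("KineticModel noise parameters must be >= 0")

    def resolvable(self) -> bool:
        """True when all state means are separated by > 2x the widest emission."""
        m = self.state_means
        gap = min(abs(m[i] - m[j]) for i in range(3) for j in range(i + 1, 3))
        return gap > 2.0 * max(self.state_sds)


@dataclass(frozen=True)
class TruthDwell:
    state: int  # STATE_DOCKED or STATE_ALTERNATIVE
    duration_s: float  # continuous-time duration
    censored: bool  # first/last dwell of the event (boundary unobserved)


@dataclass(frozen=True)
class TraceTruth:
    """Simulation ground truth carried alongside a trace."""

    state_path: np.ndarray  # per-frame majority-occupancy label
    event: Optional[tuple[int, int]]  # bound interval in frames, half-open
    dwells: tuple[TruthDwell, ...]  # continuous-time bound-state dwells
    gamma_true: float


@dataclass(frozen=True)
class Trace:
    """A two-channel fluorescence trajectory (arbitrary units per frame)."""

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_s: float
    truth: Optional[TraceTruth] = None

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor must have equal length")
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("trace intensities must be finite")
        if self.frame_s <= 0:
            raise ValueError("frame_s must be > 0")

    def __len__(self) -> int:
        return len(self.donor)


def _bound_channel_means(efficiency: float, model: KineticModel) -> tuple[float, float]:
    """Noiseless (donor, acceptor) means for a bound state of given FRET."""
    i0 = model.total_intensity
    g = model.gamma_true
    acceptor = efficiency * i0 / (1.0 + efficiency * (g - 1.0))
    donor = i0 / g - acceptor
    return donor, acceptor


def _segments_for_trace(
    model: KineticModel, n_frames: int, rng: np.random.Generator, start_state: int
) -> tuple[list[tuple[float, float, int]], Optional[float], Optional[tuple[float, float]], list[TruthDwell]]:
    """Continuous-time emission segments for one trace.

    Returns (segments, donor_bleach_time, bound_interval, truth_dwells);
    segments are (t_start, t_end, state) with state in {unbound, docked,
    alternative}; times in seconds, clipped later to the trace window.
    """
    fs = model.frame_s
    horizon = n_frames * fs

    t_donor = rng.exponential(1.0 / model.bleach_rate_donor) if model.bleach_rate_donor > 0 else math.inf
    end = min(horizon, t_donor)

    if model.k_on_frame > 0:
        t_on = rng.geometric(model.k_on_frame) * fs
    else:
        t_on = math.inf

    segments: list[tuple[float, float, int]] = []
    dwells: list[TruthDwell] = []
    if t_on >= end:
        segments.append((0.0, end, STATE_UNBOUND))
        return segments, (t_donor if t_donor < horizon else None), None, dwells

    segments.append((0.0, t_on, STATE_UNBOUND))

    k_term = model.k_off + model.bleach_rate_acceptor
    t_term = t_on + (rng.exponential(1.0 / k_term) if k_term > 0 else math.inf)
    bound_end = min(t_term, end)

    t = t_on
    state = start_state
    raw_dwells: list[tuple[int, float, float]] = []  # (state, t0, t1) untruncated
    while t < bound_end:
        rate = model.k_da if state == STATE_DOCKED else model.k_ad
        dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_next = t + dwell
        seg_end = min(t_next, bound_end)
        segments.append((t, seg_end, state))
        raw_dwells.append((state, t, t_next))
        t = t_next
        state = STATE_ALTERNATIVE if state == STATE_DOCKED else STATE_DOCKED

    if bound_end < end:
        segments.append((bound_end, end, STATE_UNBOUND))

    # Boundary dwells are censored: entry into the first and exit from the
    # last are unobserved (binding onset / FRET-loss truncation).
    n = len(raw_dwells)
    for i, (st, t0, t1) in enumerate(raw_dwells):
        duration = min(t1, bound_end) - t0
        censored = i == 0 or i == n - 1 or t1 > bound_end
        dwells.append(TruthDwell(state=st, duration_s=duration, censored=censored))

    bound_interval = (t_on, bound_end)
    return segments, (t_donor if t_donor < horizon else None), bound_interval, dwells


def simulate_binding_trace(
    model: KineticModel,
    n_frames: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    trace_id: str = "trace",
    start_state: int = STATE_DOCKED,
) -> Trace:
    """Simulate one two-channel trace with a single binding event.

    The trace begins unbound (donor-only emission), binds after a geometric
    number of frames, alternates docked/alternative with exponential dwells
    from ``start_state`` (docked by default: binding proceeds through
    template annealing into the active site), and loses FRET at the first of
    acceptor bleaching or dissociation.  Donor photobleaching truncates the
    trace.  Frames containing a transition carry occupancy-weighted mixed
    emission; per-frame ground-truth labels take the majority-occupancy
    state.
    """
    model.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if start_state not in (STATE_DOCKED, STATE_ALTERNATIVE):
        raise ValueError("start_state must be docked or alternative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fs = model.frame_s
    segments, t_donor_bleach, bound_interval, dwells = _segments_for_trace(
        model, n_frames, rng, start_state
    )

    n_keep = n_frames
    if t_donor_bleach is not None:
        n_keep = max(1, int(t_donor_bleach / fs))

    mean_d = np.zeros(n_keep)
    mean_a = np.zeros(n_keep)
    occupancy = np.zeros((3, n_keep))  # per-state occupied time per frame

    unbound_d = model.total_intensity
    docked_d, docked_a = _bound_channel_means(model.state_means[STATE_DOCKED], model)
    alt_d, alt_a = _bound_channel_means(model.state_means[STATE_ALTERNATIVE], model)
    channel_means = {
        STATE_UNBOUND: (unbound_d, 0.0),
        STATE_DOCKED: (docked_d, docked_a),
        STATE_ALTERNATIVE: (alt_d, alt_a),
    }

    horizon = n_keep * fs
    edges = np.arange(n_keep + 1) * fs
    for t0, t1, state in segments:
        t0, t1 = max(t0, 0.0), min(t1, horizon)
        if t1 <= t0:
            continue
        i0, i1 = int(t0 / fs), min(int(math.ceil(t1 / fs)), n_keep)
        overlap = np.clip(
            np.minimum(edges[i0 + 1 : i1 + 1], t1) - np.maximum(edges[i0:i1], t0), 0.0, None
        )
        frac = overlap / fs
        d, a = channel_means[state]
        mean_d[i0:i1] += frac * d
        mean_a[i0:i1] += frac * a
        occupancy[state, i0:i1] += overlap

    donor = mean_d + rng.normal(0.0, np.sqrt(model.noise_floor + model.noise_shot * np.abs(mean_d)))
    acceptor = mean_a + rng.normal(
        0.0, np.sqrt(model.noise_floor + model.noise_shot * np.abs(mean_a))
    )

    # Majority-occupancy truth label per frame; ties resolve to the lowest
    # state code (unbound first), deterministically.
    state_path = np.argmax(occupancy, axis=0).astype(np.int8)

    event = None
    if bound_interval is not None:
        f0 = int(round(bound_interval[0] / fs))
        f1 = int(math.ceil(bound_interval[1] / fs))
        f0, f1 = min(f0, n_keep), min(f1, n_keep)
        if f1 > f0:
            event = (f0, f1)

    truth = TraceTruth(
        state_path=state_path,
        event=event,
        dwells=tuple(dwells),
        gamma_true=model.gamma_true,
    )
    return Trace(trace_id=trace_id, donor=donor, acceptor=acceptor, frame_s=fs, truth=truth)


def simulate_dataset(
    model: KineticModel,
    n_traces: int,
    n_frames: int,
    seed: int,
    start_state: int = STATE_DOCKED,
) -> list[Trace]:
    """Simulate a dataset of traces; per-trace streams are spawned
    reproducibly from the master seed, so identical seeds give identical
    datasets."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traces)
    return [
        simulate_binding_trace(
            model, n_frames, np.random.default_rng(child), trace_id=f"{model.name}-{i:04d}",
            start_state=start_state,
        )
        for i, child in enumerate(children)
    ]


@dataclass(frozen=True)
class ExtensionSimParams:
    """Generative parameters for a primer-extension (gel) simulation.

    ``extension_probability[d-1]`` is the chance that a complex whose current
    RNA–DNA duplex is ``d`` basepairs adds the next nucleotide before
    dissociating; longer hybrids extend more reliably, which is what couples
    NAP to the initial duplex potential.
    """

    name: str
    extension_probability: tuple[float, ...]  # indexed by duplex length 1..len(template)
    translocation_success: float
    n_molecules: int = 20000
    recovery_control_true: float = 1.0
    max_repeats: int = 3
    intensity_scale: float = 1.0

    def validate(self, template: TemplateSpec = DEFAULT_TEMPLATE) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0.0 <= self.translocation_success <= 1.0:
            raise ValueError("translocation_success must be in [0, 1]")
        if len(self.extension_probability) < len(template):
            raise ValueError(
                "extension_probability must cover duplex lengths 1..template length"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.extension_probability):
            raise ValueError("extension probabilities must be in [0, 1]")
        if self.recovery_control_true <= 0:
            raise ValueError("recovery_control_true must be > 0")

    def p_extend(self, duplex_len: int) -> float:
        return self.extension_probability[duplex_len - 1]


@dataclass(frozen=True)
class GelLane:
    """Band intensities of one extension-assay lane.

    ``bands`` maps nucleotides added (product length, 0-based from the input
    primer 3' end) to intensity; ``first_repeat_length`` is the number of
    added nucleotides needed to reach the template 5' boundary for this
    primer.  ``truth_counts``, present for simulated lanes, holds the true
    molecule count per product length (specific activity not applied).
    """

    primer_name: str
    bands: tuple[tuple[int, float], ...]
    recovery_control_intensity: float
    first_repeat_length: int
    truth_counts: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        lengths = [b[0] for b in self.bands]
        if any(i >= j for i, j in zip(lengths, lengths[1:])):
            raise ValueError("band product_lengths must be strictly increasing")
        if any(b[1] < 0 for b in self.bands):
            raise ValueError("band intensities must be >= 0")
        if self.recovery_control_intensity <= 0:
            raise ValueError("recovery_control_intensity must be > 0")


def simulate_gel_lane(
    params: ExtensionSimParams,
    primer: PrimerSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    template: TemplateSpec = DEFAULT_TEMPLATE,
    recovery_factor: Optional[float] = None,
) -> GelLane:
    """Simulate one gel lane by stochastic per-molecule extension walks.

    Each molecule starts at the primer's initiation register, repeatedly
    extends (probability set by the current duplex length) or dissociates,
    and on reaching the template boundary either translocates (realigning to
    the short alignment-region duplex) or stops.  Band intensity encodes
    32P alpha-dGTP incorporation: molecules x labeled-dG count, times a
    lane-wide recovery factor that also scales the spiked recovery control
    (so control normalization cancels it).
    """
    params.validate(template)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    start = annealing_register(primer, template)  # raises if zero potential
    n_template = len(template)

    counts: dict[int, int] = {}
    n_current = params.n_molecules
    register = start.register
    product_len = 0
    repeats_done = 0
    while n_current > 0:
        if register == 0:
            if repeats_done >= params.max_repeats:
                counts[product_len] = counts.get(product_len, 0) + n_current
                break
            n_go = rng.binomial(n_current, params.translocation_success)
            n_stop = n_current - n_go
            if n_stop:
                counts[product_len] = counts.get(product_len, 0) + n_stop
            n_current = n_go
            register = n_template - template.alignment_region_len
            repeats_done += 1
            continue
        duplex = n_template - register
        n_go = rng.binomial(n_current, params.p_extend(duplex))
        n_stop = n_current - n_go
        if n_stop:
            counts[product_len] = counts.get(product_len, 0) + n_stop
        n_current = n_go
        register -= 1
        product_len += 1

    if recovery_factor is None:
        recovery_factor = float(rng.uniform(0.6, 1.0))
    if not recovery_factor > 0:
        raise ValueError("recovery_factor must be > 0")

    bands = []
    for length in sorted(counts):
        if length == 0:
            continue  # unextended primer carries no label
        dg = labeled_dg_count(primer, length, template, max_repeats=params.max_repeats + 1)
        intensity = counts[length] * dg * params.intensity_scale * recovery_factor
        bands.append((length, float(intensity)))

    return GelLane(
        primer_name=primer.name,
        bands=tuple(bands),
        recovery_control_intensity=float(params.recovery_control_true * recovery_factor),
        first_repeat_length=start.register,
        truth_counts=tuple(sorted(counts.items())),
    )
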