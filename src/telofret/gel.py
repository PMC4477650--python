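"""Extension-assay lane quantification: specific activity, recovery control
and nucleotide addition processivity (NAP).

Band intensities from an alpha-32P dGTP assay scale with how many labeled
dGs each product carries, so each band is first divided by its labeled-dG
count (specific-activity correction) to recover molecule-proportional
values.  NAP is the corrected intensity summed over the first repeat
addition band — the product extended to the template 5' end — plus every
higher band (those molecules necessarily passed through the first-repeat
intermediate), normalized by the spiked recovery control.  Per enzyme, NAP
values across the primer permutants are reported relative to the primer
with the greatest duplex-forming potential, (GGGGTT)3, which is set to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .duplex import DEFAULT_TEMPLATE, PrimerSpec, TemplateSpec, annealing_register, labeled_dg_count
from .simulate import GelLane

__all__ = [
    "NapResult",
    "correct_bands",
    "compute_nap",
    "normalize_nap",
    "replicate_summary",
    "quantify_lane",
]


@dataclass(frozen=True)
class NapResult:
    """NAP metrics for one primer (optionally with replicate statistics)."""

    primer_name: str
    nap_raw: float
    nap_relative: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.nap_raw < 0:
            raise ValueError("nap_raw must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


def correct_bands(lane: GelLane, dg_counts: Sequence[int]) -> GelLane:
    """Divide each band intensity by its labeled-dG count.

    ``dg_counts`` must align with ``lane.bands``.  Bands with a zero dG
    count carry no label and are excluded (with a warning) because their
    molecule count cannot be inferred.
    """
    if len(dg_counts) != len(lane.bands):
        raise ValueError(
            f"{len(dg_counts)} dG counts for {len(lane.bands)} bands in lane "
            f"{lane.primer_name!r}"
        )
    if any(c < 0 for c in dg_counts):
        raise ValueError("dG counts must be >= 0")
    corrected = []
    for (length, intensity), dg in zip(lane.bands, dg_counts):
        if dg == 0:
            warnings.warn(
                f"lane {lane.primer_name!r}: band at +{length} nt has no labeled dG; excluded",
                stacklevel=2,
            )
            continue
        corrected.append((length, intensity / dg))
    return replace(lane, bands=tuple(corrected))


def compute_nap(lane: GelLane) -> float:
    """Control-normalized NAP from a specific-activity-corrected lane.

    Sums corrected intensity over bands at or beyond the first repeat
    addition length and divides by the recovery control.  A lane with no
    such band has NAP 0 (a valid result: nothing reached the boundary).
    """
    total = sum(
        intensity for length, intensity in lane.bands if length >= lane.first_repeat_length
    )
    return float(total / lane.recovery_control_intensity)


def normalize_nap(
    results: Iterable[NapResult],
    duplex_potentials: Mapping[str, int],
) -> list[NapResult]:
    """Express NAP relative to the maximal-duplex-potential reference primer.

    The reference is the primer with the greatest duplex-forming potential
    among the inputs; its relative NAP is exactly 1.
    """
    results = list(results)
    if not results:
        raise ValueError("no NAP results to normalize")
    missing = [r.primer_name for r in results if r.primer_name not in duplex_potentials]
    if missing:
        raise ValueError(f"no duplex potential given for primers: {missing}")
    reference = max(results, key=lambda r: duplex_potentials[r.primer_name])
    if reference.nap_raw == 0:
        raise ValueError(
            f"reference primer {reference.primer_name!r} has zero NAP; cannot normalize"
        )
    return [replace(r, nap_relative=r.nap_raw / reference.nap_raw) for r in results]


def replicate_summary(replicates: Sequence[NapResult]) -> NapResult:
    """Mean and sample standard deviation of relative NAP over replicate
    assays of one primer (triplicate in the reference workflow)."""
    if len(replicates) < 2:
        raise ValueError("replicate summary needs n >= 2")
    names = {r.primer_name for r in replicates}
    if len(names) != 1:
        raise ValueError(f"replicates mix primers: {sorted(names)}")
    values = [r.nap_relative for r in replicates]
    if any(v is None for v in values):
        raise ValueError("replicates must carry nap_relative (normalize first)")
    arr = np.asarray(values, float)
    return NapResult(
        primer_name=replicates[0].primer_name,
        nap_raw=float(np.mean([r.nap_raw for r in replicates])),
        nap_relative=float(arr.mean()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=len(replicates),
    )


def quantify_lane(
    lane: GelLane,
    primer: PrimerSpec,
    template: TemplateSpec = DEFAULT_TEMPLATE,
    max_repeats: int = 8,
) -> NapResult:
    """Specific-activity correction + NAP for one lane, with dG counts
    derived from the primer's register walk on the template."""
    dg_counts = [
        labeled_dg_count(primer, length, template, max_repeats=max_repeats)
        for length, _ in lane.bands
    ]
    corrected = correct_bands(lane, dg_counts)
    return NapResult(primer_name=lane.primer_name, nap_raw=compute_nap(corrected))
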