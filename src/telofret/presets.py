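"""Bundled simulation presets and reference sequences.

Kinetic presets encode the published state positions and dwell times for
*Tetrahymena* telomerase bound to a (TG)8T2G3 primer: U36-labelled enzyme
reports the docked state at ~0.75 FRET and the alternative state at ~0.25;
U63 labelling inverts the signal (docked ~0.50, alternative ~0.90).
Conformational rates are the reciprocals of the measured mean dwell times
(wild type: tau_docked = 5 s, tau_alt = 0.8 s; L14A: 0.5 s and 0.9 s), the
camera integration time is 100 ms, and the remaining photophysical settings
(donor enhancement gamma = 1.2, intensity scale, noise floor/shot
coefficients, binding/bleaching rates) are unreported in the source data and
fixed here at values typical of single-molecule TIRF recordings (see
docs/methods.md).

Extension presets parameterize the generative gel model; they are chosen so
wild-type relative NAP rises with initial duplex potential while the L14A
enzyme fails on short hybrids and cannot translocate.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Mapping

import yaml

from .duplex import DEFAULT_TEMPLATE, PrimerSpec, TemplateSpec, enumerate_permutants
from .simulate import ExtensionSimParams, KineticModel

__all__ = [
    "KINETIC_PRESETS",
    "EXTENSION_PRESETS",
    "SMFRET_PRIMERS",
    "PERMUTANT_PRIMERS",
    "DEFAULT_TEMPLATE",
    "get_kinetic_preset",
    "get_extension_preset",
    "dump_presets",
    "load_presets",
]

_COMMON = dict(
    k_on_frame=0.01,
    k_off=0.01,
    bleach_rate_acceptor=0.01,
    bleach_rate_donor=0.005,
    gamma_true=1.2,
    frame_s=0.1,
    total_intensity=1000.0,
    noise_floor=800.0,
    noise_shot=2.0,
)

KINETIC_PRESETS: Mapping[str, KineticModel] = {
    "wt-u36": KineticModel(
        name="wt-u36",
        state_means=(0.0, 0.75, 0.25),
        state_sds=(0.03, 0.04, 0.035),
        k_da=1.0 / 5.0,
        k_ad=1.0 / 0.8,
        **_COMMON,
    ),
    "l14a-u36": KineticModel(
        name="l14a-u36",
        state_means=(0.0, 0.75, 0.25),
        state_sds=(0.03, 0.04, 0.035),
        k_da=1.0 / 0.5,
        k_ad=1.0 / 0.9,
        **_COMMON,
    ),
    "wt-u63": KineticModel(
        name="wt-u63",
        state_means=(0.0, 0.50, 0.90),
        state_sds=(0.03, 0.04, 0.04),
        k_da=1.0 / 5.0,
        k_ad=1.0 / 0.8,
        **_COMMON,
    ),
    "l14a-u63": KineticModel(
        name="l14a-u63",
        state_means=(0.0, 0.50, 0.90),
        state_sds=(0.03, 0.04, 0.04),
        k_da=1.0 / 0.5,
        k_ad=1.0 / 0.9,
        **_COMMON,
    ),
}

# Extension probability per current duplex length 1..9 bp.  Wild type
# extends short hybrids inefficiently and long hybrids almost surely;
# TEN-domain mutants are crippled specifically on short hybrids, L14A most
# severely, and L14A additionally cannot complete template translocation.
EXTENSION_PRESETS: Mapping[str, ExtensionSimParams] = {
    "wt": ExtensionSimParams(
        name="wt",
        extension_probability=(0.10, 0.30, 0.55, 0.75, 0.87, 0.93, 0.96, 0.99, 0.995),
        translocation_success=0.70,
    ),
    "l14a": ExtensionSimParams(
        name="l14a",
        extension_probability=(0.02, 0.05, 0.12, 0.30, 0.60, 0.85, 0.93, 0.98, 0.99),
        translocation_success=0.0,
    ),
    "q168a": ExtensionSimParams(
        name="q168a",
        extension_probability=(0.05, 0.15, 0.30, 0.55, 0.78, 0.90, 0.95, 0.98, 0.99),
        translocation_success=0.30,
    ),
    "f178a": ExtensionSimParams(
        name="f178a",
        extension_probability=(0.05, 0.15, 0.30, 0.55, 0.78, 0.90, 0.95, 0.98, 0.99),
        translocation_success=0.30,
    ),
    "d94a": ExtensionSimParams(
        name="d94a",
        extension_probability=(0.10, 0.30, 0.55, 0.75, 0.87, 0.93, 0.96, 0.99, 0.995),
        translocation_success=0.70,
    ),
}

#: smFRET primer series: (TG)8 anchor plus increasing telomeric 3' sequence,
#: spanning 5-9 bp of duplex-forming potential against the default template.
SMFRET_PRIMERS: tuple[PrimerSpec, ...] = (
    PrimerSpec("(TG)8T2G3", "TG" * 8 + "TT" + "GGG"),
    PrimerSpec("(TG)8T2G4", "TG" * 8 + "TT" + "GGGG"),
    PrimerSpec("(TG)8T2G4T", "TG" * 8 + "TT" + "GGGG" + "T"),
    PrimerSpec("(TG)8T2G4T2", "TG" * 8 + "TT" + "GGGG" + "TT"),
    PrimerSpec("(TG)8T2G4T2G", "TG" * 8 + "TT" + "GGGG" + "TTG"),
)

#: The six 18-nt circular permutants of the telomeric repeat used in
#: extension assays, length-matched at three repeats.
PERMUTANT_PRIMERS: tuple[PrimerSpec, ...] = tuple(enumerate_permutants("TTGGGG", 3))


def get_kinetic_preset(name: str) -> KineticModel:
    try:
        return KINETIC_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown kinetic preset {name!r}; available: {sorted(KINETIC_PRESETS)}"
        ) from None


def get_extension_preset(name: str) -> ExtensionSimParams:
    try:
        return EXTENSION_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown extension preset {name!r}; available: {sorted(EXTENSION_PRESETS)}"
        ) from None


def dump_presets(path) -> None:
    """Write all bundled presets to one YAML document."""
    doc = {
        "kinetic": {k: asdict(v) for k, v in KINETIC_PRESETS.items()},
        "extension": {k: asdict(v) for k, v in EXTENSION_PRESETS.items()},
        "template": {
            "sequence": DEFAULT_TEMPLATE.sequence,
            "alignment_region_len": DEFAULT_TEMPLATE.alignment_region_len,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_presets(path) -> dict:
    """Read a preset YAML document back into model objects."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kinetic = {
        k: KineticModel(**{**v, "state_means": tuple(v["state_means"]),
                           "state_sds": tuple(v["state_sds"])})
        for k, v in doc.get("kinetic", {}).items()
    }
    extension = {
        k: ExtensionSimParams(**{**v, "extension_probability": tuple(v["extension_probability"])})
        for k, v in doc.get("extension", {}).items()
    }
    template = DEFAULT_TEMPLATE
    if "template" in doc:
        template = TemplateSpec(**doc["template"])
    return {"kinetic": kinetic, "extension": extension, "template": template}
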