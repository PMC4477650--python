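"""Primer–template annealing registers and RNA–DNA duplex-forming potential.

The telomerase RNA carries a short template (default ``5'-CAACCCCAA-3'``,
the *Tetrahymena* 9-mer) that is copied into telomeric G-strand DNA.  A DNA
primer anneals with its 3' terminus paired to some template position (the
*register*, 0-based from the template 5' end); the duplex extends 3'-ward
along the template as a contiguous Watson–Crick run.  Nucleotide addition
moves the 3' terminus toward register 0 (the template 5' boundary), at which
point the hybrid must melt and re-anneal downstream in the 3'-terminal
alignment region — template translocation — leaving a short duplex the
length of that alignment region (3 bp by default).

Complementarity is strict Watson–Crick (G·C, A·T/U); G·U wobble pairs are
not counted, which reproduces every printed duplex length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "PrimerSpec",
    "TemplateSpec",
    "RegisterResult",
    "DEFAULT_TEMPLATE",
    "duplex_potential",
    "annealing_register",
    "translocate",
    "enumerate_permutants",
    "templated_extension",
    "labeled_dg_count",
]

_DNA_ALPHABET = set("ACGT")
_RNA_ALPHABET = set("ACGU")

#: Watson–Crick pairs, (DNA primer base, RNA template base).
_WC_PAIRS = {("G", "C"), ("C", "G"), ("A", "U"), ("T", "A")}

#: DNA complement of an RNA template base (what gets synthesized).
_TEMPLATE_COMPLEMENT = {"C": "G", "G": "C", "A": "T", "U": "A"}


@dataclass(frozen=True)
class PrimerSpec:
    """A telomeric DNA primer, written 5'->3' over {A, C, G, T}."""

    name: str
    sequence: str
    label_position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"primer {self.name!r} has non-DNA characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TemplateSpec:
    """The RNA template region, written 5'->3'.

    ``alignment_region_len`` is the number of 3'-terminal template residues
    that seed re-annealing after translocation (3 for *Tetrahymena*).
    Plain-DNA input is tolerated: T is read as U.
    """

    sequence: str = "CAACCCCAA"
    alignment_region_len: int = 3

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("template sequence must be non-empty")
        normalized = self.sequence.upper().replace("T", "U")
        bad = set(normalized) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"template has non-RNA characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", normalized)
        if not 0 <= self.alignment_region_len <= len(self.sequence):
            raise ValueError("alignment_region_len must lie within the template")

    def __len__(self) -> int:
        return len(self.sequence)


DEFAULT_TEMPLATE = TemplateSpec()


@dataclass(frozen=True)
class RegisterResult:
    """An annealing register: where the primer 3' terminus sits on the template.

    ``register`` indexes the template base (0 = template 5' end) paired with
    the primer's 3'-terminal nucleotide; the duplex occupies template
    positions ``register .. register + duplex_len - 1``.
    """

    register: int
    duplex_len: int

    def __post_init__(self) -> None:
        if self.register < 0 or self.duplex_len < 0:
            raise ValueError("register and duplex_len must be non-negative")


def _is_pair(dna: str, rna: str) -> bool:
    return (dna, rna) in _WC_PAIRS


def _run_length(primer: PrimerSpec, template: TemplateSpec, register: int) -> int:
    """Contiguous complementary run pairing the primer 3' end (read 3'->5')
    against template[register:] (read 5'->3')."""
    seq = primer.sequence
    tmpl = template.sequence
    run = 0
    while (
        register + run < len(tmpl)
        and run < len(seq)
        and _is_pair(seq[-1 - run], tmpl[register + run])
    ):
        run += 1
    return run


def duplex_potential(primer: PrimerSpec, template: TemplateSpec = DEFAULT_TEMPLATE) -> RegisterResult:
    """Maximal duplex-forming potential of a primer against the template.

    Scans every register and returns the one maximizing the contiguous
    Watson–Crick run anchored at the primer 3' terminus; ties resolve to the
    5'-most (smallest) register.  A zero-length run is a valid result.
    """
    best = RegisterResult(0, 0)
    for register in range(len(template)):
        run = _run_length(primer, template, register)
        if run > best.duplex_len:
            best = RegisterResult(register, run)
    return best


def annealing_register(primer: PrimerSpec, template: TemplateSpec = DEFAULT_TEMPLATE) -> RegisterResult:
    """Initiation register for a primer-extension reaction.

    Biological annealing is seeded by the template's 3'-terminal alignment
    region, so an initiation register must (a) place the duplex flush with
    the template 3' end, (b) engage the full alignment region, and (c) leave
    at least one templating base 5' of the terminus so the primer can be
    extended.  Among qualifying registers the longest duplex (smallest
    register) wins.  This yields the staggered 3–8 bp series for the six
    telomeric-repeat permutants, with (GGGGTT)3 maximal at 8 bp.

    Raises ``ValueError`` if the primer cannot initiate (zero qualifying
    register).
    """
    n = len(template)
    for register in range(1, n):
        wanted = n - register
        if wanted < template.alignment_region_len:
            break
        if _run_length(primer, template, register) >= wanted:
            return RegisterResult(register, wanted)
    raise ValueError(
        f"primer {primer.name!r} has no productive annealing register on the template"
    )


def translocate(register: RegisterResult, template: TemplateSpec = DEFAULT_TEMPLATE) -> RegisterResult:
    """Template translocation: realign a boundary-stalled product downstream.

    Requires the input register to sit at the template 5' boundary
    (``register == 0``); the product's 3' end then re-anneals in the
    template's 3'-terminal alignment region, giving a duplex of exactly
    ``alignment_region_len`` basepairs (3 bp for the default template).
    """
    if register.register != 0:
        raise ValueError(
            "translocation requires the primer 3' end at the template 5' boundary "
            f"(register 0), got register {register.register}"
        )
    k = template.alignment_region_len
    return RegisterResult(register=len(template) - k, duplex_len=k)


def enumerate_permutants(repeat_unit: str, n_repeats: int) -> list[PrimerSpec]:
    """All distinct circular permutations of ``repeat_unit``, each
    concatenated ``n_repeats`` times (the length-matched permutant primers)."""
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seen: dict[str, None] = {}
    for i in range(len(repeat_unit)):
        rotation = repeat_unit[i:] + repeat_unit[:i]
        seen.setdefault(rotation, None)
    return [PrimerSpec(name=f"({rot}){n_repeats}", sequence=rot * n_repeats) for rot in seen]


def templated_extension(
    primer: PrimerSpec,
    template: TemplateSpec = DEFAULT_TEMPLATE,
    max_repeats: int = 4,
) -> str:
    """The DNA nucleotides telomerase would add to ``primer``, in order.

    Starts from the primer's initiation register, runs to the template 5'
    boundary (the first-repeat product), then appends up to ``max_repeats``
    further rounds of translocation + full-template synthesis.
    """
    start = annealing_register(primer, template)
    tmpl = template.sequence
    added: list[str] = []

    def synthesize_down(from_register: int) -> None:
        for pos in range(from_register - 1, -1, -1):
            added.append(_TEMPLATE_COMPLEMENT[tmpl[pos]])

    synthesize_down(start.register)
    post = translocate(RegisterResult(0, len(tmpl) - start.register), template)
    for _ in range(max_repeats):
        synthesize_down(post.register)
    return "".join(added)


def labeled_dg_count(
    primer: PrimerSpec,
    product_length: int,
    template: TemplateSpec = DEFAULT_TEMPLATE,
    max_repeats: int = 4,
) -> int:
    """Number of radiolabeled dGTPs incorporated in a product of
    ``product_length`` added nucleotides (alpha-32P dGTP labelling: every
    templated G counts)."""
    if product_length < 0:
        raise ValueError("product_length must be >= 0")
    if product_length == 0:
        return 0
    added = templated_extension(primer, template, max_repeats=max_repeats)
    if product_length > len(added):
        raise ValueError(
            f"product_length {product_length} exceeds the {len(added)} nucleotides "
            f"modelled ({max_repeats} repeats past the first boundary)"
        )
    return added[:product_length].count("G")


def first_repeat_length(primer: PrimerSpec, template: TemplateSpec = DEFAULT_TEMPLATE) -> int:
    """Nucleotides that must be added to reach the template 5' boundary
    (the first repeat addition band) from the initiation register."""
    return annealing_register(primer, template).register
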