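"""Dose arithmetic for sprayed RNA species.

Converts mass concentrations (ng/ul) to molarity using conventional
average per-unit molar masses — 660 g/mol per base pair for duplex RNA,
330 g/mol per nucleotide for single strands — and derives the
siRNA-equivalent ("effective") molarity of a long duplex: one trigger
molecule can be diced into floor(length / 22) phased 22-nt siRNAs, so a
139-bp duplex is worth 6 siRNA equivalents and a 322-bp duplex 14.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

#: average molar mass per unit, g/mol
MASS_PER_BP_DUPLEX = 660.0
MASS_PER_NT_SINGLE = 330.0
DEFAULT_SIRNA_LENGTH = 22


@dataclass(frozen=True)
class DoseSpec:
    """An RNA dose: mass concentration, species length and strandedness."""

    concentration: float  # ng/ul
    length: int  # bp (duplex) or nt (single-stranded)
    strandedness: str = "duplex"
    label: str = ""

    def __post_init__(self):
        if self.concentration < 0:
            raise ConfigError("concentration must be >= 0")
        if self.length < 1:
            raise ConfigError("length must be >= 1")
        if self.strandedness not in ("single", "duplex"):
            raise ConfigError(
                f"strandedness must be 'single' or 'duplex', "
                f"got {self.strandedness!r}"
            )


@dataclass(frozen=True)
class MolarResult:
    molarity: float  # uM
    sirna_yield: int
    effective_molarity: float  # uM; molarity * yield

    def to_dict(self) -> dict:
        return {
            "molarity_uM": self.molarity,
            "sirna_yield": self.sirna_yield,
            "effective_molarity_uM": self.effective_molarity,
        }


def molar_concentration(dose: DoseSpec) -> float:
    """Molarity in uM: (ng/ul) / (length x unit mass g/mol) x 1000.

    ng/ul equals mg/l, so dividing by g/mol gives mmol/l / 1000 = uM
    after the factor 1000.
    """
    unit_mass = (
        MASS_PER_BP_DUPLEX if dose.strandedness == "duplex" else MASS_PER_NT_SINGLE
    )
    return dose.concentration / (dose.length * unit_mass) * 1000.0


def phased_sirna_yield(
    duplex_length: int, sirna_length: int = DEFAULT_SIRNA_LENGTH
) -> int:
    """Number of full phased siRNA units one duplex can yield."""
    if sirna_length < 1:
        raise ConfigError("sirna_length must be >= 1")
    if duplex_length < 1:
        raise ConfigError("duplex_length must be >= 1")
    return duplex_length // sirna_length


def molar_result(dose: DoseSpec, sirna_length: int = DEFAULT_SIRNA_LENGTH) -> MolarResult:
    molarity = molar_concentration(dose)
    yield_ = phased_sirna_yield(dose.length, sirna_length)
    return MolarResult(molarity, yield_, molarity * yield_)


def effective_molarity_ratio(
    dose: DoseSpec,
    reference: DoseSpec,
    reference_molarity_override: float | None = None,
) -> tuple[float, float]:
    """(molar_ratio, effective_ratio) of a dose against a reference.

    The override lets the caller divide by a *rounded* reference
    molarity (e.g. 0.1 uM for the 1.4 ng/ul positive-control siRNA,
    whose unrounded molarity is 0.0964 uM) to reproduce back-of-envelope
    arithmetic exactly.
    """
    ref_molarity = (
        reference_molarity_override
        if reference_molarity_override is not None
        else molar_concentration(reference)
    )
    if ref_molarity <= 0:
        raise ConfigError("reference molarity must be > 0")
    molar_ratio = molar_concentration(dose) / ref_molarity
    effective_ratio = molar_ratio * phased_sirna_yield(dose.length)
    return molar_ratio, effective_ratio


def sum_yields(per_reaction_yields: list[float]) -> float:
    """Total synthesis yield (ug), exact at one decimal."""
    for value in per_reaction_yields:
        if value < 0:
            raise ConfigError("yields must be >= 0")
    return round(sum(per_reaction_yields), 1)
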