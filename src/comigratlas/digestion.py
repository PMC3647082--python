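"""In-silico tryptic digestion and peptide observability.

Trypsin cleaves C-terminal to K or R, and (by the usual rule) not when the
next residue is proline. A peptide is *observable* when, at at least one
allowed charge state, its m/z falls inside the instrument scan range; the
number of distinct observable peptides of a protein is the denominator of
its emPAI. Defaults reflect an LTQ ion-trap setup: scan range m/z 450-1800,
charges 1+..3+, fixed carbamidomethylation of cysteine, two missed cleavages
tolerated for identified peptides but none in the observability denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    CARBAMIDOMETHYL_MONO,
    PROTON_MONO,
    RESIDUE_MONO,
    STANDARD_RESIDUES,
    WATER_MONO,
)
from .errors import UndefinedMassError, ValidationError
from .proteome_io import ProteinRecord


@dataclass(frozen=True)
class DigestionParams:
    """Digestion + instrument parameters governing peptide observability.

    ``max_missed_cleavages_observed`` is the search-engine tolerance applied
    to identified peptides (and to the synthetic generator's candidate pool);
    ``missed_cleavages_observable`` is the stricter convention used for the
    emPAI denominator (fully cleaved peptides only, by default).
    """

    max_missed_cleavages_observed: int = 2
    missed_cleavages_observable: int = 0
    mz_min: float = 450.0
    mz_max: float = 1800.0
    charges: frozenset[int] = frozenset({1, 2, 3})
    proline_rule: bool = True
    carbamidomethyl_cys: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages_observed < 0 or self.missed_cleavages_observable < 0:
            raise ValidationError("missed-cleavage limits must be >= 0")
        if not self.mz_min < self.mz_max:
            raise ValidationError(
                f"mz_min ({self.mz_min}) must be < mz_max ({self.mz_max})"
            )
        charges = frozenset(int(z) for z in self.charges)
        if not charges or min(charges) < 1:
            raise ValidationError("charges must be a nonempty set of integers >= 1")
        object.__setattr__(self, "charges", charges)


@dataclass(frozen=True)
class Peptide:
    """A tryptic product with its coordinates in the parent sequence.

    ``start``/``end`` are 0-based half-open offsets; ``missed_cleavages``
    counts internal cleavage sites spanned by the peptide.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions *after* which trypsin cuts (exclusive end offsets).

    The C-terminus is not included: a cut there produces no new boundary.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def cleave_tryptic(
    sequence: str, max_missed: int = 0, proline_rule: bool = True
) -> list[Peptide]:
    """Digest ``sequence`` with trypsin, allowing up to ``max_missed``
    missed cleavages; returns peptides ordered by (start, end).

    A sequence with no cleavage sites returns itself as a single peptide
    with zero missed cleavages.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    sequence = sequence.upper()
    bounds = [0] + cleavage_sites(sequence, proline_rule) + [len(sequence)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = bounds[i], bounds[j + 1]
            peptides.append(Peptide(sequence[start:end], start, end, j - i))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_monoisotopic_mass(sequence: str, carbamidomethyl_cys: bool = True) -> float:
    """Neutral monoisotopic mass of a peptide, Da.

    Raises :class:`UndefinedMassError` for an empty sequence or one with a
    letter outside the 20 standard residues.
    """
    if not sequence:
        raise UndefinedMassError("mass of an empty peptide is undefined")
    mass = WATER_MONO
    for aa in sequence:
        try:
            mass += RESIDUE_MONO[aa]
        except KeyError:
            raise UndefinedMassError(
                f"residue {aa!r} has no defined monoisotopic mass"
            ) from None
    if carbamidomethyl_cys:
        mass += CARBAMIDOMETHYL_MONO * sequence.count("C")
    return mass


def mz_for_charge(mass: float, z: int) -> float:
    """m/z of a peptide of neutral ``mass`` at charge ``z`` (protonation)."""
    if z < 1:
        raise ValidationError(f"charge must be >= 1, got {z}")
    if mass <= 0:
        raise ValidationError(f"mass must be positive, got {mass}")
    return (mass + z * PROTON_MONO) / z


def is_observable(sequence: str, params: DigestionParams) -> bool:
    """True when the peptide's m/z falls in-range for some allowed charge."""
    if not set(sequence) <= STANDARD_RESIDUES:
        return False
    mass = peptide_monoisotopic_mass(sequence, params.carbamidomethyl_cys)
    return any(
        params.mz_min <= mz_for_charge(mass, z) <= params.mz_max
        for z in params.charges
    )


def observable_peptides(
    sequence: str, params: DigestionParams, max_missed: int | None = None
) -> set[str]:
    """Distinct observable tryptic peptide sequences of a protein.

    ``max_missed`` defaults to ``params.missed_cleavages_observable`` (the
    emPAI-denominator convention); pass
    ``params.max_missed_cleavages_observed`` to get the search-tolerance
    candidate pool instead.
    """
    if max_missed is None:
        max_missed = params.missed_cleavages_observable
    peptides = cleave_tryptic(sequence, max_missed, params.proline_rule)
    return {p.sequence for p in peptides if is_observable(p.sequence, params)}


def count_observable_peptides(
    protein: ProteinRecord | str, params: DigestionParams = DigestionParams()
) -> int:
    """Number of distinct observable peptides — the emPAI denominator.

    Peptides containing nonstandard residues (undefined mass) are excluded;
    distinctness is by peptide sequence. A protein may return 0, in which
    case its emPAI is undefined.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    return len(observable_peptides(sequence, params))
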