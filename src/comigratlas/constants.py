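"""Frozen physical constants used across the package.

All masses are monoisotopic, in daltons. The residue masses are the standard
values for the 20 canonical amino acids (residue = amino acid minus water);
a peptide's neutral mass is the sum of its residue masses plus one water.
Keeping the table here, in one place, makes every mass in the package
traceable to a single source.
"""

from __future__ import annotations

#: Monoisotopic mass of water (H2O), Da.
WATER_MONO: float = 18.0105646863

#: Monoisotopic mass of a proton, Da. Used to convert neutral mass to m/z.
PROTON_MONO: float = 1.00727646688

#: Monoisotopic mass shift of carbamidomethylation (+CH2CONH2 on Cys), Da.
CARBAMIDOMETHYL_MONO: float = 57.02146373

#: Monoisotopic residue masses of the 20 standard amino acids, Da.
RESIDUE_MONO: dict[str, float] = {
    "G": 57.02146373,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841392,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841392,
    "R": 156.10111102,
    "Y": 163.06332854,
    "W": 186.07931295,
}

#: The 20 standard one-letter residue codes.
STANDARD_RESIDUES: frozenset[str] = frozenset(RESIDUE_MONO)

#: Ambiguity / nonstandard one-letter codes that may appear in real proteomes.
#: Sequences containing them are kept addressable, but peptides spanning them
#: have no defined monoisotopic mass and are excluded from observability.
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BJOUXZ")

#: Kyte-Doolittle hydropathy index per residue (dimensionless, -4.5 .. 4.5).
#: Positive = hydrophobic. Used by the synthetic-data generator to attenuate
#: peptide detection probability for hydrophobic peptides.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Version tag for the constants above; logged with every export so results
#: can be traced to the exact mass table used.
CONSTANTS_VERSION: str = "2026.1"


def gravy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy (GRAVY) of a peptide sequence."""
    if not sequence:
        raise ValueError("GRAVY of an empty sequence is undefined")
    return sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)


def normalized_hydropathy(sequence: str) -> float:
    """GRAVY rescaled linearly from [-4.5, 4.5] to [0, 1].

    0 = maximally hydrophilic, 1 = maximally hydrophobic.
    """
    return (gravy(sequence) + 4.5) / 9.0
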