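"""Synthetic gel-slice peptide identifications with known ground truth.

The generator emulates the data-generating process a BN-PAGE / LC-MS/MS
complexome experiment implies: intact complexes migrate as Gaussian bands
over ~60 gel slices; each subunit contributes tryptic peptides whose chance
of being identified saturates with the complex's local abundance (times the
subunit's stoichiometry) and is attenuated for hydrophobic peptides —
reproducing the familiar depression of emPAI for very hydrophobic subunits
such as the photosystem reaction-centre proteins. Background rows emulate
spurious single-peptide identifications scattered across the gel.

All randomness flows from one integer seed; each operation draws from a
deterministic substream, so the same seed always yields the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import KYTE_DOOLITTLE, normalized_hydropathy
from .comigration import CoMigrationGroup
from .digestion import DigestionParams, observable_peptides
from .errors import ValidationError
from .proteome_io import PeptideIdentification, ProteinRecord

#: Default number of gel slices (a 1D BN-PAGE lane cut at ~1 mm intervals).
DEFAULT_N_SLICES: int = 60

_RESIDUES = sorted(KYTE_DOOLITTLE)
# K/R together ~11% of residues so tryptic peptide lengths look realistic;
# the remaining 18 residues share the rest uniformly.
_KR_FREQ = 0.11
_RESIDUE_P = np.array(
    [_KR_FREQ / 2 if aa in "KR" else (1 - _KR_FREQ) / 18 for aa in _RESIDUES]
)


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """One simulated complex: members with stoichiometries, a Gaussian band
    position (apex slice, sigma in slices) and an abundance scale."""

    label: str
    members: tuple[tuple[str, int], ...]
    apex_slice: int
    width_slices: float
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.label}: members must be nonempty")
        if any(q < 1 for _, q in self.members):
            raise ValidationError(f"{self.label}: stoichiometries must be >= 1")
        if self.width_slices <= 0 or self.abundance <= 0:
            raise ValidationError(f"{self.label}: width and abundance must be > 0")
        object.__setattr__(
            self, "members", tuple((str(a), int(q)) for a, q in self.members)
        )

    def band_abundance(self, slice_index: int) -> float:
        d = slice_index - self.apex_slice
        return self.abundance * float(
            np.exp(-(d * d) / (2.0 * self.width_slices**2))
        )


@dataclass(frozen=True)
class NoiseParams:
    """Detection-model parameters.

    detection_rate_k:
        Saturation constant of the per-peptide detection probability
        1 − exp(−k · stoichiometry · abundance); larger k = more sensitive
        instrument.
    background_rate:
        Expected number of spurious (but sequence-true) tryptic peptide rows
        per gel slice.
    hydrophobicity_penalty:
        Fractional detection loss per unit of normalized peptide hydropathy
        (0..1 on the Kyte-Doolittle scale).
    detection_floor:
        Ion-selection cutoff: a complex band emits nothing from slices where
        its Gaussian abundance falls below this fraction of its apex
        abundance, emulating the instrument's minimum-signal threshold for
        triggering MS/MS.
    """

    detection_rate_k: float = 5.0
    background_rate: float = 1.0
    hydrophobicity_penalty: float = 0.3
    detection_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detection_rate_k <= 0:
            raise ValidationError("detection_rate_k must be > 0")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        if not 0 <= self.hydrophobicity_penalty <= 1:
            raise ValidationError("hydrophobicity_penalty must be in [0,1]")
        if not 0 <= self.detection_floor < 1:
            raise ValidationError("detection_floor must be in [0,1)")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic substream: one generator per (seed, operation)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 400),
    seed: int = 0,
    prefix: str = "SYN",
) -> list[ProteinRecord]:
    """Random protein sequences with realistic tryptic-site density."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValidationError("length_range must satisfy 10 <= min <= max")
    rng = _rng(seed, 1)
    width = len(str(n_proteins))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length, p=_RESIDUE_P))
        records.append(
            ProteinRecord(f"{prefix}{i + 1:0{width}d}", seq, "synthetic protein")
        )
    return records


def _peptide_pool(
    protein: ProteinRecord, params: DigestionParams
) -> list[tuple[str, float]]:
    """Candidate identifiable peptides (search-tolerance missed cleavages,
    in scan range) with their normalized hydropathy."""
    pool = sorted(
        observable_peptides(
            protein.sequence, params, params.max_missed_cleavages_observed
        )
    )
    return [(pep, normalized_hydropathy(pep)) for pep in pool]


def simulate_peptide_table(
    proteome: Sequence[ProteinRecord],
    specs: Sequence[SyntheticComplexSpec],
    noise: NoiseParams = NoiseParams(),
    n_slices: int = DEFAULT_N_SLICES,
    params: DigestionParams = DigestionParams(),
) -> list[PeptideIdentification]:
    """Simulate a per-slice peptide-identification table.

    For complex c at slice s with band abundance a, each candidate peptide
    of a member with stoichiometry q is reported independently with

        p = (1 − exp(−k·q·a)) · (1 − penalty · h(peptide)),  clamped to [0,1],

    where h is the peptide's normalized Kyte-Doolittle hydropathy. On top,
    ``background_rate`` Poisson-distributed spurious rows per slice draw a
    random protein and one of its true tryptic peptides.
    """
    index = {p.accession: p for p in proteome}
    for spec in specs:
        for acc, _ in spec.members:
            if acc not in index:
                raise ValidationError(
                    f"{spec.label}: member {acc!r} not in proteome"
                )

    pools: dict[str, list[tuple[str, float]]] = {}

    def pool_of(acc: str) -> list[tuple[str, float]]:
        if acc not in pools:
            pools[acc] = _peptide_pool(index[acc], params)
        return pools[acc]

    rows: list[PeptideIdentification] = []
    rng = _rng(noise.seed, 2)
    for spec in sorted(specs, key=lambda c: c.label):
        for s in range(1, n_slices + 1):
            a = spec.band_abundance(s)
            if a < noise.detection_floor * spec.abundance:
                continue  # band signal below the MS/MS selection threshold
            for acc, q in spec.members:
                rate = noise.detection_rate_k * q * a
                base = 1.0 - np.exp(-rate)
                pool = pool_of(acc)
                if not pool:
                    continue
                h = np.array([hp for _, hp in pool])
                p = np.clip(base * (1.0 - noise.hydrophobicity_penalty * h), 0.0, 1.0)
                hits = rng.random(len(pool)) < p
                for (pep, _), hit in zip(pool, hits):
                    if hit:
                        rows.append(PeptideIdentification(s, acc, pep))

    if noise.background_rate > 0:
        bg_rng = _rng(noise.seed, 3)
        accs = sorted(index)
        for s in range(1, n_slices + 1):
            for _ in range(int(bg_rng.poisson(noise.background_rate))):
                acc = accs[int(bg_rng.integers(len(accs)))]
                pool = pool_of(acc)
                if not pool:
                    continue
                pep, _ = pool[int(bg_rng.integers(len(pool)))]
                rows.append(PeptideIdentification(s, acc, pep))

    rows.sort(key=lambda r: (r.slice_index, r.accession, r.peptide))
    return rows


def true_abundance_profile(
    specs: Sequence[SyntheticComplexSpec],
    accession: str,
    n_slices: int = DEFAULT_N_SLICES,
    detection_floor: float = 0.01,
) -> list[float]:
    """Ground-truth per-slice signal for one protein: stoichiometry-weighted
    band abundance summed over the complexes it belongs to, zeroed where the
    band falls below the detection floor (the instrument-visible truth that
    a perfect quantifier could recover)."""
    out = [0.0] * n_slices
    for spec in specs:
        for acc, q in spec.members:
            if acc != accession:
                continue
            for s in range(1, n_slices + 1):
                a = spec.band_abundance(s)
                if a >= detection_floor * spec.abundance:
                    out[s - 1] += q * a
    return out


def ground_truth_groups(
    specs: Sequence[SyntheticComplexSpec],
) -> list[CoMigrationGroup]:
    """Expected co-migration groups: one per multi-member complex, anchored
    at its apex. Two complexes sharing an apex stay distinct groups."""
    groups = []
    for spec in specs:
        members = frozenset(acc for acc, _ in spec.members)
        if len(members) >= 2:
            groups.append(
                CoMigrationGroup(members, anchor_slice=spec.apex_slice,
                                 max_apex_spread=0)
            )
    return groups


def default_complex_specs(
    proteome: Sequence[ProteinRecord],
    n_complexes: int = 5,
    members_range: tuple[int, int] = (3, 6),
    apex_start: int = 8,
    apex_step: int = 10,
    width_slices: float = 1.0,
    abundance: float = 0.6,
    seed: int = 0,
) -> list[SyntheticComplexSpec]:
    """Disjoint complexes with evenly spaced apexes, for benchmark datasets.

    Members are drawn without replacement from the proteome in order;
    stoichiometries are 1 or 2.
    """
    rng = _rng(seed, 4)
    lo, hi = members_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_complexes)]
    if sum(sizes) > len(proteome):
        raise ValidationError(
            f"proteome too small: need {sum(sizes)} member proteins"
        )
    specs = []
    cursor = 0
    for i, size in enumerate(sizes):
        members = tuple(
            (proteome[cursor + j].accession, int(rng.integers(1, 3)))
            for j in range(size)
        )
        cursor += size
        specs.append(
            SyntheticComplexSpec(
                label=f"complex{i + 1}",
                members=members,
                apex_slice=apex_start + i * apex_step,
                width_slices=width_slices,
                abundance=abundance,
            )
        )
    return specs
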