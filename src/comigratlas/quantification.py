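"""emPAI abundance estimation and molar-percentage normalization.

emPAI = 10^(N_observed / N_observable) − 1, where N_observed is the number
of distinct peptide sequences identified for a protein (here: per gel
slice) and N_observable the number of distinct in-silico tryptic peptides
whose m/z falls in the instrument scan range (a whole-protein property).
mol% expresses each protein's emPAI as a share of the summed emPAI, an
approximate molar composition of the sample.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .digestion import DigestionParams, count_observable_peptides
from .errors import UndefinedDenominatorError, ValidationError
from .proteome_io import PeptideIdentification, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmpaiResult:
    """Per-protein, per-slice abundance estimate."""

    accession: str
    slice_index: int
    n_observed: int
    n_observable: int
    empai: float
    mol_percent: float | None = None


def count_observed_peptides(
    ids: Iterable[PeptideIdentification], accession: str, slice_index: int
) -> int:
    """Distinct peptide sequences attributed to ``accession`` in one slice.

    Charge and score do not contribute to distinctness: the same sequence
    seen at 2+ and 3+ counts once.
    """
    return len(
        {
            i.peptide
            for i in ids
            if i.accession == accession and i.slice_index == slice_index
        }
    )


def compute_empai(n_observed: int, n_observable: int) -> float:
    """10^(n_observed / n_observable) − 1.

    Conventions: 0 observed → 0 regardless of the denominator (including the
    0/0 case); observed > 0 with 0 observable raises
    :class:`UndefinedDenominatorError`.
    """
    if n_observed < 0 or n_observable < 0:
        raise ValidationError("peptide counts must be nonnegative")
    if n_observed == 0:
        return 0.0
    if n_observable == 0:
        raise UndefinedDenominatorError(
            f"{n_observed} observed peptides but no observable tryptic peptides"
        )
    return 10.0 ** (n_observed / n_observable) - 1.0


def compute_mol_percent(empai_by_protein: Mapping[str, float]) -> dict[str, float]:
    """Normalize emPAI values to molar percentages summing to 100."""
    if any(v < 0 for v in empai_by_protein.values()):
        raise ValidationError("emPAI values must be nonnegative")
    total = sum(empai_by_protein.values())
    if total <= 0:
        raise ValidationError("all emPAI values are zero; mol%% is undefined")
    return {acc: 100.0 * v / total for acc, v in empai_by_protein.items()}


def summed_mol_percent(mol: Mapping[str, float], subset: Iterable[str]) -> float:
    """Sum of mol% over a subset of accessions (e.g. one localization class)."""
    subset = set(subset)
    missing = subset - set(mol)
    if missing:
        raise ValidationError(f"accessions not in mol%% map: {sorted(missing)[:5]}")
    return float(sum(mol[acc] for acc in subset))


def empai_table(
    ids: Sequence[PeptideIdentification],
    proteome: Mapping[str, ProteinRecord],
    params: DigestionParams = DigestionParams(),
    *,
    strict: bool = True,
) -> list[EmpaiResult]:
    """Per-slice emPAI for every (accession, slice) present in ``ids``.

    The observable-peptide denominator is computed once per protein from its
    full sequence; the observed numerator is the per-slice distinct peptide
    count. With ``strict=False``, proteins whose denominator is zero are
    dropped with a warning instead of raising, which keeps a pipeline run
    alive when a stray identification maps to a protein with no in-range
    tryptic peptides.
    """
    per_cell: dict[tuple[str, int], set[str]] = defaultdict(set)
    for ident in ids:
        if ident.accession not in proteome:
            raise ValidationError(f"accession {ident.accession!r} not in proteome")
        per_cell[(ident.accession, ident.slice_index)].add(ident.peptide)

    observable: dict[str, int] = {}
    for acc in {acc for acc, _ in per_cell}:
        observable[acc] = count_observable_peptides(proteome[acc], params)

    results: list[EmpaiResult] = []
    for (acc, slice_index), peptides in sorted(per_cell.items()):
        try:
            empai = compute_empai(len(peptides), observable[acc])
        except UndefinedDenominatorError:
            if strict:
                raise
            logger.warning(
                "%s: identified in slice %d but has no observable peptides; dropped",
                acc, slice_index,
            )
            continue
        results.append(
            EmpaiResult(acc, slice_index, len(peptides), observable[acc], empai)
        )
    return results


def total_empai_by_protein(results: Iterable[EmpaiResult]) -> dict[str, float]:
    """Summed-over-slices emPAI per protein (the dataset-wide abundance
    used for sample-composition summaries)."""
    totals: dict[str, float] = defaultdict(float)
    for r in results:
        totals[r.accession] += r.empai
    return dict(totals)
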