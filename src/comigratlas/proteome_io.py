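"""Readers/writers for the pipeline's external formats.

Formats handled
---------------
* FASTA proteome (via Biopython), validated into :class:`ProteinRecord`.
* Peptide-identification TSV (columns ``slice_index``, ``accession``,
  ``peptide``, optional ``score`` and ``charge``) — one row per identified
  peptide per gel slice, emulating per-slice search-engine output.
* Annotation TSV (``accession``, ``localization``, ``category``).
* Mass-marker TSV (``slice_index``, ``mass_kda``) for gel calibration.

All TSVs are tab-separated UTF-8 with a mandatory header row; ``.`` or an
empty field means "missing" for optional values. Gel slices are numbered
1-based from the top of the gel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Allowed subcellular-localization classes for annotation records.
LOCALIZATIONS: frozenset[str] = frozenset(
    {"thylakoid", "envelope", "stroma", "other", "unknown"}
)

_MISSING = {"", "."}


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: accession, amino-acid sequence, free-text description."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be nonempty")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        seq = self.sequence.upper()
        if not seq.isalpha():
            raise ValidationError(
                f"{self.accession}: sequence contains non-letter characters"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class PeptideIdentification:
    """One identified peptide in one gel slice, attributed to one accession."""

    slice_index: int
    accession: str
    peptide: str
    score: float | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.slice_index < 1:
            raise ValidationError(f"slice_index must be >= 1, got {self.slice_index}")
        if not self.accession:
            raise ValidationError("accession must be nonempty")
        pep = self.peptide.upper()
        if not pep.isalpha():
            raise ValidationError(f"invalid peptide string {self.peptide!r}")
        object.__setattr__(self, "peptide", pep)
        if self.score is not None and self.score < 0:
            raise ValidationError(f"negative score {self.score}")
        if self.charge is not None and self.charge not in (1, 2, 3):
            raise ValidationError(f"charge must be in {{1,2,3}}, got {self.charge}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Subcellular localization + functional category for one accession."""

    accession: str
    localization: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"{self.accession}: localization {self.localization!r} not one of "
                f"{sorted(LOCALIZATIONS)}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA proteome into validated :class:`ProteinRecord` objects.

    The accession is the first whitespace-delimited token of the header;
    the remainder of the header becomes the description. Sequences are
    uppercased. Duplicate accessions are rejected.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, str(rec.seq), desc))
    return records


def _check_fasta_shape(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header, and
    headerless trailing garbage, naming the offending line."""
    with open(path, encoding="utf-8") as fh:
        in_body = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                in_body = True
            elif not in_body:
                raise ParseError(
                    f"{path}:{lineno}: expected FASTA header line starting with '>'"
                )


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (inverse of :func:`read_fasta`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def read_peptide_table(
    path: str | Path,
    n_slices: int,
    *,
    proteome: dict[str, ProteinRecord] | None = None,
    collect_rejects: bool = False,
) -> list[PeptideIdentification] | tuple[list[PeptideIdentification], list[int]]:
    """Read a peptide-identification TSV.

    Parameters
    ----------
    n_slices:
        Total number of gel slices S; rows with ``slice_index`` outside
        1..S are rejected with their row number.
    proteome:
        Optional accession -> ProteinRecord map; when given, each peptide is
        checked to be a substring of its protein's sequence.
    collect_rejects:
        When False (default) the first bad row raises ValidationError.
        When True, returns ``(accepted, rejected_row_numbers)`` so that
        accepted + rejected always accounts for every input row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"slice_index", "accession", "peptide"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {sorted(missing)}")

    accepted: list[PeptideIdentification] = []
    rejected: list[int] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        try:
            accepted.append(_parse_peptide_row(row, idx, n_slices, proteome))
        except ValidationError:
            if not collect_rejects:
                raise
            rejected.append(idx)
    if collect_rejects:
        return accepted, rejected
    return accepted


def _parse_peptide_row(row, lineno: int, n_slices: int, proteome) -> PeptideIdentification:
    try:
        slice_index = int(row.slice_index)
    except ValueError:
        raise ValidationError(
            f"row {lineno}: non-integer slice_index {row.slice_index!r}"
        ) from None
    if not 1 <= slice_index <= n_slices:
        raise ValidationError(
            f"row {lineno}: slice_index {slice_index} outside 1..{n_slices}"
        )
    score = getattr(row, "score", None)
    charge = getattr(row, "charge", None)
    try:
        ident = PeptideIdentification(
            slice_index=slice_index,
            accession=row.accession,
            peptide=row.peptide,
            score=None if score is None or score in _MISSING else float(score),
            charge=None if charge is None or charge in _MISSING else int(charge),
        )
    except (ValidationError, ValueError) as exc:
        raise ValidationError(f"row {lineno}: {exc}") from None
    if proteome is not None:
        prot = proteome.get(ident.accession)
        if prot is None:
            raise ValidationError(
                f"row {lineno}: accession {ident.accession!r} not in proteome"
            )
        if ident.peptide not in prot.sequence:
            raise ValidationError(
                f"row {lineno}: peptide {ident.peptide!r} is not a substring of "
                f"{ident.accession}"
            )
    return ident


def write_peptide_table(ids: Iterable[PeptideIdentification], path: str | Path) -> None:
    """Write identifications as TSV (inverse of :func:`read_peptide_table`)."""
    rows = [
        {
            "slice_index": i.slice_index,
            "accession": i.accession,
            "peptide": i.peptide,
            "score": "." if i.score is None else i.score,
            "charge": "." if i.charge is None else i.charge,
        }
        for i in ids
    ]
    pd.DataFrame(rows, columns=["slice_index", "accession", "peptide", "score", "charge"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read an annotation TSV into an accession -> AnnotationRecord map.

    Localization strings outside the known vocabulary are mapped to
    ``"unknown"`` with a logged warning rather than rejected, so that
    annotations from a differently-scoped source remain usable.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", "localization", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    out: dict[str, AnnotationRecord] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.accession in out:
            raise ValidationError(f"row {idx}: duplicate accession {row.accession!r}")
        loc = row.localization.strip().lower()
        if loc not in LOCALIZATIONS:
            logger.warning(
                "row %d: unknown localization %r for %s; recorded as 'unknown'",
                idx, row.localization, row.accession,
            )
            loc = "unknown"
        out[row.accession] = AnnotationRecord(row.accession, loc, row.category)
    return out


def read_marker_table(path: str | Path) -> list[tuple[int, float]]:
    """Read mass-calibration markers as (slice_index, mass_kda) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"slice_index", "mass_kda"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    markers: list[tuple[int, float]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            markers.append((int(row.slice_index), float(row.mass_kda)))
        except ValueError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
    return markers


def proteome_index(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by accession, rejecting duplicates."""
    out: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.accession in out:
            raise ValidationError(f"duplicate accession {rec.accession!r}")
        out[rec.accession] = rec
    return out
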