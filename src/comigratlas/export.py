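"""Per-protein dataset entries and deterministic JSON export.

Each :class:`ProteinEntry` bundles what a complexome-profiling database
shows for one protein: its migration profile, detected peaks with apparent
complex masses, the proteins co-detected in each of its slices (partner
candidates), and the proteins with the most similar profiles. The export is
a pure function of its inputs — re-running with identical inputs produces a
byte-identical file — so datasets can be versioned and diffed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .comigration import find_slice_partners, profile_similarity
from .constants import CONSTANTS_VERSION
from .errors import ValidationError
from .profiling import (
    CalibrationCurve,
    MigrationProfile,
    Peak,
    estimate_complex_mass,
)
from .quantification import EmpaiResult

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PeakEntry:
    apex_slice: int
    left_slice: int
    right_slice: int
    apex_value: float
    est_mass_kda: float | None = None
    extrapolated: bool | None = None


@dataclass(frozen=True)
class ProteinEntry:
    """Everything the dataset records about one identified protein."""

    accession: str
    description: str
    profile: tuple[float, ...]
    peaks: tuple[PeakEntry, ...]
    partners_by_slice: dict[int, tuple[str, ...]]
    similar_proteins: tuple[tuple[str, float], ...]
    total_empai: float
    n_slices_detected: int


def build_entry(
    accession: str,
    *,
    profiles: Mapping[str, MigrationProfile],
    peaks_by_protein: Mapping[str, Sequence[Peak]],
    empai_results: Sequence[EmpaiResult],
    curve: CalibrationCurve | None = None,
    description: str = "",
    similarity_threshold: float = 0.8,
    max_similar: int = 20,
) -> ProteinEntry:
    """Assemble the database entry for one quantified protein.

    Partners in each slice are ordered by descending emPAI in that slice
    (ties by accession); similar proteins are ranked by descending Pearson
    correlation of whole profiles, reported above ``similarity_threshold``.
    """
    if accession not in profiles:
        raise ValidationError(f"{accession!r} was not quantified in this dataset")
    profile = profiles[accession]
    if profile.as_array().max(initial=0.0) <= 0:
        raise ValidationError(f"{accession!r} was detected in no slice")

    empai_in_slice = {(r.accession, r.slice_index): r.empai for r in empai_results}
    own_slices = sorted(
        r.slice_index for r in empai_results
        if r.accession == accession and r.n_observed > 0
    )
    partners_by_slice: dict[int, tuple[str, ...]] = {}
    for s in own_slices:
        partners = find_slice_partners(empai_results, accession, s)
        partners_by_slice[s] = tuple(
            sorted(partners, key=lambda a: (-empai_in_slice.get((a, s), 0.0), a))
        )

    similars: list[tuple[str, float]] = []
    for other, other_profile in profiles.items():
        if other == accession:
            continue
        try:
            sim = profile_similarity(profile, other_profile)
        except ValidationError:
            continue  # constant partner profile: similarity undefined
        if sim.score >= similarity_threshold:
            similars.append((other, sim.score))
    similars.sort(key=lambda t: (-t[1], t[0]))

    peak_entries = []
    for peak in peaks_by_protein.get(accession, []):
        if curve is not None:
            mass, extrapolated = estimate_complex_mass(peak, curve)
            peak_entries.append(
                PeakEntry(peak.apex_slice, peak.left_slice, peak.right_slice,
                          peak.apex_value, mass, extrapolated)
            )
        else:
            peak_entries.append(
                PeakEntry(peak.apex_slice, peak.left_slice, peak.right_slice,
                          peak.apex_value)
            )

    return ProteinEntry(
        accession=accession,
        description=description,
        profile=profile.values,
        peaks=tuple(peak_entries),
        partners_by_slice=partners_by_slice,
        similar_proteins=tuple(similars[:max_similar]),
        total_empai=float(sum(profile.values)),
        n_slices_detected=len(own_slices),
    )


def export_dataset(
    entries: Iterable[ProteinEntry],
    path: str | Path,
    parameters: Mapping[str, object] | None = None,
) -> dict:
    """Write all entries to one schema-versioned JSON file.

    Returns a manifest with the entry count and the file's SHA-256 checksum;
    identical inputs always produce an identical checksum.
    """
    entries = list(entries)
    if not entries:
        raise ValidationError("refusing to export an empty dataset")
    payload = {
        "schema_version": SCHEMA_VERSION,
        "constants_version": CONSTANTS_VERSION,
        "parameters": dict(parameters or {}),
        "n_entries": len(entries),
        "entries": [_entry_to_json(e) for e in sorted(entries, key=lambda e: e.accession)],
    }
    text = json.dumps(payload, sort_keys=True, indent=1)
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return {
        "path": str(path),
        "n_entries": len(entries),
        "sha256": hashlib.sha256(text.encode("utf-8")).hexdigest(),
    }


def _entry_to_json(entry: ProteinEntry) -> dict:
    d = asdict(entry)
    d["profile"] = list(entry.profile)
    d["peaks"] = [asdict(p) for p in entry.peaks]
    d["partners_by_slice"] = {
        str(s): list(partners) for s, partners in entry.partners_by_slice.items()
    }
    d["similar_proteins"] = [[acc, score] for acc, score in entry.similar_proteins]
    return d


def entry_from_json(d: Mapping) -> ProteinEntry:
    """Inverse of the JSON encoding used by :func:`export_dataset`."""
    return ProteinEntry(
        accession=d["accession"],
        description=d["description"],
        profile=tuple(d["profile"]),
        peaks=tuple(PeakEntry(**p) for p in d["peaks"]),
        partners_by_slice={
            int(s): tuple(v) for s, v in d["partners_by_slice"].items()
        },
        similar_proteins=tuple((a, s) for a, s in d["similar_proteins"]),
        total_empai=d["total_empai"],
        n_slices_detected=d["n_slices_detected"],
    )
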