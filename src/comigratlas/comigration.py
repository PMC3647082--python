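"""Co-migration inference and dataset summaries.

Two complementary notions of "potential interaction partner" are provided,
mirroring how complexome databases expose them:

* *same-slice detection*: every protein identified in the slice where the
  query protein shows a data point (what a user gets by clicking one point
  of a profile);
* *peak-apex grouping*: proteins whose profile peaks fall on the same (or a
  nearby) gel slice form a candidate complex.

The module also computes the standard dataset summaries: localization class
counts and their mol% shares, functional-category tallies, and the fraction
of the predicted gene models identified.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .profiling import MigrationProfile, Peak
from .proteome_io import AnnotationRecord, LOCALIZATIONS
from .quantification import EmpaiResult


@dataclass(frozen=True)
class CoMigrationGroup:
    """Proteins whose peak apexes cluster at/near one gel slice."""

    members: frozenset[str]
    anchor_slice: int
    max_apex_spread: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a co-migration group needs >= 2 members")

    @property
    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class SimilarityScore:
    accession_a: str
    accession_b: str
    score: float


class LocalizationSummary(NamedTuple):
    counts: dict[str, int]
    percents: dict[str, int]
    mol_percent: dict[str, float]
    n_identified: int


def round_half_up(x: float) -> int:
    """Deterministic half-up integer rounding for report strings."""
    return int(math.floor(x + 0.5))


def find_slice_partners(
    detections: Iterable[EmpaiResult], accession: str, slice_index: int
) -> set[str]:
    """All proteins detected (n_observed > 0) in a slice, minus the query."""
    return {
        d.accession
        for d in detections
        if d.slice_index == slice_index and d.n_observed > 0
    } - {accession}


def profile_similarity(a: MigrationProfile, b: MigrationProfile) -> SimilarityScore:
    """Pearson correlation between two migration profiles."""
    if a.n_slices != b.n_slices:
        raise ValidationError(
            f"profile length mismatch: {a.n_slices} vs {b.n_slices}"
        )
    va, vb = a.as_array(), b.as_array()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValidationError("correlation with a constant profile is undefined")
    r = stats.pearsonr(va, vb).statistic
    return SimilarityScore(a.accession, b.accession, float(r))


def group_comigrating(
    peaks_by_protein: Mapping[str, Sequence[Peak]], tolerance: int = 0
) -> list[CoMigrationGroup]:
    """Cluster proteins into candidate complexes by peak-apex proximity.

    For every gel slice s, the proteins with a peak apex within
    ``tolerance`` slices of s form a candidate group anchored at s.
    Singleton groups are dropped and duplicates (same member set) are merged
    onto the anchor with the smallest apex spread. A group whose member set
    is a strict subset of a nearby group's (anchors within 2*tolerance) is a
    windowing artifact of the same apex cluster and is pruned; a subset
    group anchored far away (e.g. a genuine sub-complex lower in the gel)
    is kept. A protein with several peaks can appear in several groups.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    apexes: dict[str, list[int]] = {
        acc: sorted({p.apex_slice for p in peaks})
        for acc, peaks in peaks_by_protein.items()
        if peaks
    }
    if not apexes:
        return []
    max_slice = max(a for ap in apexes.values() for a in ap)

    best: dict[frozenset[str], tuple[int, int]] = {}  # members -> (spread, anchor)
    anchors: dict[frozenset[str], set[int]] = {}  # every slice yielding the set
    for s in range(1, max_slice + tolerance + 1):
        members = []
        hit_apexes = []
        for acc, ap in apexes.items():
            near = [a for a in ap if abs(a - s) <= tolerance]
            if near:
                members.append(acc)
                hit_apexes.append(min(near, key=lambda a: (abs(a - s), a)))
        if len(members) < 2:
            continue
        key = frozenset(members)
        spread = max(hit_apexes) - min(hit_apexes)
        if key not in best or (spread, s) < best[key]:
            best[key] = (spread, s)
        anchors.setdefault(key, set()).add(s)

    def _near(a: set[int], b: set[int]) -> bool:
        return any(abs(x - y) <= 2 * tolerance for x in a for y in b)

    maximal = [
        ms for ms in best
        if not any(
            ms < other and _near(anchors[ms], anchors[other]) for other in best
        )
    ]
    groups = [
        CoMigrationGroup(ms, anchor_slice=best[ms][1], max_apex_spread=best[ms][0])
        for ms in maximal
    ]
    groups.sort(key=lambda g: (g.anchor_slice, g.sorted_members))
    return groups


def summarize_localization(
    identified: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    mol: Mapping[str, float],
) -> LocalizationSummary:
    """Counts, integer percents and summed mol% per localization class.

    Proteins without an annotation are counted as "unknown". ``mol`` must be
    a mol% map over the identified set (summing to 100).
    """
    identified = sorted(set(identified))
    if not identified:
        raise ValidationError("empty identified set")
    counts: Counter[str] = Counter()
    mol_sums: dict[str, float] = {loc: 0.0 for loc in LOCALIZATIONS}
    for acc in identified:
        ann = annotations.get(acc)
        loc = ann.localization if ann is not None else "unknown"
        counts[loc] += 1
        mol_sums[loc] += mol.get(acc, 0.0)
    n = len(identified)
    percents = {loc: round_half_up(100.0 * c / n) for loc, c in counts.items()}
    return LocalizationSummary(dict(counts), percents, mol_sums, n)


def tally_categories(
    identified: Iterable[str], annotations: Mapping[str, AnnotationRecord]
) -> dict[str, int]:
    """Functional-category counts over the identified set; proteins without
    an annotation fall into "Unknown"."""
    counts: Counter[str] = Counter()
    for acc in set(identified):
        ann = annotations.get(acc)
        category = ann.category if ann is not None and ann.category else "Unknown"
        counts[category] += 1
    return dict(counts)


class Coverage(NamedTuple):
    percent: float
    rounded: int


def coverage_fraction(n_identified: int, n_models: int) -> Coverage:
    """Identified proteins as a share of all predicted gene models.

    Returns full precision alongside the half-up integer rounding used for
    report strings.
    """
    if n_models <= 0:
        raise ValidationError("n_models must be positive")
    if not 0 <= n_identified <= n_models:
        raise ValidationError("n_identified must be within 0..n_models")
    pct = 100.0 * n_identified / n_models
    return Coverage(pct, round_half_up(pct))
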