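"""Migration profiles, peak detection and gel mass calibration.

A migration profile is a protein's emPAI vector across gel slices (slice 1 =
top of the gel, where the largest complexes sit). Peaks in a profile mark
the native complexes the protein participates in; a log-linear calibration
against marker complexes of known size converts a peak's apex slice into an
apparent complex mass in kDa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .quantification import EmpaiResult


@dataclass(frozen=True)
class MigrationProfile:
    """Dense per-slice emPAI vector for one accession (or group label)."""

    accession: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if any(v < 0 for v in vals):
            raise ValidationError(f"{self.accession}: negative profile value")
        object.__setattr__(self, "values", vals)

    @property
    def n_slices(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class Peak:
    """A profile peak: apex slice plus half-max flanking interval (1-based)."""

    apex_slice: int
    left_slice: int
    right_slice: int
    apex_value: float

    def __post_init__(self) -> None:
        if not self.left_slice <= self.apex_slice <= self.right_slice:
            raise ValidationError("peak interval must contain its apex")
        if self.apex_value <= 0:
            raise ValidationError("apex value must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares fit log10(mass_kDa) = slope * slice + intercept."""

    slope: float
    intercept: float
    marker_count: int
    residuals_log10: tuple[float, ...]
    slice_min: int
    slice_max: int

    def predict_mass(self, slice_index: float) -> float:
        return 10.0 ** (self.slope * slice_index + self.intercept)


class MassEstimate(NamedTuple):
    mass_kda: float
    extrapolated: bool


def build_profiles(
    empai_results: Iterable[EmpaiResult], n_slices: int
) -> dict[str, MigrationProfile]:
    """Assemble dense profiles (zeros where a protein was not identified)."""
    vectors: dict[str, list[float]] = {}
    for r in empai_results:
        if not 1 <= r.slice_index <= n_slices:
            raise ValidationError(
                f"{r.accession}: slice {r.slice_index} outside 1..{n_slices}"
            )
        vec = vectors.setdefault(r.accession, [0.0] * n_slices)
        vec[r.slice_index - 1] += r.empai
    return {
        acc: MigrationProfile(acc, tuple(vec)) for acc, vec in sorted(vectors.items())
    }


def aggregate_group(
    profiles: Mapping[str, MigrationProfile], members: Iterable[str], label: str
) -> MigrationProfile:
    """Element-wise sum of member profiles, e.g. to merge paralogs that share
    a complex subunit role (PsaD1 + PsaD2 -> "PsaD")."""
    members = sorted(set(members))
    if not members:
        raise ValidationError("aggregate_group requires at least one member")
    missing = [m for m in members if m not in profiles]
    if missing:
        raise ValidationError(f"unknown member accession(s): {missing}")
    length = profiles[members[0]].n_slices
    if any(profiles[m].n_slices != length for m in members):
        raise ValidationError("member profiles differ in length")
    summed = np.zeros(length)
    for m in members:
        summed += profiles[m].as_array()
    return MigrationProfile(label, tuple(summed))


def detect_peaks(
    profile: MigrationProfile, rel_height: float = 0.1, min_value: float = 0.01
) -> list[Peak]:
    """Find profile peaks as plateau-merged local maxima with sufficient
    topographic prominence.

    A maximum qualifies when its *prominence* — its height above the higher
    of the two minima separating it from the nearest taller part of the
    profile — is at least ``max(min_value, rel_height * max(profile))``.
    Prominence (rather than raw height) suppresses sampling-noise bumps on
    the flank of a dominant peak while keeping genuine secondary complexes,
    whose valleys drop back near zero. For an isolated peak prominence
    equals height, so the two criteria agree on well-separated peaks.

    Gel boundaries count as maxima, and a plateau reports its topmost
    (leftmost) slice as apex — ties resolve toward the larger complex. Each
    peak's interval extends along strictly descending flanks while values
    stay at or above half the apex, stopping before a local minimum so that
    intervals of neighbouring peaks never overlap.
    """
    if not 0 < rel_height <= 1:
        raise ValidationError("rel_height must be in (0, 1]")
    if min_value < 0:
        raise ValidationError("min_value must be >= 0")
    v = profile.as_array()
    n = len(v)
    peak_max = float(v.max(initial=0.0))
    if peak_max <= 0:
        return []
    threshold = max(min_value, rel_height * peak_max)

    peaks: list[Peak] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_nb = v[i - 1] if i > 0 else -math.inf
        right_nb = v[j + 1] if j + 1 < n else -math.inf
        if (v[i] > left_nb and v[i] > right_nb and v[i] > 0
                and _prominence(v, i, j) >= threshold):
            half = 0.5 * v[i]
            left = i
            while left - 1 >= 0 and v[left - 1] < v[left] and v[left - 1] >= half:
                left -= 1
            if left < i and left - 1 >= 0 and v[left - 1] > v[left]:
                left += 1  # stopped on a shared local minimum; leave it out
            right = j
            while right + 1 < n and v[right + 1] < v[right] and v[right + 1] >= half:
                right += 1
            if right > j and right + 1 < n and v[right + 1] > v[right]:
                right -= 1
            peaks.append(Peak(i + 1, left + 1, right + 1, float(v[i])))
        i = j + 1
    return peaks


def _prominence(v: np.ndarray, i: int, j: int) -> float:
    """Topographic prominence of the plateau maximum spanning v[i..j].

    On each side, walk away from the plateau tracking the running minimum
    until a value strictly above the plateau is met; the prominence is the
    plateau height minus the higher of the two side bases. A side with no
    higher value before the gel edge imposes no constraint (base 0, signal
    absent beyond the gel), so the global maximum's prominence equals its
    height and a band truncated at the boundary keeps full prominence.
    """
    apex = v[i]
    base_left = 0.0
    running = apex
    for k in range(i - 1, -1, -1):
        if v[k] > apex:
            base_left = running
            break
        running = min(running, v[k])
    base_right = 0.0
    running = apex
    for k in range(j + 1, len(v)):
        if v[k] > apex:
            base_right = running
            break
        running = min(running, v[k])
    return float(apex - max(base_left, base_right))


def detect_peaks_all(
    profiles: Mapping[str, MigrationProfile],
    rel_height: float = 0.1,
    min_value: float = 0.01,
) -> dict[str, list[Peak]]:
    """Peak detection over a whole profile map (convenience wrapper)."""
    return {
        acc: detect_peaks(profile, rel_height, min_value)
        for acc, profile in profiles.items()
    }


def fit_calibration(markers: Sequence[tuple[int, float]]) -> CalibrationCurve:
    """Fit log10(mass) against slice index by least squares.

    Requires >= 2 markers with distinct slice indices and positive masses;
    the fitted slope must be negative (mass decreases down the gel).
    """
    if len(markers) < 2:
        raise ValidationError("calibration needs at least 2 markers")
    slices = [s for s, _ in markers]
    masses = [m for _, m in markers]
    if len(set(slices)) < 2:
        raise ValidationError("markers must cover at least 2 distinct slices")
    if any(m <= 0 for m in masses):
        raise ValidationError("marker masses must be positive")
    x = np.asarray(slices, dtype=float)
    y = np.log10(np.asarray(masses, dtype=float))
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError(
            "calibration slope is nonnegative; markers do not decrease in mass "
            "down the gel"
        )
    residuals = tuple(float(r) for r in y - (fit.slope * x + fit.intercept))
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        marker_count=len(markers),
        residuals_log10=residuals,
        slice_min=min(slices),
        slice_max=max(slices),
    )


def estimate_complex_mass(peak: Peak, curve: CalibrationCurve) -> MassEstimate:
    """Apparent complex mass at the peak apex; flagged when the apex lies
    outside the marker range (extrapolation)."""
    mass = curve.predict_mass(peak.apex_slice)
    extrapolated = not curve.slice_min <= peak.apex_slice <= curve.slice_max
    return MassEstimate(mass, extrapolated)
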