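"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: digestion enumerates all
substrings and filters by boundary validity, masses come from pyteomics,
and peak finding scans every index exhaustively.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_PROTON = 1.00727646688
_CAM = 57.02146373


def brute_force_tryptic(
    sequence: str, max_missed: int, proline_rule: bool = True
) -> list[tuple[str, int, int, int]]:
    """All tryptic products as (sequence, start, end, missed) via substring
    enumeration: a substring is a product iff both boundaries are termini or
    cleavage points and it spans <= max_missed internal cleavage points."""
    n = len(sequence)
    cuts = {
        i
        for i in range(1, n)
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P")
    }
    bounds = cuts | {0, n}
    out = []
    for s in range(n):
        if s not in bounds:
            continue
        for e in range(s + 1, n + 1):
            if e not in bounds:
                continue
            internal = sum(1 for c in cuts if s < c < e)
            if internal <= max_missed:
                out.append((sequence[s:e], s, e, internal))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def brute_force_observable_count(
    sequence: str,
    mz_min: float = 450.0,
    mz_max: float = 1800.0,
    charges: tuple[int, ...] = (1, 2, 3),
    max_missed: int = 0,
    proline_rule: bool = True,
    carbamidomethyl: bool = True,
) -> int:
    """Distinct in-scan-range tryptic peptides, masses from pyteomics."""
    peptides = {p for p, _, _, _ in brute_force_tryptic(sequence, max_missed, proline_rule)}
    count = 0
    for pep in peptides:
        if set(pep) - _STANDARD:
            continue
        m = _pmass.fast_mass(pep)
        if carbamidomethyl:
            m += _CAM * pep.count("C")
        if any(mz_min <= (m + z * _PROTON) / z <= mz_max for z in charges):
            count += 1
    return count


def brute_force_peak_apexes(
    values, rel_height: float = 0.1, min_value: float = 0.01
) -> list[int]:
    """1-based apex slices of plateau local maxima whose topographic
    prominence reaches max(min_value, rel_height * max), by exhaustive scan."""
    v = list(map(float, values))
    n = len(v)
    top = max(v) if v else 0.0
    if top <= 0:
        return []
    threshold = max(min_value, rel_height * top)
    apexes = []
    for i in range(n):
        if i > 0 and v[i] == v[i - 1]:
            continue  # not a plateau's leftmost point
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if (i > 0 and v[i - 1] >= v[i]) or (j < n - 1 and v[j + 1] >= v[i]):
            continue
        if v[i] <= 0:
            continue
        # base per side = min between apex and nearest strictly higher value;
        # a side with no higher value (incl. the gel edge) contributes 0
        bases = []
        for rng in (range(i - 1, -1, -1), range(j + 1, n)):
            low = v[i]
            hit_higher = False
            for k in rng:
                if v[k] > v[i]:
                    hit_higher = True
                    break
                low = min(low, v[k])
            bases.append(low if hit_higher else 0.0)
        if v[i] - max(bases) >= threshold:
            apexes.append(i + 1)
    return apexes
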