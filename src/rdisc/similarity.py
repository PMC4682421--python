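"""Similarity measures between discrete Raman spectra.

Two peaks from different spectra are *matched* when their positions
differ by at most ``delta`` (default 10 cm^-1).  Peak matching is
one-to-one and maximizes the number of matched pairs, breaking ties by
minimal total position distance; on sorted position lists this optimum
is found by dynamic programming over non-crossing matchings.

Three scores are defined on a matching:

* ``s1`` — position Jaccard: ``|matches| / (n_a + n_b - |matches|)``,
  the tolerance-aware intersection-over-union of the two position sets.
* ``s2`` — Pearson correlation of the matched peak intensities; defined
  as 0 when there are fewer than 2 matched pairs or either matched
  intensity vector is constant.
* ``s`` — combined score ``sqrt(s1) * s2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import DiscreteSpectrum

__all__ = [
    "PeakMatching",
    "match_peaks",
    "s1_position",
    "s2_intensity",
    "combined_similarity",
]

DEFAULT_DELTA = 10.0


@dataclass(frozen=True)
class PeakMatching:
    """A one-to-one matching between the peaks of two discrete spectra."""

    pairs: tuple[tuple[int, int], ...]
    n_a: int
    n_b: int

    @property
    def n_matches(self) -> int:
        return len(self.pairs)


def match_peaks(a: DiscreteSpectrum, b: DiscreteSpectrum, delta: float = DEFAULT_DELTA) -> PeakMatching:
    """Maximum one-to-one matching of peaks within position tolerance ``delta``.

    Among all maximum-cardinality matchings the one with minimal total
    position distance is returned.  Because position lists are sorted and
    compatibility is an interval condition, an optimal matching is always
    non-crossing, so a quadratic DP over the two sorted lists is exact
    (verified against brute force in the test suite).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    pa = a.positions
    pb = b.positions
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        return PeakMatching((), na, nb)
    # DP over (i, j): best = (n_matches, -total_distance), lexicographic max
    NEG = (-1, 0.0)
    best = np.empty((na + 1, nb + 1), dtype=object)
    choice = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0: skip a, 1: skip b, 2: match
    for j in range(nb + 1):
        best[na, j] = (0, 0.0)
    for i in range(na + 1):
        best[i, nb] = (0, 0.0)
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            options = [(best[i + 1, j], 0), (best[i, j + 1], 1)]
            d = abs(pa[i] - pb[j])
            if d <= delta:
                m, negd = best[i + 1, j + 1]
                options.append(((m + 1, negd - d), 2))
            val, ch = max(options, key=lambda t: t[0])
            best[i, j] = val
            choice[i, j] = ch
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < na and j < nb:
        ch = choice[i, j]
        if ch == 2:
            pairs.append((i, j))
            i += 1
            j += 1
        elif ch == 0:
            i += 1
        else:
            j += 1
    return PeakMatching(tuple(pairs), na, nb)


def _s1_of(m: PeakMatching) -> float:
    union = m.n_a + m.n_b - m.n_matches
    return m.n_matches / union if union else 0.0


def _s2_of(m: PeakMatching, a: DiscreteSpectrum, b: DiscreteSpectrum) -> float:
    if m.n_matches < 2:
        return 0.0
    ia = a.intensities[[p[0] for p in m.pairs]]
    ib = b.intensities[[p[1] for p in m.pairs]]
    if np.ptp(ia) == 0 or np.ptp(ib) == 0:
        return 0.0
    r = np.corrcoef(ia, ib)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def s1_position(a: DiscreteSpectrum, b: DiscreteSpectrum, delta: float = DEFAULT_DELTA) -> float:
    """Position Jaccard similarity in [0, 1].

    ``|matches| / |union|`` with the union counted by inclusion-exclusion
    under the matching (``n_a + n_b - |matches|``).  Two empty spectra
    score 0 by definition.
    """
    return _s1_of(match_peaks(a, b, delta))


def s2_intensity(a: DiscreteSpectrum, b: DiscreteSpectrum, delta: float = DEFAULT_DELTA) -> float:
    """Pearson correlation of matched peak intensities, in [-1, 1].

    Defined as 0 when fewer than 2 peaks match (including the no-common-
    peaks case) or when either matched-intensity vector is constant.
    """
    return _s2_of(match_peaks(a, b, delta), a, b)


def combined_similarity(a: DiscreteSpectrum, b: DiscreteSpectrum, delta: float = DEFAULT_DELTA) -> float:
    """Combined score ``sqrt(s1) * s2`` (one matching, both scores)."""
    m = match_peaks(a, b, delta)
    return float(np.sqrt(_s1_of(m)) * _s2_of(m, a, b))
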