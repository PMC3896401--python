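"""Independent brute-force oracles used to check the analytical statistics.

These deliberately enumerate individuals / evaluate the discrete Fourier sum
directly, staying independent of the vectorised implementations they verify.
"""

from __future__ import annotations

import cmath
import itertools


def pairwise_within_enumerated(nA: int, na: int) -> float:
    """Mean difference over all unordered pairs of individuals, enumerated."""
    alleles = [1] * nA + [0] * na
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def pairwise_between_enumerated(demeX, demeY) -> float:
    """Mean difference over all cross-deme individual pairs, enumerated."""
    ax = [1] * demeX[0] + [0] * demeX[1]
    ay = [1] * demeY[0] + [0] * demeY[1]
    diffs = [a != b for a in ax for b in ay]
    return sum(diffs) / len(diffs)


def pairwise_corrected_enumerated(demeX, demeY) -> float:
    return pairwise_between_enumerated(demeX, demeY) - (
        pairwise_within_enumerated(*demeX) + pairwise_within_enumerated(*demeY)
    ) / 2.0


def fbar_direct(frequencies) -> float:
    """Amplitude-weighted mean spectral frequency via the O(N^2) DFT sum."""
    p = list(frequencies)
    n = len(p)
    assert n % 2 == 1
    num = 0.0
    den = 0.0
    for k in range(1, (n - 1) // 2 + 1):
        coeff = sum(p[j] * cmath.exp(-2j * cmath.pi * k * j / n) for j in range(n))
        amp = abs(coeff)
        num += (k / n) * amp
        den += amp
    if den == 0.0:
        return 0.0
    return num / den


def segment_scan(frequencies, atol: float = 0.0):
    """Run-length scanner over deme labels; returns (domains, clines) as
    lists of (label, start_row, width) / (start_row, width), 1-based."""

    def label(f):
        if f >= 1.0 - atol:
            return "A"
        if f <= atol:
            return "a"
        return "mix"

    domains, clines = [], []
    start = 0
    labels = [label(f) for f in frequencies]
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            width = i - start
            if labels[start] == "mix":
                clines.append((start + 1, width))
            else:
                domains.append((labels[start], start + 1, width))
            start = i
    return domains, clines
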