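"""Naive, independent reference implementations used only as test oracles.

Everything here is written as plain double loops straight from the defining
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def cheb(x, i, j, m):
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def naive_apen(x, m, r):
    """ApEn: log-averaged match fractions (self-matches included),
    phi_m - phi_{m+1}."""
    n = len(x)

    def phi(mm):
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            matches = sum(1 for j in range(count) if cheb(x, i, j, mm) <= r)
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def naive_saen(x, m, r):
    """SaEn: -ln(A/B) over N-m templates, self-matches excluded."""
    n = len(x)
    nt = n - m

    def frac(mm):
        total = 0.0
        for i in range(nt):
            matches = sum(
                1 for j in range(nt) if j != i and cheb(x, i, j, mm) <= r
            )
            total += matches / (nt - 1)
        return total / nt

    b = frac(m)
    a = frac(m + 1)
    return -math.log(a / b)


def naive_fuen(x, m, r):
    """FuEn: graded memberships exp(-ln2 (D/r)^2), self-pairs excluded,
    ln(phi_m) - ln(phi_{m+1})."""
    n = len(x)

    def phi(mm):
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            s = sum(
                math.exp(-math.log(2.0) * (cheb(x, i, j, mm) / r) ** 2)
                for j in range(count)
                if j != i
            )
            total += s / (count - 1)
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def straight_line_team(referred, svm_top, svm_second, dt, elm):
    """Literal transcription of decision principles I-III with fallback.

    Returns (label, principle).
    """
    if not referred:
        return svm_top, "I"
    if dt == svm_top or elm == svm_top:
        return svm_top, "II"
    if dt == svm_second or elm == svm_second:
        return svm_second, "III"
    return svm_top, "FALLBACK"


def entropy_bits(labels):
    n = len(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        out -= p * math.log2(p)
    return out


def naive_gain_ratio(x, y, threshold):
    """Gain ratio of the binary split x <= threshold, from the definitions."""
    pairs = sorted(zip(x, y))
    left = [lbl for v, lbl in pairs if v <= threshold]
    right = [lbl for v, lbl in pairs if v > threshold]
    n = len(y)
    labels = list(y)
    gain = entropy_bits(labels) - (
        len(left) / n * entropy_bits(left) + len(right) / n * entropy_bits(right)
    )
    split_info = entropy_bits(["L"] * len(left) + ["R"] * len(right))
    return gain / split_info
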