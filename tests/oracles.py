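"""Independent brute-force reference implementations used only by tests.

These deliberately use different mechanisms from the package (regex
matching, plain-python scans, two-pass formulas) so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import re

import numpy as np


def nonwear_oracle(counts, window: int = 60, max_interruption: int = 2) -> np.ndarray:
    """Wear flags via regex over the zero/nonzero string.

    A bout candidate is a maximal match of zeros with interior nonzero
    interruptions of at most ``max_interruption``; it is nonwear when its
    zero-minute count reaches ``window``.
    """
    s = "".join("0" if c == 0 else "1" for c in counts)
    wear = np.ones(len(s), dtype=bool)
    pattern = re.compile(r"0+(?:1{1,%d}0+)*" % max_interruption)
    for m in pattern.finditer(s):
        if m.group().count("0") >= window:
            wear[m.start() : m.end()] = False
    return wear


def mean_sd_oracle(values) -> tuple[float, float]:
    """Two-pass mean and sample SD computed with plain python arithmetic."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, float("nan")
    ss = sum((v - mean) ** 2 for v in values)
    return mean, (ss / (n - 1)) ** 0.5


def mage_oracle(values) -> float:
    """MAGE via exhaustive turning-point enumeration on the deduplicated series.

    Consecutive duplicates are removed (amplitudes are value differences, so
    plateau positions are irrelevant); every interior strict local extremum
    plus both endpoints is a turning point; excursions above one sample SD of
    the *original* block qualify, counted in the direction of the first
    qualifying excursion.
    """
    v = list(map(float, values))
    if len(v) < 3:
        return float("nan")
    _, sd = mean_sd_oracle(v)
    if sd == 0 or sd != sd:
        return float("nan")
    dedup = [v[0]]
    for x in v[1:]:
        if x != dedup[-1]:
            dedup.append(x)
    if len(dedup) < 2:
        return float("nan")
    tps = [dedup[0]]
    for i in range(1, len(dedup) - 1):
        if (dedup[i - 1] < dedup[i] > dedup[i + 1]) or (dedup[i - 1] > dedup[i] < dedup[i + 1]):
            tps.append(dedup[i])
    tps.append(dedup[-1])
    excursions = [(tps[i + 1] - tps[i]) for i in range(len(tps) - 1)]
    qualifying = [e for e in excursions if abs(e) > sd]
    if not qualifying:
        return float("nan")
    ascending = qualifying[0] > 0
    kept = [abs(e) for e in qualifying if (e > 0) == ascending]
    return sum(kept) / len(kept)


def vif_oracle(X: np.ndarray) -> np.ndarray:
    """VIF per column via explicit auxiliary least squares with lstsq."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
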