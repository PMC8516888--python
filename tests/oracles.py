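"""First-principles statistical oracles, independent of the library path.

These recompute Pearson correlation and the paired t-test from raw sums
and the t-distribution integral, for cross-checking the stats module.
"""

from __future__ import annotations

import math

from scipy.special import betainc


def t_sf(t: float, df: int) -> float:
    """Survival function of Student's t via the incomplete beta integral."""
    x = df / (df + t * t)
    p = 0.5 * betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def pearson_bruteforce(x, y) -> tuple[float, float]:
    """(r, two-tailed p) from raw product-moment sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return r, 2.0 * t_sf(abs(t), n - 2)


def paired_ttest_bruteforce(x, y) -> tuple[float, float]:
    """(t, two-tailed p) on differences, from raw sums."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2.0 * t_sf(abs(t), n - 1)
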