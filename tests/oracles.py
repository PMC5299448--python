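"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: exact rational
arithmetic for NSAF, explicit hypergeometric enumeration for the Fisher
test, and the textbook t-statistic formula for the paired t-test.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy import stats


def nsaf_bruteforce(counts: dict[str, int], lengths: dict[str, int]) -> dict[str, Fraction]:
    """Exact NSAF by direct evaluation of (S/L) / sum(S/L) in rationals."""
    saf = {a: Fraction(c, lengths[a]) for a, c in counts.items()}
    total = sum(saf.values())
    return {a: v / total for a, v in saf.items()}


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Enumerates every table with the same margins and sums the point
    hypergeometric probabilities not exceeding the observed table's
    (with a tiny relative tolerance against float round-off).
    """
    row1, col1, total = a + b, a + c, a + b + c + d

    def point_prob(x: int) -> float:
        return (
            math.comb(col1, x)
            * math.comb(total - col1, row1 - x)
            / math.comb(total, row1)
        )

    p_obs = point_prob(a)
    lo = max(0, row1 - (total - col1))
    hi = min(row1, col1)
    return min(
        1.0,
        sum(p for x in range(lo, hi + 1) if (p := point_prob(x)) <= p_obs * (1 + 1e-9)),
    )


def paired_t_two_sided(tumor: list[float], adjacent: list[float]) -> float:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-tailed via the t CDF."""
    d = [x - y for x, y in zip(tumor, adjacent)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return 2.0 * stats.t.sf(abs(t), df=n - 1)
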