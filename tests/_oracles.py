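"""Brute-force oracle implementations, independent of the package.

Direct textbook formulas (explicit sums, two-way ANOVA by loops) used to
cross-check the package's statistics. Deliberately naive and slow.
"""

from __future__ import annotations

import math


def pearson_oracle(x, y) -> float:
    """Pearson r from the raw covariance formula."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ols_oracle(x, y) -> tuple[float, float]:
    """(slope, intercept) of y on x from the normal equations."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    return slope, my - slope * mx


def icc_a1_oracle(x, y) -> float:
    """ICC(A,1) from an explicit two-way ANOVA on the n x 2 table."""
    table = [[float(a), float(b)] for a, b in zip(x, y)]
    n = len(table)
    k = 2
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def screen_oracle(values: list[float], k: float = 2.0) -> list[int]:
    """Indices a brute-force percentage-difference screen would remove from a
    single series (pooled SD over this series' signed deltas only)."""
    n = len(values)
    deltas = []
    per_point = {}
    for i in range(1, n - 1):
        dp = 100.0 * (values[i] - values[i - 1]) / values[i - 1]
        dn = 100.0 * (values[i] - values[i + 1]) / values[i + 1]
        per_point[i] = (dp, dn)
        deltas.extend([dp, dn])
    m = sum(deltas) / len(deltas)
    sd = math.sqrt(sum((d - m) ** 2 for d in deltas) / (len(deltas) - 1))
    cut = k * sd
    return [i for i, (dp, dn) in per_point.items()
            if abs(dp) > cut and abs(dn) > cut]
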