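"""Independent brute-force oracles, coded from the defining formulas with
explicit loops — deliberately naive so they share nothing with the
implementation they check."""

from __future__ import annotations

import math


def two_pass_variance(row) -> float:
    n = len(row)
    mean = sum(row) / n
    return sum((x - mean) ** 2 for x in row) / (n - 1)


def matrix_margins(values):
    """Row means, column means and grand mean by explicit double loops."""
    g, n = len(values), len(values[0])
    row_means = [sum(values[i][j] for j in range(n)) / n for i in range(g)]
    col_means = [sum(values[i][j] for i in range(g)) / g for j in range(n)]
    grand = sum(sum(r) for r in values) / (g * n)
    return row_means, col_means, grand


def ecovalence(values, i) -> float:
    row_means, col_means, grand = matrix_margins(values)
    n = len(values[0])
    return sum(
        (values[i][j] - row_means[i] - col_means[j] + grand) ** 2 for j in range(n)
    )


def interaction_ss(values) -> float:
    return sum(ecovalence(values, i) for i in range(len(values)))


def two_way_ss(values):
    """SS_env, SS_gen, SS_interaction from the margin decomposition."""
    g, n = len(values), len(values[0])
    row_means, col_means, grand = matrix_margins(values)
    ss_env = g * sum((cm - grand) ** 2 for cm in col_means)
    ss_gen = n * sum((rm - grand) ** 2 for rm in row_means)
    return ss_env, ss_gen, interaction_ss(values)


def shukla_paper(values, i) -> float:
    n = len(values[0])
    return ecovalence(values, i) / (n - 1)


def shukla_classical(values, i) -> float:
    g, n = len(values), len(values[0])
    w = [ecovalence(values, m) for m in range(g)]
    return (g * (g - 1) * w[i] - sum(w)) / ((g - 1) * (g - 2) * (n - 1))


def least_squares_line(y, x):
    """Slope, deviation mean square (n-2) and R² via normal equations."""
    n = len(y)
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    b = sxy / sxx
    ss_res = sum((yi - ybar - b * (xi - xbar)) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return b, ss_res / (n - 2), 1.0 - ss_res / ss_tot


def pearson_r(x, y) -> float:
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((a - xbar) * (b - ybar) for a, b in zip(x, y))
    den = math.sqrt(sum((a - xbar) ** 2 for a in x)) * math.sqrt(
        sum((b - ybar) ** 2 for b in y)
    )
    return num / den


def harmonic_mean(ranks) -> float:
    return len(ranks) / sum(1.0 / r for r in ranks)


def angular_sector_scan(ray_angles_deg, angle_deg) -> int:
    """Which sector (index into sorted rays) contains the angle, by a 0.1-degree
    brute-force walk counter-clockwise from the nearest ray at or below it."""
    rays = sorted(a % 360.0 for a in ray_angles_deg)
    a = angle_deg % 360.0
    best = len(rays) - 1  # sector [last ray, first ray) wrapping
    for idx, ray in enumerate(rays):
        if ray <= a + 1e-12:
            best = idx
    return best
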