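"""Independent brute-force oracles used only by the tests.

These deliberately avoid the vector primitives of the package: angles come
from the law of cosines on squared distances, point-line distances from the
implicit-form formula |ax + by + c| / sqrt(a^2 + b^2), projections from
solving the 1-D parametric minimisation directly, and the ICC from explicit
two-way ANOVA mean squares.
"""

import math


def dist(p, q):
    return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)


def angle_at_vertex(a, v, b):
    """Law-of-cosines angle (degrees) at v in triangle a-v-b."""
    c2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
    u2 = (a[0] - v[0]) ** 2 + (a[1] - v[1]) ** 2
    w2 = (b[0] - v[0]) ** 2 + (b[1] - v[1]) ** 2
    cosang = (u2 + w2 - c2) / (2 * math.sqrt(u2) * math.sqrt(w2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def point_line_distance(p, a, b):
    """|ax + by + c| / sqrt(a^2 + b^2) for the line through a and b."""
    la = b[1] - a[1]
    lb = a[0] - b[0]
    lc = -(la * a[0] + lb * a[1])
    return abs(la * p[0] + lb * p[1] + lc) / math.sqrt(la**2 + lb**2)


def acute_angle_between_lines(a1, a2, b1, b2):
    """Acute angle (degrees) between two lines given by point pairs."""
    t1 = math.atan2(a2[1] - a1[1], a2[0] - a1[0])
    t2 = math.atan2(b2[1] - b1[1], b2[0] - b1[0])
    d = abs(t1 - t2) % math.pi
    return math.degrees(min(d, math.pi - d))


def project_param(p, a, b):
    """Parameter t in [?, ?] minimising |a + t(b-a) - p| (closed form)."""
    dx, dy = b[0] - a[0], b[1] - a[1]
    return ((p[0] - a[0]) * dx + (p[1] - a[1]) * dy) / (dx * dx + dy * dy)


def icc2_1(x, y):
    """ICC(2,1) absolute agreement from explicit two-way ANOVA mean squares."""
    n = len(x)
    k = 2
    grand = (sum(x) + sum(y)) / (n * k)
    row_means = [(a + b) / 2 for a, b in zip(x, y)]
    col_means = [sum(x) / n, sum(y) / n]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for col in (x, y) for v in col)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
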