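"""Independent scalar oracles used by the tests.

Everything here is a direct, loop-based transcription of the defining
equations — deliberately sharing no code with the package — so that
agreement is evidence, not tautology.
"""

import math

# Same published sRGB matrix the package uses; the transcription below is
# otherwise independent (scalar math, explicit loops).
_M = (
    (0.4124, 0.3576, 0.1805),
    (0.2126, 0.7152, 0.0722),
    (0.0193, 0.1192, 0.9505),
)
_WHITE = tuple(sum(row) for row in _M)


def srgb_decode_scalar(v: float) -> float:
    if v <= 0.04045:
        return v / 12.92
    return ((v + 0.055) / 1.055) ** 2.4


def _cie_f(t: float) -> float:
    d = 6.0 / 29.0
    if t > d**3:
        return t ** (1.0 / 3.0)
    return t / (3.0 * d * d) + 4.0 / 29.0


def srgb_pixel_to_lab(r: float, g: float, b: float):
    """One pixel through sRGB → linear → XYZ → CIELAB, all scalar."""
    rl, gl, bl = (srgb_decode_scalar(v) for v in (r, g, b))
    xyz = [
        _M[i][0] * rl + _M[i][1] * gl + _M[i][2] * bl
        for i in range(3)
    ]
    fx, fy, fz = (_cie_f(xyz[i] / _WHITE[i]) for i in range(3))
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def mean_sd_loop(values):
    """Brute-force mean and population SD."""
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / n
    return m, math.sqrt(var)


def chi_square_loop(counts):
    """Pearson chi-square by direct summation of (O−E)²/E."""
    rows = len(counts)
    cols = len(counts[0])
    total = sum(sum(row) for row in counts)
    row_sums = [sum(row) for row in counts]
    col_sums = [sum(counts[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            e = row_sums[i] * col_sums[j] / total
            stat += (counts[i][j] - e) ** 2 / e
    return stat, (rows - 1) * (cols - 1)


def pooled_t_ci(mean1, sd1, n1, mean2, sd2, n2, tcrit):
    """Closed-form pooled-variance mean difference and CI half-width."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    return diff, se, diff - tcrit * se, diff + tcrit * se


def covariance_loop(xs, ys):
    """Population covariance by explicit loop."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
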