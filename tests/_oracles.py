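"""Independent brute-force implementations of the track metrics.

Deliberately written with plain Python loops and the math module, sharing
no code with the package, so that they can serve as oracles.
"""

import math


def inst_speeds(t, x, y):
    out = []
    for i in range(len(t) - 1):
        d = math.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
        out.append(d / (t[i + 1] - t[i]))
    return out


def path_length(x, y):
    total = 0.0
    for i in range(len(x) - 1):
        total += math.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
    return total


def mean_speed(t, x, y):
    return path_length(x, y) / (t[-1] - t[0])


def speed_dynamic(t, x, y):
    v = inst_speeds(t, x, y)
    n = len(v)
    m = sum(v) / n
    ss = 0.0
    for s in v:
        ss += (s - m) ** 2
    return math.sqrt(ss / (n - 1))


def straightness(x, y):
    net = math.sqrt((x[-1] - x[0]) ** 2 + (y[-1] - y[0]) ** 2)
    p = path_length(x, y)
    return min(max(net / p, 0.0), 1.0)


def direction_change_rate(t, x, y, threshold_deg=30.0, min_step=0.3):
    events = 0
    for i in range(len(t) - 2):
        ax, ay = x[i + 1] - x[i], y[i + 1] - y[i]
        bx, by = x[i + 2] - x[i + 1], y[i + 2] - y[i + 1]
        la = math.sqrt(ax * ax + ay * ay)
        lb = math.sqrt(bx * bx + by * by)
        if la <= min_step or lb <= min_step:
            continue
        angle = abs(math.atan2(ax * by - ay * bx, ax * bx + ay * by))
        if angle > math.radians(threshold_deg):
            events += 1
    return events / (t[-1] - t[0])


def welch(a, b):
    """Closed-form Welch t statistic, two-sided p, Welch-Satterthwaite df."""
    import scipy.stats as st

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * st.t.sf(abs(t), df)
    return t, p, df


def random_track(rng, n=None):
    """A random but well-formed track as (t, x, y) arrays."""
    import numpy as np

    if n is None:
        n = int(rng.integers(3, 80))
    dt = 1.0 / 7.0
    t = np.arange(n) * dt
    x = np.cumsum(rng.normal(0.0, 1.2, size=n))
    y = np.cumsum(rng.normal(0.0, 1.2, size=n))
    return t, x, y
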