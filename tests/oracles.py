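"""Independent brute-force oracles used to cross-check the feature bank."""

import numpy as np
from scipy import stats


def poincare_oracle(x, m=1):
    """Direct rotation of the lag-m return map and per-triplet areas."""
    pts = np.array([(x[i], x[i + m]) for i in range(len(x) - m)])
    rot = np.array([[np.cos(np.pi / 4), np.sin(np.pi / 4)],
                    [-np.sin(np.pi / 4), np.cos(np.pi / 4)]])
    proj = pts @ rot.T
    sd2 = np.std(proj[:, 0], ddof=1)  # along line of identity
    sd1 = np.std(proj[:, 1], ddof=1)  # perpendicular
    areas = []
    for i in range(len(pts) - 2):
        (x1, y1), (x2, y2), (x3, y3) = pts[i], pts[i + 1], pts[i + 2]
        areas.append(0.5 * ((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)))
    ccm = np.mean(areas) / (np.pi * sd1 * sd2)
    return sd1, sd2, ccm


def higuchi_oracle(x, kmax=10):
    """Textbook Higuchi construction with explicit loops."""
    n = len(x)
    logs = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            n_i = (n - 1 - m) // k
            total = sum(abs(x[m + i * k] - x[m + (i - 1) * k])
                        for i in range(1, n_i + 1))
            lengths.append(total * (n - 1) / (n_i * k) / k)
        logs.append(np.log(np.mean(lengths)))
    ks = np.arange(1, kmax + 1)
    return np.polyfit(np.log(1.0 / ks), logs, 1)[0]


def kruskal_p_oracle(*groups):
    """H statistic from first principles (ranks + chi-square), no ties."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return stats.chi2.sf(h, df=len(groups) - 1)
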