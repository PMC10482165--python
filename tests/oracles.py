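"""Independent reference implementations used as test oracles.

Everything here is deliberately written as literal, loop-based arithmetic
with no shared code with the package: dict-based pair counting for the
GLCM, plain formula transcriptions for the spectral indices and model
metrics.  Slow but unambiguous.
"""

from __future__ import annotations

import math

import numpy as np

FEATURES = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEM", "COR")

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_window_features(q, valid, window, distance, angle, symmetric):
    """GLCM features of one window by explicit pair enumeration.

    Returns a dict feature -> value, or None if the window holds no
    countable pair.  ``q`` and ``valid`` are ``window x window`` arrays;
    pixels with q < 0 are ineligible.
    """
    dr0, dc0 = ANGLE_OFFSETS[angle]
    dr, dc = dr0 * distance, dc0 * distance
    counts: dict[tuple[int, int], float] = {}
    n = 0
    for r in range(window):
        for c in range(window):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < window and 0 <= c2 < window):
                continue
            if q[r, c] < 0 or q[r2, c2] < 0:
                continue
            if not (valid[r, c] and valid[r2, c2]):
                continue
            i, j = int(q[r, c]), int(q[r2, c2])
            counts[(i, j)] = counts.get((i, j), 0.0) + 1.0
            if symmetric:
                counts[(j, i)] = counts.get((j, i), 0.0) + 1.0
            n += 1
    if n == 0:
        return None
    total = sum(counts.values())
    P = {cell: v / total for cell, v in counts.items()}

    mea = sum(i * p for (i, j), p in P.items())
    var = sum((i - mea) ** 2 * p for (i, j), p in P.items())
    hom = sum(p / (1.0 + (i - j) ** 2) for (i, j), p in P.items())
    con = sum((i - j) ** 2 * p for (i, j), p in P.items())
    dis = sum(abs(i - j) * p for (i, j), p in P.items())
    ent = -sum(p * math.log(p) for p in P.values() if p > 0)
    sem = sum(p * p for p in P.values())

    mu_i = sum(i * p for (i, j), p in P.items())
    mu_j = sum(j * p for (i, j), p in P.items())
    var_i = sum((i - mu_i) ** 2 * p for (i, j), p in P.items())
    var_j = sum((j - mu_j) ** 2 * p for (i, j), p in P.items())
    if var_i * var_j <= 1e-20:
        cor = float("nan")
    else:
        cov = sum((i - mu_i) * (j - mu_j) * p for (i, j), p in P.items())
        cor = cov / math.sqrt(var_i * var_j)
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con,
            "DIS": dis, "ENT": ent, "SEM": sem, "COR": cor}


def brute_sliding_features(q, eligible, window, distance, angle, symmetric):
    """Feature planes [feature, row, col] via per-window brute enumeration."""
    H, W = q.shape
    h = window // 2
    out = np.full((len(FEATURES), H, W), np.nan)
    for r in range(h, H - h):
        for c in range(h, W - h):
            sub_q = q[r - h:r + h + 1, c - h:c + h + 1]
            sub_v = eligible[r - h:r + h + 1, c - h:c + h + 1]
            feats = brute_window_features(sub_q, sub_v, window, distance,
                                          angle, symmetric)
            if feats is None:
                continue
            for f, name in enumerate(FEATURES):
                out[f, r, c] = feats[name]
    return out


def spreadsheet_indices(r450, r530, r570, r675, r730, r850):
    """The nine index formulas transcribed literally, one expression each."""
    def div(a, b):
        return a / b if b != 0 else float("nan")

    return {
        "NDVI": div(r850 - r675, r850 + r675),
        "NDRE": div(r850 - r730, r850 + r730),
        "EVI2": div(2.5 * (r850 - r675), 1 + r850 + 2.4 * r675),
        "CI_green": div(r850, r530) - 1 if r530 != 0 else float("nan"),
        "CI_red_edge": div(r850, r730) - 1 if r730 != 0 else float("nan"),
        "NEI": div((1.8 + div(r675, r850)) * r730 + r675, r850 + r675),
        "OSAVI": div(r850 - r675, r850 + r675 + 0.16),
        "DATT": div(r850 - r730, r850 - r675),
        "TBVI": div(r850 - r730 + 2 * r450, r850 + r730 - 2 * r450),
    }
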