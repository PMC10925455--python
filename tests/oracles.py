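"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code path with the
package: distances come from an explicit min-over-tumor-pixels search,
hole filling from a border flood fill, the t-distribution tail from
numerical integration of its density, and Spearman's rho from hand-built
average ranks plus the raw Pearson formula.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.integrate import quad
from scipy.spatial.distance import cdist

# zone codes mirrored here (fixed public constants)
OUTSIDE, INTRA_POS, INTRA_NEG, PERI_POS, PERI_NEG = 0, 1, 2, 3, 4


def brute_distance_um(mask_bool: np.ndarray, resolution: float) -> np.ndarray:
    """Min Euclidean pixel-center distance to any True pixel, exhaustively."""
    h, w = mask_bool.shape
    out = np.full((h, w), np.inf)
    targets = np.argwhere(mask_bool)
    if targets.size == 0:
        return out
    pix = np.argwhere(np.ones((h, w), dtype=bool))
    d = cdist(pix.astype(float), targets.astype(float)).min(axis=1)
    return (d * resolution).reshape(h, w)


def flood_fill_background(tumor: np.ndarray) -> np.ndarray:
    """Background pixels reachable from the border via 4-connectivity (BFS)."""
    h, w = tumor.shape
    reach = np.zeros((h, w), dtype=bool)
    dq: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not tumor[r, c] and not reach[r, c]:
                reach[r, c] = True
                dq.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not tumor[r, c] and not reach[r, c]:
                reach[r, c] = True
                dq.append((r, c))
    while dq:
        r, c = dq.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not tumor[rr, cc] \
                    and not reach[rr, cc]:
                reach[rr, cc] = True
                dq.append((rr, cc))
    return reach


def brute_zones(
    pos: np.ndarray, neg: np.ndarray, resolution: float, band_um: float,
    tie_break: str = "pos",
) -> np.ndarray:
    """Exhaustive zone assignment with the same contracts as the package.

    Intratumoral = tumor pixels, pixels 8-adjacent to tumor, and pixels
    enclosed by tumor (not border-reachable); each non-tumor intratumoral
    pixel takes the class of its nearest tumor pixel (tie -> tie_break).
    Peritumoral = other non-tumor pixels within the band, classed the same
    way.
    """
    h, w = pos.shape
    tumor = pos | neg
    dpos = brute_distance_um(pos, resolution)
    dneg = brute_distance_um(neg, resolution)

    if tie_break == "pos":
        closer_pos = dpos <= dneg
    else:
        closer_pos = dpos < dneg

    enclosed = ~tumor & ~flood_fill_background(tumor)
    contact = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if tumor[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and tumor[rr, cc]:
                        contact[r, c] = True
    zone = np.full((h, w), OUTSIDE, dtype=np.uint8)
    intra_extra = enclosed | contact
    zone[intra_extra & closer_pos] = INTRA_POS
    zone[intra_extra & ~closer_pos] = INTRA_NEG
    zone[pos] = INTRA_POS
    zone[neg] = INTRA_NEG
    dmin = np.minimum(dpos, dneg)
    peri = ~tumor & ~intra_extra & (dmin <= band_um)
    zone[peri & closer_pos] = PERI_POS
    zone[peri & ~closer_pos] = PERI_NEG
    return zone


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided t-test p-value via numerical integration of the t density."""
    if not math.isfinite(t):
        return 0.0

    def density(x: float) -> float:
        c = math.gamma((df + 1) / 2.0) / (
            math.sqrt(df * math.pi) * math.gamma(df / 2.0)
        )
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(density, abs(t), np.inf, epsabs=1e-14, epsrel=1e-13)
    return 2.0 * tail


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean of their positions."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (the definition of Spearman's rho)."""
    rx = average_ranks(np.asarray(x, dtype=float))
    ry = average_ranks(np.asarray(y, dtype=float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for Spearman's rho via the t approximation."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return t_two_sided_p(t, n - 2)
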