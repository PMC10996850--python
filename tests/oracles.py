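"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized/labeling machinery of the package:
explicit per-pixel loops, BFS flood fill, and exhaustive searches.
"""

from collections import deque

import numpy as np


def brute_detect(slc, min_excess=5, min_area=5):
    """Per-pixel mirror comparison + BFS flood-fill labeling (8-connectivity).

    Returns a list of sets of (row, col) coordinates, sorted by region max
    HU descending (ties by area descending).
    """
    n_rows, n_cols = slc.pixels.shape
    hyper = np.zeros((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            if not slc.brain_mask[r, c]:
                continue
            mc = 2 * slc.midline - c
            if not (0 <= mc < n_cols):
                continue
            if int(slc.pixels[r, c]) - int(slc.pixels[r, mc]) >= min_excess:
                hyper[r, c] = True

    seen = np.zeros_like(hyper)
    regions = []
    for r in range(n_rows):
        for c in range(n_cols):
            if not hyper[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                rr, cc = queue.popleft()
                comp.add((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < n_rows and 0 <= nc < n_cols
                                and hyper[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            if len(comp) >= min_area:
                regions.append(comp)
    regions.sort(key=lambda s: (-max(int(slc.pixels[p]) for p in s), -len(s)))
    return regions


def brute_best_disc(admissible):
    """Exhaustive search for the largest pixel-disc inside a boolean mask.

    Tries every admissible center and every realizable radius (distances
    between pixel centers); returns (n_pixels, center, radius) of a best disc.
    """
    coords = np.argwhere(admissible)
    n_rows, n_cols = admissible.shape
    best = (0, None, -1.0)
    radii = sorted({
        float(np.hypot(dr, dc))
        for dr in range(n_rows)
        for dc in range(n_cols)
    })
    for r0, c0 in coords:
        for rad in radii:
            ok = True
            count = 0
            for r in range(n_rows):
                for c in range(n_cols):
                    if np.hypot(r - r0, c - c0) <= rad + 1e-9:
                        if admissible[r, c]:
                            count += 1
                        else:
                            ok = False
                            break
                if not ok:
                    break
            if ok and count > best[0]:
                best = (count, (int(r0), int(c0)), rad)
    return best


def chi2_observed_expected(a, b, c, d):
    """Pearson chi-square via the sum((O-E)^2 / E) formulation."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    return float(((obs - expected) ** 2 / expected).sum())
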