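"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive: a stack-based flood fill for connected
components, exhaustive rank-assignment enumeration for the Mann-Whitney
test, and explicit pixel enumeration for rasterized disks.  None of them
share code with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def flood_fill_components(mask: np.ndarray, min_area: int = 1) -> list[set[tuple[int, int]]]:
    """8-connected components of a boolean mask as pixel sets, dropping
    components with fewer than ``min_area`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                comp = set()
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return [c for c in comps if len(c) >= min_area]


from functools import lru_cache


@lru_cache(maxsize=None)
def _u_null_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """U for every assignment of n1 of the pooled ranks to group a."""
    idx = range(n1 + n2)
    out = []
    for chosen in combinations(idx, n1):
        chosen_set = set(chosen)
        u = sum(1 for i in chosen for j in idx if j not in chosen_set and i > j)
        out.append(u)
    return tuple(out)


def mann_whitney_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U and p for tie-free samples by
    enumerating every assignment of the pooled ranks to group a."""
    a = list(map(float, a))
    b = list(map(float, b))
    n1, n2 = len(a), len(b)
    assert len(set(a + b)) == n1 + n2, "enumeration oracle requires tie-free data"
    u_obs = sum(1 for x in a for y in b if x > y)
    dist = _u_null_distribution(n1, n2)
    total = comb(n1 + n2, n1)
    le = sum(1 for u in dist if u <= u_obs)
    ge = sum(1 for u in dist if u >= u_obs)
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(u_obs), p


def disk_pixels(center_row: int, center_col: int, radius: int) -> set[tuple[int, int]]:
    """All integer pixels whose centre lies within ``radius`` of the disk
    centre (Euclidean, inclusive), enumerated over the bounding square."""
    out = set()
    for r in range(center_row - radius, center_row + radius + 1):
        for c in range(center_col - radius, center_col + radius + 1):
            if (r - center_row) ** 2 + (c - center_col) ** 2 <= radius**2:
                out.add((r, c))
    return out
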