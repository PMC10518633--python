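"""Brute-force reference implementations used to cross-check fast paths."""

from collections import deque

import numpy as np


def local_mean_threshold_oracle(volume: np.ndarray, window: int, c: float) -> np.ndarray:
    """Recompute every window mean by direct summation (edge-replicate pad).

    Windows span floor((w-1)/2) pixels before and ceil((w-1)/2) after the
    centre, per 2D slice; foreground is strictly intensity > mean + c.
    """
    vol = np.asarray(volume, dtype=np.float64)
    before = (window - 1) // 2
    after = window - 1 - before
    out = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        sl = np.pad(vol[z], ((before, after), (before, after)), mode="edge")
        for y in range(vol.shape[1]):
            for x in range(vol.shape[2]):
                mean = sl[y:y + window, x:x + window].mean()
                out[z, y, x] = vol[z, y, x] > mean + c
    return out


_NEIGHBOURS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[int]:
    """Component sizes by breadth-first flood fill (sorted descending)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    sizes = []
    nbrs = _NEIGHBOURS[connectivity]
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            z, y, x = q.popleft()
            size += 1
            for dz, dy, dx in nbrs:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                        and 0 <= p[2] < mask.shape[2]
                        and mask[p] and not seen[p]):
                    seen[p] = True
                    q.append(p)
        sizes.append(size)
    return sorted(sizes, reverse=True)
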