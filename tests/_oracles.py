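"""Independent brute-force reference implementations used by the tests."""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_sizes(supra: np.ndarray) -> np.ndarray:
    """Connected-component sizes (26-neighbourhood) via BFS; returns a map
    of cluster size per voxel (0 outside the suprathreshold set)."""
    shape = supra.shape
    sizes = np.zeros(shape, dtype=float)
    seen = np.zeros(shape, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in np.argwhere(supra):
        start = tuple(start)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        members = [start]
        while queue:
            cur = queue.popleft()
            for off in offsets:
                nxt = tuple(np.add(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nxt, shape)):
                    continue
                if supra[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
                    members.append(nxt)
        for m in members:
            sizes[m] = len(members)
    return sizes


def tfce_bruteforce(stat: np.ndarray, e=0.5, h=2.0, dh=None, n_steps=100):
    """Per-threshold explicit labelling TFCE oracle (both polarities)."""
    stat = np.asarray(stat, dtype=float)
    peak = float(np.max(np.abs(stat)))
    if peak == 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = peak / n_steps
    out = np.zeros_like(stat)
    for sign in (1.0, -1.0):
        part = np.where(sign * stat > 0, sign * stat, 0.0)
        top = part.max()
        height = dh
        while height <= top + 1e-12:
            sizes = flood_fill_sizes(part >= height)
            out += sign * (sizes**e) * (height**h) * dh * (part >= height)
            height += dh
    return out
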