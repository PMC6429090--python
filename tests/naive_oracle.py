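"""Naive reference implementations of the segmentation pipeline.

Deliberately literal: per-pixel double loops for the disk mean, an explicit
inequality, and breadth-first flood fill for components.  Used to check the
vectorized pipeline pixel-for-pixel; shares no code with it.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def naive_disk_mean(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel mean over the in-bounds disk, by explicit enumeration."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    out = np.empty((h, w))
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    for r in range(h):
        for c in range(w):
            total = 0.0
            count = 0
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    total += img[rr, cc]
                    count += 1
            out[r, c] = total / count
    return out


def naive_threshold(convolved: np.ndarray, original: np.ndarray, alpha: float) -> np.ndarray:
    h, w = original.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = convolved[r, c] > alpha * float(original[r, c])
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int = 4) -> list[list[tuple[int, int]]]:
    """Connected components by BFS flood fill; returns pixel lists."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = []
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    pr, pc = queue.popleft()
                    comp.append((pr, pc))
                    for dr, dc in nbrs:
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                components.append(comp)
    return components


def naive_size_filter(mask: np.ndarray, min_size: int, connectivity: int = 4) -> np.ndarray:
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_size:
            for r, c in comp:
                out[r, c] = True
    return out


def naive_segment(
    img: np.ndarray, radius: int, alpha: float, min_size: int, connectivity: int = 4
) -> np.ndarray:
    conv = naive_disk_mean(img, radius)
    mask = naive_threshold(conv, img, alpha)
    return naive_size_filter(mask, min_size, connectivity)
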