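"""Independent brute-force oracles for geometry and morphology.

Deliberately naive per-pixel implementations, kept free of scipy/skimage so
they stay independent of the code paths they validate.
"""

import numpy as np


def point_in_polygon(r, c, vertices):
    """Even-odd (crossing number) test for one point."""
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if r1 == r2:
            continue
        if (r1 > r) != (r2 > r) and c < (c2 - c1) * (r - r1) / (r2 - r1) + c1:
            inside = not inside
    return inside


def rasterize_polygon(vertices, height, width):
    out = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            out[r, c] = point_in_polygon(r, c, vertices)
    return out


def _get(mask, r, c, outside):
    h, w = mask.shape
    if 0 <= r < h and 0 <= c < w:
        return mask[r, c]
    return outside


def dilate_once(mask):
    """3x3 dilation, outside the frame treated as background."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = any(
                _get(mask, r + dr, c + dc, False)
                for dr in (-1, 0, 1) for dc in (-1, 0, 1))
    return out


def erode_once(mask, border=True):
    """3x3 erosion; ``border`` is the value assumed outside the frame."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(
                _get(mask, r + dr, c + dc, border)
                for dr in (-1, 0, 1) for dc in (-1, 0, 1))
    return out


def dilate(mask, n):
    for _ in range(n):
        mask = dilate_once(mask)
    return mask


def erode(mask, n, border=True):
    for _ in range(n):
        mask = erode_once(mask, border)
    return mask


def enlarge(mask, dist):
    """All pixels within Euclidean distance ``dist`` of the foreground."""
    h, w = mask.shape
    fg = np.argwhere(mask)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            out[r, c] = any((r - fr) ** 2 + (c - fc) ** 2 <= dist ** 2
                            for fr, fc in fg)
    return out


def label_components(mask, connectivity=8):
    """Connected-component labeling by flood fill; returns (labels, n)."""
    if connectivity == 8:
        neighbours = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                      if (dr, dc) != (0, 0)]
    else:
        neighbours = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    n = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                n += 1
                stack = [(r0, c0)]
                labels[r0, c0] = n
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neighbours:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w
                                and mask[rr, cc] and labels[rr, cc] == 0):
                            labels[rr, cc] = n
                            stack.append((rr, cc))
    return labels, n


def fill_holes(mask):
    """Foreground plus any background region not connected to the frame.

    Background connectivity is 4 — the dual of the 8-connected foreground.
    """
    bg_labels, n = label_components(~mask, connectivity=4)
    h, w = mask.shape
    border_labels = set(bg_labels[0]) | set(bg_labels[-1]) \
        | set(bg_labels[:, 0]) | set(bg_labels[:, -1])
    out = mask.copy()
    for i in range(1, n + 1):
        if i not in border_labels:
            out |= bg_labels == i
    return out


def select_component(mask, min_px, max_px):
    """Size-gated central-component selection, holes filled.

    Returns None when no component passes the gate.  Tie-break mirrors the
    documented policy: nearest centroid to center, then largest, then lowest
    label.
    """
    labels, n = label_components(mask)
    h, w = mask.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    best = None
    for i in range(1, n + 1):
        pts = np.argwhere(labels == i)
        size = len(pts)
        if not min_px <= size <= max_px:
            continue
        cy, cx = pts.mean(axis=0)
        d = ((cy - center[0]) ** 2 + (cx - center[1]) ** 2) ** 0.5
        key = (d, -size, i)
        if best is None or key < best[0]:
            best = (key, i)
    if best is None:
        return None
    return fill_holes(labels == best[1])
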