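"""Independent brute-force oracles used to validate the implementation.

Everything here is written against the mathematical definitions with plain
Python loops (or, for the exhaustive batched sweeps, raw array shifts) and
deliberately shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

# Window conventions (must match the package's documented convention):
# erosion samples offsets -(s//2) .. s-1-s//2; dilation uses the reflected
# window.  For odd s the two coincide and are centered.


def erosion_offsets(size: int) -> list[int]:
    return list(range(-(size // 2), size - size // 2))


def dilation_offsets(size: int) -> list[int]:
    return [-o for o in reversed(erosion_offsets(size))]


def erode_loop(mask: np.ndarray, size: int) -> np.ndarray:
    """Sliding-window erosion; out-of-image pixels count as background."""
    mask = np.asarray(mask, dtype=bool)
    if size <= 1:
        return mask.copy()
    h, w = mask.shape
    offs = erosion_offsets(size)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            out[i, j] = all(
                0 <= i + a < h and 0 <= j + b < w and mask[i + a, j + b]
                for a in offs
                for b in offs
            )
    return out


def dilate_loop(mask: np.ndarray, size: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if size <= 1:
        return mask.copy()
    h, w = mask.shape
    offs = dilation_offsets(size)
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            out[i, j] = any(
                0 <= i + a < h and 0 <= j + b < w and mask[i + a, j + b]
                for a in offs
                for b in offs
            )
    return out


def fill_loop(mask: np.ndarray, size: int) -> np.ndarray:
    return erode_loop(dilate_loop(mask, size), size)


def clean_loop(mask: np.ndarray, size: int) -> np.ndarray:
    return dilate_loop(erode_loop(mask, size), size)


# --- batched shift-based variants for exhaustive sweeps -------------------

def erode_batch(masks: np.ndarray, size: int) -> np.ndarray:
    """Erosion of a (N, h, w) stack via explicit shifts of a padded array."""
    if size <= 1:
        return masks.copy()
    pad = size
    p = np.pad(masks, ((0, 0), (pad, pad), (pad, pad)), constant_values=False)
    h, w = masks.shape[1:]
    out = np.ones_like(masks)
    for a in erosion_offsets(size):
        for b in erosion_offsets(size):
            out &= p[:, pad + a : pad + a + h, pad + b : pad + b + w]
    return out


def dilate_batch(masks: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return masks.copy()
    pad = size
    p = np.pad(masks, ((0, 0), (pad, pad), (pad, pad)), constant_values=False)
    h, w = masks.shape[1:]
    out = np.zeros_like(masks)
    for a in dilation_offsets(size):
        for b in dilation_offsets(size):
            out |= p[:, pad + a : pad + a + h, pad + b : pad + b + w]
    return out


# --- connected components -------------------------------------------------

def flood_fill_label(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components as pixel sets, ranked by (-size, first pixel)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                comps.append(comp)
    return sorted(comps, key=lambda comp: (-len(comp), min(r * w + c for r, c in comp)))


# --- percentile -----------------------------------------------------------

def percentile_interp(values, q: float) -> float:
    """Linear-interpolation percentile computed from sorted order statistics."""
    vals = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(vals)
    if n == 1:
        return vals[0]
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return vals[lo] + (h - lo) * (vals[hi] - vals[lo])


# --- statistics -----------------------------------------------------------

def pearson_loop(r, g) -> float:
    r = [float(x) for x in np.asarray(r).ravel()]
    g = [float(x) for x in np.asarray(g).ravel()]
    n = len(r)
    rbar = sum(r) / n
    gbar = sum(g) / n
    num = sum((r[i] - rbar) * (g[i] - gbar) for i in range(n))
    den = math.sqrt(
        sum((x - rbar) ** 2 for x in r) * sum((y - gbar) ** 2 for y in g)
    )
    return float("nan") if den == 0 else num / den


def manders_loop(r, g) -> float:
    r = [float(x) for x in np.asarray(r).ravel()]
    g = [float(x) for x in np.asarray(g).ravel()]
    num = sum(r[i] * g[i] for i in range(len(r)))
    den = math.sqrt(sum(x * x for x in r) * sum(y * y for y in g))
    return float("nan") if den == 0 else num / den
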