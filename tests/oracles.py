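"""Independent brute-force oracles used by the test suite.

Everything here is written for clarity over speed and stays independent of
the package implementations it checks: scalar loops instead of vectorised
algebra, exhaustive scans instead of heaps, pairwise counting instead of
curve integration, exact rational arithmetic instead of floats.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# -- gradient ---------------------------------------------------------------

def convolve_magnitude_bruteforce(img: np.ndarray, kx: np.ndarray,
                                  ky: np.ndarray) -> np.ndarray:
    """Direct per-pixel correlation with reflected borders."""
    h, w = img.shape
    kh, kw = kx.shape
    out = np.zeros((h, w))

    def reflect(i: int, n: int) -> int:
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    for y in range(h):
        for x in range(w):
            gx = gy = 0.0
            for dy in range(kh):
                for dx in range(kw):
                    yy = reflect(y + dy - kh // 2, h)
                    xx = reflect(x + dx - kw // 2, w)
                    gx += img[yy, xx] * kx[dy, dx]
                    gy += img[yy, xx] * ky[dy, dx]
            out[y, x] = math.hypot(gx, gy)
    return out


# -- watershed --------------------------------------------------------------

def priority_flood_bruteforce(surface: np.ndarray,
                              markers: np.ndarray) -> np.ndarray:
    """Meyer flooding with watershed lines, via exhaustive argmin scans.

    Semantics mirror the documented flooding contract: pop order is
    (surface value, insertion order), neighbours pushed N, S, W, E, seeds
    scanned row-major, 4-connectivity, ridge pixels where two basins meet.
    The queue is a plain list scanned linearly for its minimum.
    """
    h, w = surface.shape
    labels = markers.astype(int).copy()
    visited = labels > 0
    queue: list[tuple[float, int, int, int]] = []
    counter = 0
    neigh = ((-1, 0), (1, 0), (0, -1), (0, 1))

    def push_around(y: int, x: int) -> None:
        nonlocal counter
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not visited[ny, nx]:
                queue.append((float(surface[ny, nx]), counter, ny, nx))
                counter += 1

    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                push_around(y, x)

    while queue:
        best = 0
        for i in range(1, len(queue)):       # first minimum in insertion order
            if queue[i][:2] < queue[best][:2]:
                best = i
        _, _, y, x = queue.pop(best)
        if visited[y, x]:
            continue
        visited[y, x] = True
        adjacent = set()
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] > 0:
                adjacent.add(int(labels[ny, nx]))
        if len(adjacent) == 1:
            labels[y, x] = adjacent.pop()
            push_around(y, x)
    return labels


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label maps agree up to a bijective relabelling.

    Ridge pixels (label 0) must coincide exactly.
    """
    if a.shape != b.shape:
        return False
    if ((a == 0) != (b == 0)).any():
        return False
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for va, vb in zip(a.ravel().tolist(), b.ravel().tolist()):
        if va == 0:
            continue
        if fwd.setdefault(va, vb) != vb or rev.setdefault(vb, va) != va:
            return False
    return True


# -- network ops ------------------------------------------------------------

def attention_gate_scalar(x: np.ndarray, g: np.ndarray, w_x, w_g, b_g, phi,
                          b_phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel scalar evaluation of the additive attention gate."""
    h, wd, cx = x.shape
    ci = w_x.shape[1]
    out = np.zeros_like(x, dtype=float)
    alpha = np.zeros((h, wd, 1))
    for i in range(h):
        for j in range(wd):
            inter = [b_g[c]
                     + sum(x[i, j, a] * w_x[a, c] for a in range(cx))
                     + sum(g[i, j, a] * w_g[a, c] for a in range(g.shape[2]))
                     for c in range(ci)]
            s = b_phi + sum(inter[c] * phi[c, 0] for c in range(ci))
            a_ij = 1.0 / (1.0 + math.exp(-s))
            alpha[i, j, 0] = a_ij
            for c in range(cx):
                out[i, j, c] = a_ij * x[i, j, c]
    return out, alpha


def lstm_step_scalar(x, h_prev, c_prev, W_f, W_i, W_c, W_o,
                     b_f, b_i, b_c, b_o) -> tuple[np.ndarray, np.ndarray]:
    """Element-by-element evaluation of one LSTM step."""
    z = list(x) + list(h_prev) + list(c_prev)
    hidden = len(h_prev)

    def sig(v: float) -> float:
        return 1.0 / (1.0 + math.exp(-v))

    h_new = np.zeros(hidden)
    c_new = np.zeros(hidden)
    for k in range(hidden):
        f = sig(sum(W_f[k][j] * z[j] for j in range(len(z))) + b_f[k])
        i = sig(sum(W_i[k][j] * z[j] for j in range(len(z))) + b_i[k])
        cand = math.tanh(sum(W_c[k][j] * z[j] for j in range(len(z))) + b_c[k])
        o = sig(sum(W_o[k][j] * z[j] for j in range(len(z))) + b_o[k])
        c_new[k] = f * c_prev[k] + i * cand
        h_new[k] = o * math.tanh(c_new[k])
    return h_new, c_new


# -- metrics ----------------------------------------------------------------

def counting_metrics(true_labels, predicted_labels, target_class
                     ) -> dict[str, Fraction | None]:
    """Se/Sp/Pr/F for one class by direct sample counting, exact rationals."""
    tp = sum(1 for t, p in zip(true_labels, predicted_labels)
             if t == target_class and p == target_class)
    fn = sum(1 for t, p in zip(true_labels, predicted_labels)
             if t == target_class and p != target_class)
    fp = sum(1 for t, p in zip(true_labels, predicted_labels)
             if t != target_class and p == target_class)
    tn = sum(1 for t, p in zip(true_labels, predicted_labels)
             if t != target_class and p != target_class)

    def frac(num: int, den: int) -> Fraction | None:
        return None if den == 0 else Fraction(num, den)

    return {"se": frac(tp, tp + fn), "sp": frac(tn, tn + fp),
            "pr": frac(tp, tp + fp),
            "f": frac(2 * tp, 2 * tp + fp + fn)}


def auc_mann_whitney(scores, labels, positive) -> float | None:
    """AUC as the pairwise probability that a positive outscores a negative."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
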