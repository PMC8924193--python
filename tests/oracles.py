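"""Independent brute-force oracles used to cross-check optimized code paths.

These are deliberately naive (linear scans, double loops, per-definition
formulas) and share no code with the package implementations they verify.
"""

from __future__ import annotations

import numpy as np


def otsu_brute_force(pixels: np.ndarray) -> int:
    """Argmax of between-class variance over all 256 candidate thresholds."""
    flat = np.asarray(pixels).ravel().astype(np.float64)
    n = flat.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            w0 = lo.size / n
            w1 = hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_t, best_var = t, var
    return best_t


def watershed_priority_flood(
    elevation: np.ndarray, markers: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Priority flood by repeated linear scan of the frontier list.

    Candidate pop order: minimal elevation first; at equal elevation the
    earliest-appended candidate wins (FIFO on plateaus). Initial candidates
    come from marker pixels in lexicographic (row, col) order.
    """
    elev = np.asarray(elevation, dtype=float)
    h, w = elev.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    labels = np.where(mask, np.asarray(markers), 0).astype(int)
    frontier: list[tuple[float, int, int, int, int]] = []
    stamp = [0]

    def push_neighbors(r, c, lab):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                frontier.append((elev[rr, cc], stamp[0], rr, cc, lab))
                stamp[0] += 1

    for r in range(h):
        for c in range(w):
            if labels[r, c] > 0:
                push_neighbors(r, c, labels[r, c])
    while frontier:
        i_best = min(range(len(frontier)), key=lambda i: frontier[i])
        _, _, r, c, lab = frontier.pop(i_best)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        push_neighbors(r, c, lab)
    return labels


def dice_brute_force(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def hausdorff_brute_force(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """Double-loop sup-inf Euclidean distance, both directions."""

    def directed(xs, ys):
        worst = 0.0
        for x in xs:
            best = min(float(np.hypot(x[0] - y[0], x[1] - y[1])) for y in ys)
            worst = max(worst, best)
        return worst

    return max(directed(pts_a, pts_b), directed(pts_b, pts_a))


def boundary_brute_force(mask: np.ndarray) -> np.ndarray:
    """Object pixels with a 4-neighbor outside the object (or off the image)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    pts.append((r, c))
                    break
    return np.array(pts, dtype=float).reshape(-1, 2)


def _match_by_overlap(objs_a: dict, objs_b: dict):
    """a_id -> (b_id, overlapped) by maximal overlap / nearest boundary."""
    match = {}
    for aid, am in objs_a.items():
        best, best_n = None, 0
        for bid in sorted(objs_b):
            n = int((am & objs_b[bid]).sum())
            if n > best_n:
                best, best_n = bid, n
        if best is not None:
            match[aid] = (best, True)
        else:
            ab = boundary_brute_force(am)
            bbest, bd = None, np.inf
            for bid in sorted(objs_b):
                d = hausdorff_brute_force(ab, boundary_brute_force(objs_b[bid]))
                if d < bd:
                    bbest, bd = bid, d
            match[aid] = (bbest, False)
    return match


def object_dice_brute_force(seg: np.ndarray, ref: np.ndarray) -> float:
    seg = np.asarray(seg)
    ref = np.asarray(ref)
    objs_s = {int(i): seg == i for i in np.unique(seg[seg > 0])}
    objs_g = {int(i): ref == i for i in np.unique(ref[ref > 0])}
    if not objs_s and not objs_g:
        return 1.0
    if not objs_s or not objs_g:
        return 0.0

    def one_way(objs_a, objs_b):
        total = sum(int(m.sum()) for m in objs_a.values())
        match = _match_by_overlap(objs_a, objs_b)
        s = 0.0
        for aid, am in objs_a.items():
            bid, overlapped = match[aid]
            d = dice_brute_force(am, objs_b[bid]) if overlapped else 0.0
            s += (int(am.sum()) / total) * d
        return s

    return 0.5 * (one_way(objs_s, objs_g) + one_way(objs_g, objs_s))


def object_hausdorff_brute_force(seg: np.ndarray, ref: np.ndarray) -> float:
    seg = np.asarray(seg)
    ref = np.asarray(ref)
    objs_s = {int(i): seg == i for i in np.unique(seg[seg > 0])}
    objs_g = {int(i): ref == i for i in np.unique(ref[ref > 0])}
    if not objs_s or not objs_g:
        raise ValueError("undefined")

    def one_way(objs_a, objs_b):
        total = sum(int(m.sum()) for m in objs_a.values())
        match = _match_by_overlap(objs_a, objs_b)
        s = 0.0
        for aid, am in objs_a.items():
            bid, _ = match[aid]
            h = hausdorff_brute_force(
                boundary_brute_force(am), boundary_brute_force(objs_b[bid])
            )
            s += (int(am.sum()) / total) * h
        return s

    return 0.5 * (one_way(objs_s, objs_g) + one_way(objs_g, objs_s))


def random_instance_map(
    rng: np.random.Generator, shape=(16, 16), n_objects=3, radius=(2, 5)
) -> np.ndarray:
    """Random blobby instance map for metric cross-checks (may have fewer
    than n_objects if draws vanish)."""
    h, w = shape
    out = np.zeros(shape, dtype=np.int32)
    label = 0
    for _ in range(n_objects):
        r0 = rng.integers(0, h)
        c0 = rng.integers(0, w)
        rad = rng.integers(radius[0], radius[1] + 1)
        rr, cc = np.mgrid[0:h, 0:w]
        blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        blob &= out == 0
        if blob.sum() >= 2:
            label += 1
            out[blob] = label
    return out
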