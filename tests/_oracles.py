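"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive: explicit footprint shifts for
morphology, border-labelled flood fill for cavities, nested loops over disc
offsets for the height-map lids, and direct quadrature for the studentized
range distribution.  None of it shares code paths with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy import ndimage as ndi
from scipy import stats as sps


def ball_offsets(r: float) -> list[tuple[int, int, int]]:
    n = int(math.floor(r))
    out = []
    for dz in range(-n, n + 1):
        for dy in range(-n, n + 1):
            for dx in range(-n, n + 1):
                if dz * dz + dy * dy + dx * dx <= r * r:
                    out.append((dz, dy, dx))
    return out


def disc_offsets(r: float) -> list[tuple[int, int]]:
    n = int(math.floor(r))
    return [
        (dy, dx)
        for dy in range(-n, n + 1)
        for dx in range(-n, n + 1)
        if dy * dy + dx * dx <= r * r
    ]


def _shift3(a: np.ndarray, dz: int, dy: int, dx: int, fill: bool) -> np.ndarray:
    """Shift with constant fill (no wraparound)."""
    out = np.full_like(a, fill)
    zs_src = slice(max(0, -dz), a.shape[0] - max(0, dz))
    ys_src = slice(max(0, -dy), a.shape[1] - max(0, dy))
    xs_src = slice(max(0, -dx), a.shape[2] - max(0, dx))
    zs_dst = slice(max(0, dz), a.shape[0] - max(0, -dz))
    ys_dst = slice(max(0, dy), a.shape[1] - max(0, -dy))
    xs_dst = slice(max(0, dx), a.shape[2] - max(0, -dx))
    out[zs_dst, ys_dst, xs_dst] = a[zs_src, ys_src, xs_src]
    return out


def bf_dilate(mask: np.ndarray, r: float) -> np.ndarray:
    out = np.zeros_like(mask)
    for dz, dy, dx in ball_offsets(r):
        out |= _shift3(mask, dz, dy, dx, False)
    return out


def bf_erode(mask: np.ndarray, r: float) -> np.ndarray:
    out = np.ones_like(mask)
    for dz, dy, dx in ball_offsets(r):
        out &= _shift3(mask, dz, dy, dx, True)
    # outside the array is background, so voxels whose ball pokes out erode
    n = int(math.floor(r))
    if n > 0:
        border = np.ones_like(mask)
        border[n:-n or None, n:-n or None, n:-n or None] = False
        # recompute those strictly: any out-of-bounds offset is background
        for idx in np.argwhere(out & border):
            z, y, x = idx
            for dz, dy, dx in ball_offsets(r):
                zz, yy, xx = z + dz, y + dy, x + dx
                if not (
                    0 <= zz < mask.shape[0]
                    and 0 <= yy < mask.shape[1]
                    and 0 <= xx < mask.shape[2]
                ):
                    out[z, y, x] = False
                    break
    return out


def bf_fill_enclosed(mask: np.ndarray) -> np.ndarray:
    """Fill background not connected (6-conn) to the array border."""
    bg = ~mask
    labels, _ = ndi.label(bg, structure=ndi.generate_binary_structure(3, 1))
    border_labels = set()
    for face in (
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1],
    ):
        border_labels |= set(np.unique(face))
    border_labels -= {0}
    enclosed = bg & ~np.isin(labels, sorted(border_labels))
    return mask | enclosed


def bf_lid_fill(mask: np.ndarray, r: float) -> np.ndarray:
    """Column fill between flat-disc-opened outer and flat-disc-closed inner
    height maps, written with explicit per-pixel loops."""
    nz, ny, nx = mask.shape
    sent = nz + int(math.floor(r)) + 2
    zt = np.full((ny, nx), sent, dtype=float)
    zb = np.full((ny, nx), -sent, dtype=float)
    for y in range(ny):
        for x in range(nx):
            col = np.nonzero(mask[:, y, x])[0]
            if col.size:
                zt[y, x], zb[y, x] = col[0], col[-1]
    offs = disc_offsets(r)

    def g_ero(f, sign):
        out = np.empty_like(f)
        for y in range(ny):
            for x in range(nx):
                vals = [
                    f[min(max(y + dy, 0), ny - 1), min(max(x + dx, 0), nx - 1)]
                    for dy, dx in offs
                ]  # replicate edges, matching mode="nearest"
                out[y, x] = min(vals) if sign < 0 else max(vals)
        return out

    zt_lid = g_ero(g_ero(zt, -1), +1)  # grayscale opening
    zb_lid = g_ero(g_ero(zb, +1), -1)  # grayscale closing
    out = mask.copy()
    for y in range(ny):
        for x in range(nx):
            lo, hi = zt_lid[y, x], zb_lid[y, x]
            for z in range(nz):
                if lo <= z <= hi:
                    out[z, y, x] = True
    return out


def bf_close_and_fill(bone: np.ndarray, roi: np.ndarray, r: float) -> np.ndarray:
    """Brute-force mirror of the close-and-fill semantics."""
    pad = int(math.ceil(r)) + 1
    m = np.pad(bone & roi, pad)
    closed = bf_erode(bf_dilate(m, r), r)
    filled = bf_lid_fill(bf_fill_enclosed(closed), r)
    return filled[pad:-pad, pad:-pad, pad:-pad]


def bf_largest_component(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    """Largest 26-connected component by BFS flood fill."""
    from collections import deque

    offsets = [
        tuple(o - 1 for o in idx)
        for idx in np.argwhere(structure)
        if tuple(idx) != (1, 1, 1)
    ]
    seen = np.zeros_like(mask)
    best, best_size, best_seed = None, -1, None
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            comp.append(p)
            for o in offsets:
                np_ = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if all(0 <= np_[i] < mask.shape[i] for i in range(3)):
                    if mask[np_] and not seen[np_]:
                        seen[np_] = True
                        q.append(np_)
        lin = min(np.ravel_multi_index(p, mask.shape) for p in comp)
        if len(comp) > best_size or (len(comp) == best_size and lin < best_seed):
            best, best_size, best_seed = comp, len(comp), lin
    out = np.zeros_like(mask)
    for p in best:
        out[p] = True
    return out


def bf_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over histogram bin edges for the threshold with
    maximal between-class variance (ties toward the lower edge)."""
    hist, edges = np.histogram(values, bins=nbins)
    best_t, best_v = None, -1.0
    centers = (edges[:-1] + edges[1:]) / 2
    for i in range(1, nbins):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, edges[i]
    return float(best_t)


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range by direct numerical quadrature."""

    def inner(u):
        # P(range of k std normals <= q*u)
        val, _ = integrate.quad(
            lambda z: sps.norm.pdf(z)
            * (sps.norm.cdf(z) - sps.norm.cdf(z - q * u)) ** (k - 1),
            -8 - q * u, 8,
            limit=200,
        )
        return k * val

    # density of u = sqrt(chi2_df / df)
    def chi_density(u):
        return (
            2.0
            * (df / 2.0) ** (df / 2.0)
            / math.gamma(df / 2.0)
            * u ** (df - 1)
            * math.exp(-df * u * u / 2.0)
        )

    cdf, _ = integrate.quad(lambda u: chi_density(u) * inner(u), 0, 6, limit=200)
    return 1.0 - cdf


def mc_two_sample_t_power(
    d: float, n: int, alpha: float, reps: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo power of the two-sided pooled t-test via its sufficient
    statistics (exact in distribution).  Returns (power, MC standard error)."""
    rng = np.random.default_rng(seed)
    m1 = rng.normal(d, 1.0 / math.sqrt(n), reps)
    m2 = rng.normal(0.0, 1.0 / math.sqrt(n), reps)
    v1 = rng.chisquare(n - 1, reps) / (n - 1)
    v2 = rng.chisquare(n - 1, reps) / (n - 1)
    sp = np.sqrt((v1 + v2) / 2.0)
    t = (m1 - m2) / (sp * math.sqrt(2.0 / n))
    crit = sps.t.ppf(1 - alpha / 2, 2 * n - 2)
    p = float(np.mean(np.abs(t) >= crit))
    return p, math.sqrt(p * (1 - p) / reps)
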