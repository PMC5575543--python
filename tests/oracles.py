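"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: explicit loops over voxels, neighbor scans for surface
extraction, full pairwise distance matrices for the modified Hausdorff
distance, ray-casting for point-in-polygon. These share no code with the
package implementations they check.
"""

import numpy as np

_FACE_NEIGHBORS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]


def boundary_points(bits, spacing, origin):
    nx, ny, nz = bits.shape
    pts = []
    for i, j, k in np.argwhere(bits):
        for di, dj, dk in _FACE_NEIGHBORS:
            ii, jj, kk = i + di, j + dj, k + dk
            outside = not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz)
            if outside or not bits[ii, jj, kk]:
                pts.append((i * spacing[0] + origin[0],
                            j * spacing[1] + origin[1],
                            k * spacing[2] + origin[2]))
                break
    return np.asarray(pts, dtype=float)


def volume_error(a_bits, b_bits):
    na = int(a_bits.sum())
    return (int(b_bits.sum()) - na) / na * 100.0


def mean_uptake_error(vox, a_bits, b_bits):
    ma = vox[a_bits].sum() / a_bits.sum()
    mb = vox[b_bits].sum() / b_bits.sum()
    return (mb - ma) / ma * 100.0


def max_uptake_error(vox, a_bits, b_bits):
    xa, xb = vox[a_bits].max(), vox[b_bits].max()
    return (xb - xa) / xa * 100.0


def com_error(a_bits, b_bits, spacing, origin):
    def com(bits):
        idx = np.argwhere(bits).astype(float)
        return (idx * spacing + origin).mean(axis=0)
    return float(np.sqrt(((com(b_bits) - com(a_bits)) ** 2).sum()))


def dsc(a_bits, b_bits):
    inter = int((a_bits & b_bits).sum())
    return 2.0 * inter / (int(a_bits.sum()) + int(b_bits.sum()))


def sensitivity(a_bits, b_bits):
    return int((a_bits & b_bits).sum()) / int(a_bits.sum())


def ppv(a_bits, b_bits):
    return int((a_bits & b_bits).sum()) / int(b_bits.sum())


def modified_hausdorff_cm(a_bits, b_bits, spacing, origin):
    pa = boundary_points(a_bits, spacing, origin)
    pb = boundary_points(b_bits, spacing, origin)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(d.min(axis=1).mean(), d.min(axis=0).mean()) / 10.0


def duv(a_bits, b_bits):
    return int((a_bits | b_bits).sum()) - int((a_bits & b_bits).sum())


def surface_area_mm2(bits, spacing):
    nx, ny, nz = bits.shape
    sx, sy, sz = spacing
    areas = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for i, j, k in np.argwhere(bits):
        for di, dj, dk in _FACE_NEIGHBORS:
            ii, jj, kk = i + di, j + dj, k + dk
            outside = not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz)
            if outside or not bits[ii, jj, kk]:
                axis = 0 if di else (1 if dj else 2)
                total += areas[axis]
    return total


def duv_thickness_cm(a_bits, b_bits, spacing):
    n = duv(a_bits, b_bits)
    if n == 0:
        return 0.0
    voxvol = spacing[0] * spacing[1] * spacing[2]
    return n * voxvol / surface_area_mm2(a_bits, spacing) / 10.0


def point_in_polygon(x, y, poly):
    """Even-odd ray casting; poly is an (N, 2) array of vertices."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xc:
                inside = not inside
    return inside


def connected_component_bfs(bits, start):
    """26-connected component of ``start`` via breadth-first search."""
    from collections import deque

    nx, ny, nz = bits.shape
    seen = np.zeros_like(bits)
    if not bits[start]:
        return seen
    q = deque([start])
    seen[start] = True
    offs = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            for dk in (-1, 0, 1) if (di, dj, dk) != (0, 0, 0)]
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in offs:
            ii, jj, kk = i + di, j + dj, k + dk
            if (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz
                    and bits[ii, jj, kk] and not seen[ii, jj, kk]):
                seen[ii, jj, kk] = True
                q.append((ii, jj, kk))
    return seen
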