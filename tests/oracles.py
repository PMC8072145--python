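"""Independent brute-force oracles for texture matrices and concordance.

Deliberately naive: explicit Python loops, stack-based flood fill, exhaustive
pair/run enumeration. These share no code paths with the package internals
they cross-check.
"""

from __future__ import annotations

import numpy as np

ALL_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def glszm_bruteforce(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zone matrix by explicit stack-based flood fill (26-connectivity)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    ng = int(levels[mask].max())
    visited = np.zeros(levels.shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or visited[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in ALL_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < shape[0]
                            and 0 <= ny < shape[1]
                            and 0 <= nx < shape[2]
                            and mask[nz, ny, nx]
                            and not visited[nz, ny, nx]
                            and levels[nz, ny, nx] == g
                        ):
                            visited[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones.append((int(g), size))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def glrlm_bruteforce(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Run-length matrix for one direction by walking every lattice line."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    ng = int(levels[mask].max())
    shape = levels.shape
    d = np.asarray(direction)
    runs: list[tuple[int, int]] = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                pos = np.array([z, y, x])
                prev = pos - d
                # only start from cells with no same-run predecessor
                if (
                    (prev >= 0).all()
                    and (prev < shape).all()
                    and mask[tuple(prev)]
                    and mask[z, y, x]
                    and levels[tuple(prev)] == levels[z, y, x]
                ):
                    continue
                if not mask[z, y, x]:
                    continue
                g = levels[z, y, x]
                length = 0
                cur = pos.copy()
                while (
                    (cur >= 0).all()
                    and (cur < shape).all()
                    and mask[tuple(cur)]
                    and levels[tuple(cur)] == g
                ):
                    length += 1
                    cur = cur + d
                runs.append((int(g), length))
    max_len = max(l for _, l in runs)
    P = np.zeros((ng, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def glcm_bruteforce(
    levels: np.ndarray, mask: np.ndarray, direction, distance: int = 1
) -> np.ndarray:
    """Symmetric co-occurrence counts by triple loop over voxels."""
    levels = np.asarray(levels)
    mask = np.asarray(mask).astype(bool)
    ng = int(levels[mask].max())
    shape = levels.shape
    d = tuple(c * distance for c in direction)
    C = np.zeros((ng, ng))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nz, ny, nx = z + d[0], y + d[1], x + d[2]
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and mask[nz, ny, nx]
                ):
                    i, j = levels[z, y, x] - 1, levels[nz, ny, nx] - 1
                    C[i, j] += 1
                    C[j, i] += 1
    return C


def harrell_c_bruteforce(scores, time, event) -> float:
    """Concordance by explicit double loop over ordered pairs."""
    n = len(scores)
    conc = ties = comparable = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                comparable += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comparable


def logrank_bruteforce(time, event, group) -> float:
    """Two-group log-rank chi-square from explicit 2x2 tables per event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_total = at_risk.sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d_total = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        o_minus_e += d1 - d_total * n1 / n_total
        if n_total > 1:
            var += (
                d_total
                * (n1 / n_total)
                * (1 - n1 / n_total)
                * (n_total - d_total)
                / (n_total - 1)
            )
    return float(o_minus_e**2 / var)
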