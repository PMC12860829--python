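"""Brute-force oracles: naive neighbourhood enumerations, independent of the
vectorized implementations they check."""

from __future__ import annotations

import numpy as np

DIRS13 = [(dx, dy, dz)
          for dx in (0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
          if (dx, dy, dz) > (0, 0, 0)]
NEIGHBORS26 = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]


def _inside(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def brute_glcm(levels: np.ndarray, directions=DIRS13, symmetric: bool = True) -> np.ndarray:
    ng = int(levels.max())
    counts = np.zeros((ng, ng))
    for p in zip(*np.nonzero(levels)):
        for d in directions:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(q, levels.shape) and levels[q] > 0:
                counts[levels[p] - 1, levels[q] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def brute_glrlm(levels: np.ndarray, directions=DIRS13) -> np.ndarray:
    ng = int(levels.max())
    max_len = max(levels.shape)
    counts = np.zeros((ng, max_len))
    for d in directions:
        for start in zip(*np.nonzero(np.ones_like(levels))):
            back = tuple(a - b for a, b in zip(start, d))
            if _inside(back, levels.shape):
                continue  # not the first voxel of this line
            # walk the whole line and parse maximal equal-level runs
            seq = []
            p = start
            while _inside(p, levels.shape):
                seq.append(int(levels[p]))
                p = tuple(a + b for a, b in zip(p, d))
            i = 0
            while i < len(seq):
                j = i
                while j < len(seq) and seq[j] == seq[i]:
                    j += 1
                if seq[i] > 0:
                    counts[seq[i] - 1, (j - i) - 1] += 1
                i = j
    return counts


def brute_glszm(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    n_vox = int((levels > 0).sum())
    counts = np.zeros((ng, n_vox))
    seen = set()
    for p in zip(*np.nonzero(levels)):
        if p in seen:
            continue
        g = levels[p]
        stack, zone = [p], set()
        seen.add(p)
        while stack:
            q = stack.pop()
            zone.add(q)
            for d in NEIGHBORS26:
                r = tuple(a + b for a, b in zip(q, d))
                if _inside(r, levels.shape) and r not in seen and levels[r] == g:
                    seen.add(r)
                    stack.append(r)
        counts[g - 1, len(zone) - 1] += 1
    return counts


def brute_ngtdm(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    table = np.zeros((ng, 2))
    for p in zip(*np.nonzero(levels)):
        nb = [levels[tuple(a + b for a, b in zip(p, d))]
              for d in NEIGHBORS26
              if _inside(tuple(a + b for a, b in zip(p, d)), levels.shape)
              and levels[tuple(a + b for a, b in zip(p, d))] > 0]
        if not nb:
            continue
        g = int(levels[p])
        table[g - 1, 0] += 1
        table[g - 1, 1] += abs(g - float(np.mean(nb)))
    return table


def brute_gldm(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    ng = int(levels.max())
    deps = []
    for p in zip(*np.nonzero(levels)):
        dep = 0
        for d in NEIGHBORS26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(q, levels.shape) and levels[q] > 0 and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        deps.append((int(levels[p]), dep))
    max_dep = max(d for _, d in deps) + 1
    counts = np.zeros((ng, max_dep))
    for g, dep in deps:
        counts[g - 1, dep] += 1
    return counts
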