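"""Shared fixtures and independent oracle implementations.

Oracles here deliberately use a different computational route than the
package (explicit loops, recursion, pairwise counting) so that agreement is
evidence of correctness rather than shared code.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ivcdetect import phantom


# ---------------------------------------------------------------- oracles


def mip_loop_oracle(voxels: np.ndarray, axis: int) -> np.ndarray:
    """Per-pixel maximum via explicit iteration over the collapsed axis."""
    moved = np.moveaxis(voxels, axis, -1)
    out = np.full(moved.shape[:2], -np.inf)
    for i in range(moved.shape[0]):
        for j in range(moved.shape[1]):
            m = moved[i, j, 0]
            for k in range(1, moved.shape[2]):
                if moved[i, j, k] > m:
                    m = moved[i, j, k]
            out[i, j] = m
    return out


def flood_fill_components(mask: np.ndarray) -> list[frozenset]:
    """8-connected components by iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = set()
        while stack:
            x, y = stack.pop()
            comp.add((x, y))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    nx, ny = x + dx, y + dy
                    if (
                        0 <= nx < mask.shape[0]
                        and 0 <= ny < mask.shape[1]
                        and mask[nx, ny]
                        and not seen[nx, ny]
                    ):
                        seen[nx, ny] = True
                        stack.append((nx, ny))
        comps.append(frozenset(comp))
    return comps


def nms_recursive_oracle(boxes, confidences, iou_fn, iou_thr, conf_thr):
    """Keep-best-then-recurse formulation of non-maximum suppression."""
    alive = [i for i in range(len(boxes)) if confidences[i] >= conf_thr]

    def recurse(indices):
        if not indices:
            return []
        best = max(indices, key=lambda i: confidences[i])
        rest = [
            i
            for i in indices
            if i != best and iou_fn(boxes[i], boxes[best]) < iou_thr
        ]
        return [best] + recurse(rest)

    return recurse(alive)


def auc_concordance_oracle(labels, scores) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), by exhaustive pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def max_bipartite_tp_oracle(det_boxes, truth_boxes, iou_fn, thr) -> int:
    """Maximum number of detection-truth pairs at IoU >= thr, by brute force."""
    n_d, n_t = len(det_boxes), len(truth_boxes)
    feasible = [
        [iou_fn(d, t) >= thr for t in truth_boxes] for d in det_boxes
    ]
    best = 0
    k = min(n_d, n_t)
    for size in range(k, 0, -1):
        for dsub in itertools.combinations(range(n_d), size):
            for tperm in itertools.permutations(range(n_t), size):
                if all(feasible[d][t] for d, t in zip(dsub, tperm)):
                    return size
    return best


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_phantom():
    """One phantom with a hooked filter and two confounders, fixed seed."""
    spec = phantom.PhantomSpec(
        objects=[
            phantom.ObjectSpec(kind="filter_hooked", center=(48, 58, 80), size=9.0),
            phantom.ObjectSpec(kind="clip", center=(100, 64, 60), size=2.0),
            phantom.ObjectSpec(kind="stent", center=(16, 64, 100), size=5.0),
        ],
        seed=3,
    )
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def tissue_only_phantom():
    return phantom.generate_phantom(phantom.PhantomSpec(objects=[], seed=5))
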