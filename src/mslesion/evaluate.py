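"""Lesion-wise comparison of an automated map against a reference map.

Misclassified lesions — automated components with no reference counterpart
(false positives) and reference lesions the automation missed (false
negatives) — are what a reader must correct, so they are counted at the
component level, not the voxel level. Components are matched one-to-one,
greedily by descending voxel overlap, which keeps FP/FN well defined when
components split or merge: one reference lesion covered by two predictions
yields one true positive plus one false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .change import label_components
from .io_volumes import BinaryMask, check_same_grid

__all__ = ["MatchResult", "match_components", "summarize_misclassification"]


@dataclass
class MatchResult:
    """One-to-one component matching between predicted and reference masks.

    ``tp_pairs`` holds (pred id, ref id, overlap voxels, dice) per match;
    unmatched predicted components are false positives, unmatched reference
    components false negatives; ``n_misclassified = n_fp + n_fn``.
    """

    tp_pairs: list[tuple[int, int, int, float]]
    fp_ids: list[int]
    fn_ids: list[int]

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp_ids)

    @property
    def n_fn(self) -> int:
        return len(self.fn_ids)

    @property
    def n_misclassified(self) -> int:
        return self.n_fp + self.n_fn


def match_components(
    pred: BinaryMask,
    ref: BinaryMask,
    connectivity: int = 26,
    min_overlap_voxels: int = 1,
) -> MatchResult:
    """Match predicted against reference lesion components.

    A predicted and a reference component may match iff they share at least
    ``min_overlap_voxels`` voxels; matching is greedy by descending overlap
    (ties toward smaller predicted id, then smaller reference id), each
    component matched at most once. Per-pair Dice is
    ``2 |P ∩ R| / (|P| + |R|)``.
    """
    check_same_grid(pred, ref)
    pl = label_components(pred, connectivity).data
    rl = label_components(ref, connectivity).data
    n_pred = int(pl.max())
    n_ref = int(rl.max())
    pred_sizes = np.bincount(pl.ravel(), minlength=n_pred + 1)
    ref_sizes = np.bincount(rl.ravel(), minlength=n_ref + 1)

    both = (pl > 0) & (rl > 0)
    overlaps: dict[tuple[int, int], int] = {}
    if np.any(both):
        pairs = np.stack([pl[both], rl[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        for (pi, ri), n in zip(uniq, counts):
            if n >= min_overlap_voxels:
                overlaps[(int(pi), int(ri))] = int(n)

    # greedy: largest overlap first, deterministic tie-break by (pred, ref) id
    order = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    matched_pred: set[int] = set()
    matched_ref: set[int] = set()
    tp_pairs: list[tuple[int, int, int, float]] = []
    for (pi, ri), n in order:
        if pi in matched_pred or ri in matched_ref:
            continue
        matched_pred.add(pi)
        matched_ref.add(ri)
        dice = 2.0 * n / (pred_sizes[pi] + ref_sizes[ri])
        tp_pairs.append((pi, ri, n, float(dice)))

    fp_ids = [i for i in range(1, n_pred + 1) if i not in matched_pred]
    fn_ids = [i for i in range(1, n_ref + 1) if i not in matched_ref]
    return MatchResult(tp_pairs=tp_pairs, fp_ids=fp_ids, fn_ids=fn_ids)


def summarize_misclassification(m: MatchResult) -> tuple[int, int, int]:
    """(n_fp, n_fn, n_misclassified) — the lesion-wise error count a reader
    would have to correct."""
    return m.n_fp, m.n_fn, m.n_misclassified
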