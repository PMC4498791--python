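"""Voxel-overlap analysis: confusion counts, Dice similarity, volumes.

For a result voxel set R and truth set T on a shared grid:

    TP = |R ∩ T|    FP = |R ∩ ~T|    FN = |~R ∩ T|    TN = |~R ∩ ~T|

    DSC = 2·TP / ((FP + TP) + (TP + FN))

DSC is symmetric in (R, T), lies in [0, 1], and equals 1 iff R = T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import BinaryMask, GridMismatchError

__all__ = [
    "OverlapCounts",
    "DSCMatrix",
    "confusion_counts",
    "dsc",
    "dsc_between",
    "mask_volume_cm3",
    "dsc_matrix",
]

REFERENCE_LABEL = "Ref."


@dataclass
class OverlapCounts:
    """TP/FP/FN/TN voxel counts for a (result, truth) mask pair."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_counts(result: BinaryMask, truth: BinaryMask) -> OverlapCounts:
    """Voxelwise confusion counts; the two masks must share one grid exactly
    (no silent resampling)."""
    if not result.same_grid(truth):
        raise GridMismatchError("result and truth masks are on different grids")
    r, t = result.data, truth.data
    tp = int(np.count_nonzero(r & t))
    fp = int(np.count_nonzero(r & ~t))
    fn = int(np.count_nonzero(~r & t))
    tn = r.size - tp - fp - fn
    return OverlapCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dsc(counts: OverlapCounts) -> float:
    """Dice similarity coefficient from confusion counts.

    Raises when both masks are empty (|R| = |T| = 0): the coefficient is
    undefined there and silently returning 0 or 1 would corrupt sweeps.
    """
    denom = (counts.FP + counts.TP) + (counts.TP + counts.FN)
    if denom == 0:
        raise ValueError("DSC undefined: both masks are empty")
    return 2.0 * counts.TP / denom


def dsc_between(a: BinaryMask, b: BinaryMask) -> float:
    return dsc(confusion_counts(a, b))


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Physical mask volume: voxel count x voxel volume, in cm^3."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


@dataclass
class DSCMatrix:
    """Pairwise observer DSC table with a reference column.

    ``values`` has observers as rows, the first ``n-1`` observers as columns
    (lower triangle filled; diagonal and upper triangle NaN) plus a final
    reference column giving each observer's DSC against the reference mask.
    """

    labels: list[str]
    values: pd.DataFrame

    def observer_pair_values(self) -> list[float]:
        """The lower-triangle pairwise entries in row-major order."""
        out = []
        for i, row in enumerate(self.labels):
            for col in self.labels[:i]:
                out.append(float(self.values.loc[row, col]))
        return out

    def reference_column(self) -> list[float]:
        return [float(v) for v in self.values[REFERENCE_LABEL]]


def dsc_matrix(masks: dict[str, BinaryMask], reference: BinaryMask) -> DSCMatrix:
    """Pairwise DSC among named observer masks plus a reference column."""
    labels = list(masks)
    if not labels:
        raise ValueError("need at least one observer mask")
    columns = labels[:-1] + [REFERENCE_LABEL] if len(labels) > 1 else [REFERENCE_LABEL]
    table = pd.DataFrame(np.nan, index=labels, columns=columns)
    for i, row in enumerate(labels):
        for col in labels[:i]:
            table.loc[row, col] = dsc_between(masks[row], masks[col])
        table.loc[row, REFERENCE_LABEL] = dsc_between(masks[row], reference)
    return DSCMatrix(labels=labels, values=table)
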