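"""Occlusion (information-discarding) analysis of trained classifiers.

After cross-validation, prediction scores are recomputed on inputs whose
voxels have been zeroed outside ("outside discarding") or inside ("inside
discarding") a cube of parameter ``r``, localizing where in the pocket the
predictive signal lives.  Models are reused as trained -- batch-norm
statistics stay frozen -- and scores are reported against both ``r`` and
the volume of the region whose information is retained:

    outside: (edge - 2r)^3        inside: edge^3 - (2r)^3
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .function import decode_labels
from .model import CVResult, confusion_counts, sacc
from .voxel import region_keep_mask


def retained_volume(mode: str, r: float, edge: float = 24.0) -> float:
    """Volume (cubic angstrom) keeping its original information at radius r."""
    if not 0 <= r < edge / 2:
        raise ValueError(f"r must satisfy 0 <= r < {edge / 2}")
    if mode == "outside":
        return (edge - 2 * r) ** 3
    if mode == "inside":
        return edge**3 - (2 * r) ** 3
    raise ValueError(f"mode must be 'outside' or 'inside', got {mode!r}")


@dataclass
class OcclusionCurve:
    """Sacc versus occlusion radius for one discarding mode."""

    mode: str
    table: pd.DataFrame  # columns: r, retained_volume, sacc_mean, sacc_sd

    def point(self, r: float) -> pd.Series:
        return self.table.set_index("r").loc[r]


def occlusion_sweep(
    run: CVResult,
    X: np.ndarray,
    mode: str,
    r_values: Sequence[float] = tuple(range(12)),
    edge: float = 24.0,
    voxel: float | None = None,
) -> OcclusionCurve:
    """Re-score every test fold under information discarding.

    ``X`` must be the voxel array the run was trained on, shape
    (m, 4, n, n, n); ``voxel`` defaults to ``edge / n``.
    """
    if not run.fold_models:
        raise ValueError("run has no trained fold models")
    X = np.asarray(X)
    n = X.shape[2]
    if voxel is None:
        voxel = edge / n
    rows = []
    for r in r_values:
        keep = region_keep_mask(n, edge, voxel, mode, r).astype(X.dtype)
        per_fold = []
        for fold, model in enumerate(run.fold_models):
            test = np.where(run.fold_assignment == fold)[0]
            masked = X[test] * keep[None, None]
            probs = model.forward(masked.astype(np.float32), train=False)
            preds = (probs >= 0.5).astype(int)
            names = [decode_labels(p, run.scheme) for p in preds]
            counts = confusion_counts(
                [run.observed_classes[i] for i in test], names, run.classes
            )
            per_fold.append(sacc(counts))
        per_fold = np.array(per_fold)
        rows.append(
            {
                "r": float(r),
                "retained_volume": retained_volume(mode, r, edge),
                "sacc_mean": float(per_fold.mean()),
                "sacc_sd": float(per_fold.std()),
            }
        )
    return OcclusionCurve(mode=mode, table=pd.DataFrame(rows))
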