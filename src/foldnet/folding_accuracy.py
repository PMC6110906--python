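"""Per-vertex signal representation accuracy and gyrus/sulcus partition.

Accuracy is the Pearson correlation between each original signal and its
dictionary reconstruction.  Network ROIs are split by curvature sign
(pcurv >= 0 gyral, < 0 sulcal) and accuracy values collected per group.
Raw Pearson values are retained, including negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sparse_coding import Dictionary, SignalMatrix, SparseCodes, reconstruct
from .synthetic_cortex import SurfaceMesh

__all__ = [
    "AccuracyMap",
    "RoiAccuracy",
    "representation_accuracy",
    "partition_by_curvature",
    "collect_roi_accuracy",
    "summarize_network",
]


@dataclass
class AccuracyMap:
    """Per-vertex accuracy P; NaN marks vertices with a constant reconstruction."""

    P: np.ndarray
    vertex_ids: np.ndarray

    def lookup(self) -> dict:
        return {int(v): float(p) for v, p in zip(self.vertex_ids, self.P)}


@dataclass
class RoiAccuracy:
    roi_id: object
    V_gyri: list  # vertex ids, aligned with P_gyri
    V_sulci: list
    P_gyri: np.ndarray
    P_sulci: np.ndarray
    n_dropped: int = 0  # roi vertices without a defined P
    degenerate: bool = field(default=False)  # one group empty


def representation_accuracy(X: SignalMatrix, D: Dictionary,
                            codes: SparseCodes) -> AccuracyMap:
    """Pearson correlation between every column of X and its reconstruction.

    Columns whose reconstruction is constant get NaN (undefined) and are
    dropped by downstream collectors.
    """
    Xhat = reconstruct(D, codes)
    Xmat = X.X
    if Xhat.shape != Xmat.shape:
        raise ValueError("reconstruction shape mismatch")
    xc = Xmat - Xmat.mean(axis=0)
    rc = Xhat - Xhat.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    rn = np.linalg.norm(rc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.einsum("ij,ij->j", xc, rc) / (xn * rn)
    P[rn == 0] = np.nan
    P[xn == 0] = np.nan
    if np.all(np.isnan(P)):
        raise ValueError("every reconstruction is constant; no accuracy defined")
    return AccuracyMap(P=P, vertex_ids=np.asarray(X.vertex_ids))


def partition_by_curvature(mesh: SurfaceMesh, vertices) -> tuple:
    """Split a vertex set into (gyral, sulcal) by curvature sign.

    pcurv >= 0 is gyral (the boundary value 0 counts as gyral); pcurv < 0
    is sulcal.  The two sets are disjoint and exhaustive.
    """
    verts = sorted(int(v) for v in vertices)
    gyri = {v for v in verts if mesh.pcurv[v] >= 0}
    sulci = {v for v in verts if mesh.pcurv[v] < 0}
    return gyri, sulci


def collect_roi_accuracy(acc: AccuracyMap, roi, partition: tuple,
                         roi_id=None) -> RoiAccuracy:
    """Collect accuracy values of one ROI split by the gyral/sulcal partition.

    Vertices without a defined accuracy (excluded at normalization or
    NaN) are dropped and counted.  A ROI whose gyral or sulcal group ends
    up empty is flagged degenerate; the stats stage decides what to do.
    """
    gyri, sulci = partition
    table = acc.lookup()
    vg, pg, vs, ps, dropped = [], [], [], [], 0
    for v in sorted(int(u) for u in roi):
        p = table.get(v)
        if p is None or np.isnan(p):
            dropped += 1
            continue
        if v in gyri:
            vg.append(v)
            pg.append(p)
        elif v in sulci:
            vs.append(v)
            ps.append(p)
        else:
            dropped += 1
    return RoiAccuracy(
        roi_id=roi_id, V_gyri=vg, V_sulci=vs,
        P_gyri=np.asarray(pg, dtype=float), P_sulci=np.asarray(ps, dtype=float),
        n_dropped=dropped, degenerate=(len(pg) == 0 or len(ps) == 0),
    )


def summarize_network(rois: list) -> pd.DataFrame:
    """Per-ROI and pooled means/sds/sizes of gyral and sulcal accuracy."""
    if not rois:
        raise ValueError("need at least one ROI")
    rows = []
    for roi in rois:
        rows.append({
            "roi_id": roi.roi_id,
            "mean_gyri": roi.P_gyri.mean() if roi.P_gyri.size else np.nan,
            "mean_sulci": roi.P_sulci.mean() if roi.P_sulci.size else np.nan,
            "sd_gyri": roi.P_gyri.std(ddof=1) if roi.P_gyri.size > 1 else np.nan,
            "sd_sulci": roi.P_sulci.std(ddof=1) if roi.P_sulci.size > 1 else np.nan,
            "n_gyri": roi.P_gyri.size,
            "n_sulci": roi.P_sulci.size,
        })
    pooled_g = np.concatenate([r.P_gyri for r in rois]) if rois else np.array([])
    pooled_s = np.concatenate([r.P_sulci for r in rois]) if rois else np.array([])
    rows.append({
        "roi_id": "pooled",
        "mean_gyri": pooled_g.mean() if pooled_g.size else np.nan,
        "mean_sulci": pooled_s.mean() if pooled_s.size else np.nan,
        "sd_gyri": pooled_g.std(ddof=1) if pooled_g.size > 1 else np.nan,
        "sd_sulci": pooled_s.std(ddof=1) if pooled_s.size > 1 else np.nan,
        "n_gyri": pooled_g.size,
        "n_sulci": pooled_s.size,
    })
    return pd.DataFrame(rows)
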