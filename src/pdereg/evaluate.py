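"""Post-registration assessment: Dice overlap, relative intensity error,
relative gradient magnitude, Jacobian extrema, and label warping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage

from .grid import GridSpec, ScalarField, VectorField
from .transport import TimeGrid, cgl_nodes, solve_jacobian

__all__ = [
    "LabelVolume",
    "EvaluationReport",
    "dice",
    "dice_all",
    "mse_rel",
    "grad_rel_inf",
    "jacobian_extrema",
    "warp_labels",
    "evaluation_report",
]


@dataclass
class LabelVolume:
    """Integer-valued segmentation on a grid; background is 0."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label volume must be integer-valued")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label shape does not match grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def label_set(self) -> list[int]:
        return [int(l) for l in np.unique(self.labels) if l != 0]


@dataclass
class EvaluationReport:
    dsc_per_label: dict[int, float]
    dsc_summary: dict[str, float]
    mse_rel: float | None = None
    grad_rel_inf: float | None = None
    jacobian_min: float | None = None
    jacobian_max: float | None = None

    def to_dict(self) -> dict:
        return {
            "dsc_per_label": {str(k): v for k, v in self.dsc_per_label.items()},
            "dsc_summary": self.dsc_summary,
            "mse_rel": self.mse_rel,
            "grad_rel_inf": self.grad_rel_inf,
            "jacobian_min": self.jacobian_min,
            "jacobian_max": self.jacobian_max,
        }


def _labels_arr(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelVolume) else np.asarray(x)


def dice(seg_a, seg_b, label: int) -> float:
    """Dice similarity coefficient 2|A ∩ B| / (|A| + |B|) for one label."""
    a = _labels_arr(seg_a) == label
    b = _labels_arr(seg_b) == label
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError(f"label {label} absent from both volumes; DSC undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_all(seg_a, seg_b) -> dict[int, float]:
    """DSC per foreground label present in either volume."""
    a, b = _labels_arr(seg_a), _labels_arr(seg_b)
    labels = sorted(set(np.unique(a)) | set(np.unique(b)) - {0})
    return {int(l): dice(a, b, int(l)) for l in labels if l != 0}


def _summary(values: list[float]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
        "q3": float(q[3]), "max": float(q[4]), "mean": float(v.mean()),
    }


def mse_rel(m1: ScalarField, i0: ScalarField, i1: ScalarField) -> float:
    """Relative image similarity error after registration, in percent:
    100 * ||m(1) - I1||^2 / ||I0 - I1||^2."""
    denom = float(np.sum((i0.data - i1.data) ** 2))
    if denom == 0:
        raise ValueError("I0 equals I1; relative error undefined")
    return 100.0 * float(np.sum((m1.data - i1.data) ** 2)) / denom


def grad_rel_inf(g_n, g_0) -> float:
    """Relative gradient magnitude ||g_n||_inf / ||g_0||_inf."""
    def _inf(g):
        arr = g.coeffs if hasattr(g, "coeffs") else g.data
        return float(np.abs(arr).max())

    denom = _inf(g_0)
    if denom == 0:
        raise ValueError("initial gradient is zero")
    return _inf(g_n) / denom


def jacobian_extrema(v: VectorField, timegrid: TimeGrid | None = None) -> tuple[float, float]:
    """(min, max) of the Jacobian determinant of the inverse transformation."""
    tg = timegrid if timegrid is not None else cgl_nodes(5)
    j0 = solve_jacobian(v, tg)[0].data
    return float(j0.min()), float(j0.max())


def warp_labels(labels: LabelVolume, disp: VectorField) -> LabelVolume:
    """Nearest-neighbor pullback of a label map through ``id + disp``
    (pass the pullback map phi(1) to carry source labels into the target
    frame, matching m(1) = I0 o phi(1); pass psi for the opposite direction).
    Labels are never invented, only preserved or dropped."""
    grid = labels.grid
    scale = np.asarray(grid.shape, dtype=float).reshape((-1,) + (1,) * grid.dim)
    pts = grid.index_coords() + disp.data * scale
    warped = ndimage.map_coordinates(labels.labels, pts, order=0, mode="grid-wrap")
    return LabelVolume(grid, warped)


def evaluation_report(
    warped_labels,
    target_labels,
    m1: ScalarField | None = None,
    i0: ScalarField | None = None,
    i1: ScalarField | None = None,
    v: VectorField | None = None,
    grad_final=None,
    grad_init=None,
) -> EvaluationReport:
    """Assemble the standard report: per-label DSC with quartile summary,
    plus MSErel / relative gradient / Jacobian extrema when inputs allow."""
    dsc = dice_all(warped_labels, target_labels)
    rep = EvaluationReport(dsc_per_label=dsc, dsc_summary=_summary(list(dsc.values())))
    if m1 is not None and i0 is not None and i1 is not None:
        rep.mse_rel = mse_rel(m1, i0, i1)
    if grad_final is not None and grad_init is not None:
        rep.grad_rel_inf = grad_rel_inf(grad_final, grad_init)
    if v is not None:
        rep.jacobian_min, rep.jacobian_max = jacobian_extrema(v)
    return rep
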