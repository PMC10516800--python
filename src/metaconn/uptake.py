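"""Subjects x ROI uptake tables: reading, validation, global scaling.

An :class:`UptakeTable` holds one group's mean regional uptake values (one
row per animal, one column per ROI, arbitrary optical-density units).  The
tabular analogue of whole-brain proportional scaling is provided by
:func:`global_scale`: each subject's row is rescaled so its mean over ROIs
equals a common target, removing global-uptake differences between animals
before cross-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import ROIRegistry

__all__ = ["UptakeTable", "UptakeError", "read_uptake", "global_scale"]


class UptakeError(ValueError):
    """Raised on invalid uptake data."""


@dataclass(frozen=True)
class UptakeTable:
    """One group's subjects x ROI uptake matrix.

    ``values`` is an ``n_subjects x n_rois`` float array; column order is the
    registry ROI order and is the order used by every downstream matrix.
    """

    group_name: str
    subject_ids: tuple[str, ...]
    roi_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise UptakeError("values must be a 2-D subjects x ROIs matrix")
        n, p = values.shape
        if n != len(self.subject_ids) or p != len(self.roi_ids):
            raise UptakeError(
                f"shape {values.shape} inconsistent with {len(self.subject_ids)} "
                f"subjects / {len(self.roi_ids)} ROIs"
            )
        if len(set(self.subject_ids)) != n:
            raise UptakeError("duplicate subject ids")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            cells = [f"({self.subject_ids[i]}, {self.roi_ids[j]})" for i, j in bad[:10]]
            raise UptakeError(f"missing/non-finite entries at {', '.join(cells)}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subject_ids),
                            columns=list(self.roi_ids))

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "subject_id"
        frame.to_csv(path)

    def drop_subject(self, index: int) -> "UptakeTable":
        """Leave-one-out copy with the subject at ``index`` removed."""
        keep = [i for i in range(self.n_subjects) if i != index]
        return UptakeTable(
            group_name=self.group_name,
            subject_ids=tuple(self.subject_ids[i] for i in keep),
            roi_ids=self.roi_ids,
            values=self.values[keep],
        )

    def validate_variance(self) -> None:
        """Raise if any ROI column is constant (Pearson r undefined)."""
        sd = self.values.std(axis=0)
        flat = [self.roi_ids[j] for j in np.flatnonzero(sd == 0)]
        if flat:
            raise UptakeError(f"zero-variance ROI column(s): {', '.join(flat)}")


def read_uptake(path: str | Path, registry: ROIRegistry,
                group_name: str | None = None) -> UptakeTable:
    """Read a group CSV (``subject_id`` first column, one column per ROI).

    Columns are re-indexed to registry order; missing ROI columns, missing
    values, and zero-variance columns raise :class:`UptakeError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    missing = [rid for rid in registry.roi_ids if rid not in frame.columns]
    if missing:
        raise UptakeError(f"{path.name}: missing ROI column(s): {', '.join(missing[:10])}")
    frame = frame[registry.roi_ids]
    table = UptakeTable(
        group_name=group_name or path.stem,
        subject_ids=tuple(str(s) for s in frame.index),
        roi_ids=tuple(registry.roi_ids),
        values=frame.to_numpy(dtype=float),
    )
    table.validate_variance()
    return table


def global_scale(table: UptakeTable, target_mean: float = 100.0) -> UptakeTable:
    """Proportionally rescale each subject so its ROI-mean equals ``target_mean``.

    Row ``i`` is multiplied by ``target_mean / mean(row_i)``.  Idempotent;
    raises if any subject mean is non-positive.
    """
    if target_mean <= 0:
        raise UptakeError("target_mean must be positive")
    means = table.values.mean(axis=1)
    if np.any(means <= 0):
        bad = [table.subject_ids[i] for i in np.flatnonzero(means <= 0)]
        raise UptakeError(f"non-positive subject mean(s): {', '.join(bad)}")
    scaled = table.values * (target_mean / means)[:, None]
    return UptakeTable(table.group_name, table.subject_ids, table.roi_ids, scaled)
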