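"""Between-group edge differences: Fisher Z-test with a 2n-iteration
double jackknife.

Two independent correlation coefficients r1 (group 1) and r2 (group 2)
estimated from n1 and n2 subjects are compared with

    Z = [atanh(r1) - atanh(r2)] / sqrt(1/(n1-3) + 1/(n2-3))

which is approximately standard normal under r1 = r2; positive Z means r1
exceeds r2.  A two-sided p follows from the normal CDF.

Reliability again comes from leave-one-out: with matched groups of n
subjects each, 2n iterations each drop a single subject from exactly one
group (the other stays at full n) and recompute the whole Z matrix.  An
edge difference is reliable only if p < alpha with a consistent Z sign in
all 2n iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import EdgeSet, _R_CLAMP, _edge_set_from_mask, pearson_matrix
from .uptake import UptakeTable

__all__ = ["GroupZResult", "fisher_z", "fisher_z_matrix",
           "reliable_differences_double_jackknife"]


@dataclass(frozen=True)
class GroupZResult:
    """Full-sample Z/p matrices plus the double-jackknife reliability mask."""

    roi_ids: tuple[str, ...]
    z: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n1: int
    n2: int
    reliable_mask: np.ndarray = field(repr=False)
    alpha: float

    def reliable_edges(self, r1_full: np.ndarray | None = None) -> EdgeSet:
        """Reliable differences as a signed EdgeSet (sign = sign of full Z)."""
        r_store = r1_full if r1_full is not None else self.z
        return _edge_set_from_mask(self.reliable_mask, r_store, self.roi_ids,
                                   "group_difference", self.alpha,
                                   sign_source=self.z)


def fisher_z(r1, r2, n1: int, n2: int):
    """Fisher Z statistic for the difference of two independent correlations.

    Accepts scalars or arrays; requires ``n1, n2 >= 4`` (the variance term
    ``1/(n-3)`` must be positive and finite).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError(f"need n1, n2 >= 4, got n1={n1}, n2={n2}")
    r1 = np.clip(np.asarray(r1, dtype=float), -_R_CLAMP, _R_CLAMP)
    r2 = np.clip(np.asarray(r2, dtype=float), -_R_CLAMP, _R_CLAMP)
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z) if z.ndim == 0 else z


def fisher_z_p(z):
    """Two-sided normal p-value, ``2 * (1 - Phi(|Z|))``."""
    return 2.0 * stats.norm.sf(np.abs(z))


def fisher_z_matrix(table1: UptakeTable, table2: UptakeTable) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise Z and p matrices between two groups' correlation matrices."""
    if table1.roi_ids != table2.roi_ids:
        raise ValueError("tables must share the same ROI ordering")
    r1 = pearson_matrix(table1).r
    r2 = pearson_matrix(table2).r
    z = fisher_z(r1, r2, table1.n_subjects, table2.n_subjects)
    np.fill_diagonal(z, 0.0)
    p = fisher_z_p(z)
    np.fill_diagonal(p, 1.0)
    return z, p


def reliable_differences_double_jackknife(table1: UptakeTable, table2: UptakeTable,
                                          alpha: float = 0.05,
                                          strict_full_sample: bool = False) -> GroupZResult:
    """Between-group reliable edge differences under the 2n-iteration jackknife.

    Each iteration removes one subject from exactly one group (n vs n-1)
    and recomputes the Z matrix; an edge difference is reliable iff
    ``p < alpha`` with a consistent Z sign in all ``n1 + n2`` iterations.
    The full-sample Z and p are reported alongside (and gate the mask only
    when ``strict_full_sample`` is set).
    """
    if table1.roi_ids != table2.roi_ids:
        raise ValueError("tables must share the same ROI ordering")
    n1, n2 = table1.n_subjects, table2.n_subjects
    if min(n1, n2) < 5:
        raise ValueError(f"double jackknife needs n >= 5 per group, got {n1}, {n2}")
    if n1 != n2:
        warnings.warn(
            "group sizes differ; running n1 + n2 drop-one iterations instead of 2n",
            stacklevel=2,
        )
    z_full, p_full = fisher_z_matrix(table1, table2)
    p_rois = len(table1.roi_ids)
    keep = np.ones((p_rois, p_rois), dtype=bool)
    sign_ref = None
    iterations = [(table1.drop_subject(i), table2) for i in range(n1)]
    iterations += [(table1, table2.drop_subject(i)) for i in range(n2)]
    for t1, t2 in iterations:
        z, p = fisher_z_matrix(t1, t2)
        keep &= p < alpha
        s = np.sign(z)
        if sign_ref is None:
            sign_ref = s
        else:
            keep &= s == sign_ref
    if strict_full_sample:
        keep &= p_full < alpha
    np.fill_diagonal(keep, False)
    return GroupZResult(table1.roi_ids, z_full, p_full, n1, n2, keep, alpha)
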