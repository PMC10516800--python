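"""Within-group metabolic connectivity: cross-subject correlation matrices
and jackknife-reliable edges.

Connectivity is estimated cross-sectionally: for each unordered ROI pair the
Pearson correlation of mean uptake is computed *across the n subjects of one
group* (not over time).  Each correlation gets a two-sided p-value from the
exact null distribution of r under bivariate normality, via
``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of freedom.

To control the type-I error inflation from thousands of simultaneous
correlations, an edge counts as *reliably* significant only if it reaches
``p < alpha`` — with a consistent sign — in every one of the n leave-one-
subject-out recomputations.  This jackknife criterion is strictly more
conservative than the single full-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .registry import ROIRegistry
from .uptake import UptakeTable

__all__ = [
    "CorrelationResult",
    "Edge",
    "EdgeSet",
    "pearson_matrix",
    "r_to_z",
    "correlation_p_values",
    "reliable_edges_jackknife",
]

# largest |r| for which atanh stays finite in double precision
_R_CLAMP = 1.0 - 1e-15


@dataclass(frozen=True)
class CorrelationResult:
    """Symmetric r / Fisher-z / p matrices for one group of ``n`` subjects."""

    roi_ids: tuple[str, ...]
    r: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n: int


@dataclass(frozen=True)
class Edge:
    """A reliable signed edge; ``sign`` is +1/-1 and matches ``r_full``."""

    roi_i: str
    roi_j: str
    sign: int
    r_full: float


@dataclass(frozen=True)
class EdgeSet:
    """Jackknife-surviving edges, with (i, j) in registry order and i < j."""

    edges: tuple[Edge, ...]
    provenance: str  # "within_group" | "group_difference"
    alpha: float

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.roi_i, e.roi_j) for e in self.edges}


def r_to_z(r):
    """Fisher r-to-z transform, ``0.5 * ln((1+r)/(1-r))`` = atanh(r).

    Odd and strictly increasing on (-1, 1); raises for ``|r| >= 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("r must satisfy |r| < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def correlation_p_values(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r at sample size ``n`` (df = n-2).

    ``|r| = 1`` maps to p = 0 (the t statistic diverges).
    """
    if n < 4:
        raise ValueError(f"need n >= 4 subjects, got {n}")
    r = np.asarray(r, dtype=float)
    rr = np.clip(r, -_R_CLAMP, _R_CLAMP)
    t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def pearson_matrix(table: UptakeTable) -> CorrelationResult:
    """All-pairs cross-subject Pearson correlations for one group.

    Returns r together with its Fisher-z transform (z clamped to finite
    values where ``|r| = 1``) and two-sided p-values.  Raises on constant
    columns or ``n < 4``.
    """
    if table.n_subjects < 4:
        raise ValueError(f"need n >= 4 subjects, got {table.n_subjects}")
    table.validate_variance()
    r = np.corrcoef(table.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    p = correlation_p_values(r, table.n_subjects)
    np.fill_diagonal(p, 1.0)  # diagonal excluded from edge enumeration
    return CorrelationResult(tuple(table.roi_ids), r, z, p, table.n_subjects)


def _edge_set_from_mask(mask: np.ndarray, r_full: np.ndarray,
                        roi_ids: tuple[str, ...], provenance: str,
                        alpha: float, sign_source: np.ndarray | None = None) -> EdgeSet:
    signs = np.sign(sign_source if sign_source is not None else r_full)
    edges = []
    iu = np.triu_indices(len(roi_ids), k=1)
    for i, j in zip(*iu):
        if mask[i, j]:
            edges.append(Edge(roi_ids[i], roi_ids[j], int(signs[i, j]) or 1,
                              float(r_full[i, j])))
    return EdgeSet(tuple(edges), provenance, alpha)


def reliable_edges_jackknife(table: UptakeTable, alpha: float = 0.05,
                             strict_full_sample: bool = False,
                             registry: ROIRegistry | None = None) -> EdgeSet:
    """Within-group reliable edges under the n-iteration jackknife.

    One subject is dropped at a time and the correlation matrix recomputed
    with the remaining ``n - 1``; an edge is kept iff ``p < alpha`` with a
    consistent r sign in *all* n iterations.  The edge's recorded sign comes
    from the full-sample r.  ``strict_full_sample`` additionally requires
    full-sample ``p < alpha`` (off by default: the reliability criterion as
    published is the all-iterations rule alone).
    """
    n = table.n_subjects
    if n < 5:
        raise ValueError(f"jackknife needs n >= 5 subjects, got {n}")
    full = pearson_matrix(table)
    p_rois = len(table.roi_ids)
    keep = np.ones((p_rois, p_rois), dtype=bool)
    sign_ref = None
    for i in range(n):
        sub = table.drop_subject(i)
        res = pearson_matrix(sub)
        keep &= res.p < alpha
        s = np.sign(res.r)
        if sign_ref is None:
            sign_ref = s
        else:
            keep &= s == sign_ref
    if strict_full_sample:
        keep &= full.p < alpha
    np.fill_diagonal(keep, False)
    return _edge_set_from_mask(keep, full.r, full.roi_ids, "within_group", alpha)
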