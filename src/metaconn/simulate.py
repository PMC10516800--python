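"""Synthetic group-wise uptake data with controlled correlation structure.

Real inputs to this analysis are mean regional uptake values for ~10 animals
per group, correlated across animals within anatomical structures.  This
module emulates that design so every downstream stage has known ground
truth: a target correlation matrix is assembled from per-structure blocks
(constant within-block correlation) plus individually planted edges, repaired
to the nearest positive semi-definite (PSD) matrix by eigenvalue clipping,
and sampled as a multivariate normal — the distributional setting the
Pearson/Fisher machinery assumes.  Group differences are created by planting
different target correlations for selected edges in otherwise-matched specs.

Defaults mirror the emulated study design: 10 subjects per group, 176 ROIs
in 6 structure blocks, positive uptake around a common baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .registry import ROIRegistry
from .uptake import UptakeTable

__all__ = [
    "CovarianceSpec",
    "GroupSpec",
    "SimulationError",
    "build_correlation_matrix",
    "generate_group",
    "plant_group_difference",
]


class SimulationError(ValueError):
    """Raised on infeasible or invalid simulation specs."""


@dataclass(frozen=True)
class CovarianceSpec:
    """Target correlation structure for one group.

    ``within_block_r`` may be a single float applied to every structure or a
    ``{structure: r}`` mapping.  ``planted_edges`` entries ``(i, j, r)``
    override the block value for that ROI pair (indices or roi_ids).  The
    assembled matrix is repaired to PSD before sampling; if the repair moves
    any entry by more than ``repair_tolerance`` the spec is rejected as
    infeasible.
    """

    roi_count: int
    block_assignment: tuple[str, ...]  # structure code per ROI, registry order
    within_block_r: float | dict = 0.0
    planted_edges: tuple = ()
    baseline_mean: float = 100.0
    noise_sd: float = 5.0
    repair_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.roi_count <= 0 or len(self.block_assignment) != self.roi_count:
            raise SimulationError("block_assignment length must equal roi_count")
        if self.baseline_mean <= 0 or self.noise_sd <= 0:
            raise SimulationError("baseline_mean and noise_sd must be positive")
        for r in (self.within_block_r.values()
                  if isinstance(self.within_block_r, dict) else [self.within_block_r]):
            if not -1.0 < r < 1.0:
                raise SimulationError(f"within-block correlation {r} outside (-1, 1)")
        for i, j, r in self.planted_edges:
            if not -1.0 < r < 1.0:
                raise SimulationError(f"planted correlation {r} outside open interval (-1, 1)")
            if i == j:
                raise SimulationError("planted edge must join two distinct ROIs")


@dataclass(frozen=True)
class GroupSpec:
    """One group: a name, a subject count, a covariance target, a seed."""

    name: str
    covariance: CovarianceSpec
    n_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        # n-3 in the Fisher Z denominator and >= 3 subjects per jackknife
        # iteration both require at least 4 animals
        if self.n_subjects < 4:
            raise SimulationError(f"need n_subjects >= 4, got {self.n_subjects}")


def _block_r(spec: CovarianceSpec, structure: str) -> float:
    if isinstance(spec.within_block_r, dict):
        return float(spec.within_block_r.get(structure, 0.0))
    return float(spec.within_block_r)


def _edge_index(spec: CovarianceSpec, key, roi_ids: list[str] | None) -> int:
    if isinstance(key, str):
        if roi_ids is None or key not in roi_ids:
            raise SimulationError(f"planted edge references unknown ROI {key!r}")
        return roi_ids.index(key)
    idx = int(key)
    if not 0 <= idx < spec.roi_count:
        raise SimulationError(f"planted edge index {idx} out of range")
    return idx


def build_correlation_matrix(spec: CovarianceSpec,
                             roi_ids: list[str] | None = None
                             ) -> tuple[np.ndarray, dict]:
    """Assemble the target correlation matrix and repair it to PSD.

    Returns ``(matrix, meta)`` where ``meta['max_repair_delta']`` records the
    largest absolute entry change the PSD repair introduced and
    ``meta['min_eigenvalue']`` the pre-repair minimum eigenvalue.  Raises
    :class:`SimulationError` if the repair exceeds ``spec.repair_tolerance``.
    """
    p = spec.roi_count
    target = np.eye(p)
    blocks = np.asarray(spec.block_assignment)
    for structure in dict.fromkeys(spec.block_assignment):
        idx = np.flatnonzero(blocks == structure)
        r = _block_r(spec, structure)
        if r != 0.0 and len(idx) > 1:
            sub = np.ix_(idx, idx)
            target[sub] = r
            target[idx, idx] = 1.0
    for i_key, j_key, r in spec.planted_edges:
        i = _edge_index(spec, i_key, roi_ids)
        j = _edge_index(spec, j_key, roi_ids)
        target[i, j] = target[j, i] = r

    # eigenvalue-clipping PSD repair, then re-normalize to unit diagonal
    eigval, eigvec = np.linalg.eigh(target)
    min_eig = float(eigval[0])
    repaired = target
    if min_eig < 0:
        clipped = np.clip(eigval, 0.0, None)
        repaired = (eigvec * clipped) @ eigvec.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        repaired = (repaired + repaired.T) / 2.0
        np.fill_diagonal(repaired, 1.0)
    delta = float(np.max(np.abs(repaired - target)))
    if delta > spec.repair_tolerance:
        raise SimulationError(
            f"PSD repair moved an entry by {delta:.4f} > tolerance "
            f"{spec.repair_tolerance}; correlation targets are jointly infeasible"
        )
    return repaired, {"max_repair_delta": delta, "min_eigenvalue": min_eig}


def generate_group(spec: GroupSpec, registry: ROIRegistry) -> UptakeTable:
    """Draw one group's subjects x ROI uptake table.

    Samples ``n_subjects`` i.i.d. multivariate-normal vectors with the
    repaired target correlation, scaled by ``noise_sd`` and shifted by
    ``baseline_mean``.  Reproducible: the same spec and seed give an
    identical table.  Degenerate draws (any constant column) are rejected
    and resampled with an incremented seed.
    """
    cov_spec = spec.covariance
    if len(registry) != cov_spec.roi_count:
        raise SimulationError(
            f"registry has {len(registry)} ROIs but spec expects {cov_spec.roi_count}"
        )
    corr, _ = build_correlation_matrix(cov_spec, roi_ids=registry.roi_ids)
    # eigen-based factor: robust for singular PSD matrices where Cholesky fails
    eigval, eigvec = np.linalg.eigh(corr)
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    seed = spec.seed
    for _attempt in range(10):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((spec.n_subjects, cov_spec.roi_count))
        values = cov_spec.baseline_mean + cov_spec.noise_sd * (z @ factor.T)
        if np.all(values.std(axis=0) > 0):
            break
        seed += 1  # degenerate draw (probability ~0); resample
    subject_ids = tuple(f"{spec.name}_s{i + 1:02d}" for i in range(spec.n_subjects))
    return UptakeTable(spec.name, subject_ids, tuple(registry.roi_ids), values)


def plant_group_difference(spec_control: GroupSpec,
                           edges,
                           name_other: str = "exercise",
                           seed_other: int | None = None
                           ) -> tuple[GroupSpec, GroupSpec]:
    """Build a matched spec pair differing only at the listed edges.

    ``edges`` is a list of ``(roi_i, roi_j, r_control, r_other)``.  Both
    resulting covariance targets are validated (built and PSD-repaired)
    before returning.
    """
    cov = spec_control.covariance
    planted_c = list(cov.planted_edges)
    planted_o = list(cov.planted_edges)
    for i, j, r_c, r_o in edges:
        planted_c.append((i, j, r_c))
        planted_o.append((i, j, r_o))
    cov_c = replace(cov, planted_edges=tuple(planted_c))
    cov_o = replace(cov, planted_edges=tuple(planted_o))
    if all(isinstance(k, int) for i, j, _ in cov_c.planted_edges for k in (i, j)):
        for c in (cov_c, cov_o):
            build_correlation_matrix(c)  # raises if infeasible
    control = replace(spec_control, covariance=cov_c)
    other = replace(spec_control, covariance=cov_o, name=name_other,
                    seed=spec_control.seed + 1 if seed_other is None else seed_other)
    return control, other
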