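"""ROI parcellation registry for the cortico-basal ganglia-thalamic (CBT) network.

The analysis operates on a fixed parcellation of 176 regions of interest
(ROIs) spanning six structures: caudoputamen (CP, 66 ROIs), substantia nigra
pars reticulata (SNr, 25), globus pallidus externus (GPe, 27), motor cortex
(MOTOR, 18), prefrontal cortex (PFC, 19) and thalamic nuclei (TH, 21).
ROIs are grouped by structure and, within a structure, ordered from rostral
to caudal bregma level.  The registry is purely tabular metadata: it names
each ROI, assigns it to a structure, and records its connectome domain label
and bregma coordinate.  It also provides the unordered ROI pair-count
arithmetic underlying connectivity-density percentages.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ROI",
    "ROIRegistry",
    "STRUCTURES",
    "default_registry",
    "default_registry_path",
    "load_registry",
    "pair_count",
    "RegistryError",
]

#: Closed set of structure codes in canonical (rostral-first) display order.
STRUCTURES: tuple[str, ...] = ("CP", "SNr", "GPe", "MOTOR", "PFC", "TH")

REGISTRY_COLUMNS = ("roi_id", "structure", "subdivision", "domain_label", "bregma_mm")


class RegistryError(ValueError):
    """Raised on malformed or inconsistent registry data."""


@dataclass(frozen=True)
class ROI:
    """A single region of interest.

    Parameters
    ----------
    roi_id
        Unique label, conventionally ``<subdivision><bregma>_<index>``
        (e.g. ``"CPr+1.3_a"``).
    structure
        One of :data:`STRUCTURES`.
    subdivision
        Finer anatomical grouping (e.g. ``CPr``, ``Cg1``, ``VA/VL``).
    domain_label
        Connectome-nomenclature domain the ROI samples.
    bregma_mm
        Signed rostro-caudal coordinate in millimetres relative to bregma.
    """

    roi_id: str
    structure: str
    subdivision: str
    domain_label: str
    bregma_mm: float

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise RegistryError(
                f"unknown structure code {self.structure!r} for ROI {self.roi_id!r}; "
                f"expected one of {STRUCTURES}"
            )
        if not math.isfinite(self.bregma_mm):
            raise RegistryError(f"non-finite bregma for ROI {self.roi_id!r}")


class ROIRegistry:
    """Ordered, validated collection of :class:`ROI` entries.

    Ordering is part of the contract: correlation-matrix rows/columns and
    all deterministic tie-breaks follow registry order.
    """

    def __init__(self, rois: Iterable[ROI]):
        self._rois: list[ROI] = list(rois)
        seen: set[str] = set()
        for roi in self._rois:
            if roi.roi_id in seen:
                raise RegistryError(f"duplicate roi_id {roi.roi_id!r}")
            seen.add(roi.roi_id)
        self._index = {roi.roi_id: i for i, roi in enumerate(self._rois)}

    def __len__(self) -> int:
        return len(self._rois)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self._rois)

    def __getitem__(self, key: int | str) -> ROI:
        if isinstance(key, str):
            return self._rois[self._index[key]]
        return self._rois[key]

    def __contains__(self, roi_id: str) -> bool:
        return roi_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ROIRegistry):
            return NotImplemented
        return self._rois == other._rois

    @property
    def roi_ids(self) -> list[str]:
        return [r.roi_id for r in self._rois]

    @property
    def structures(self) -> list[str]:
        """Structure codes present, in canonical order."""
        present = {r.structure for r in self._rois}
        return [s for s in STRUCTURES if s in present]

    def index_of(self, roi_id: str) -> int:
        try:
            return self._index[roi_id]
        except KeyError:
            raise RegistryError(f"ROI {roi_id!r} not in registry") from None

    def structure_of(self, roi_id: str) -> str:
        return self[roi_id].structure

    def rois_in(self, structure: str) -> list[ROI]:
        if structure not in STRUCTURES:
            raise RegistryError(f"unknown structure code {structure!r}")
        return [r for r in self._rois if r.structure == structure]

    def structure_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self._rois:
            counts[r.structure] = counts.get(r.structure, 0) + 1
        return counts

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(REGISTRY_COLUMNS)
            for r in self._rois:
                writer.writerow(
                    [r.roi_id, r.structure, r.subdivision, r.domain_label,
                     format(r.bregma_mm, "+.1f")]
                )

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "roi_id": r.roi_id,
                "structure": r.structure,
                "subdivision": r.subdivision,
                "domain_label": r.domain_label,
                "bregma_mm": r.bregma_mm,
            }
            for r in self._rois
        ]
        Path(path).write_text(json.dumps(records, indent=1), encoding="utf-8")


def _roi_from_record(record: dict, where: str) -> ROI:
    missing = [c for c in REGISTRY_COLUMNS if c not in record or record[c] in (None, "")]
    if missing:
        raise RegistryError(f"{where}: missing field(s) {missing}")
    try:
        bregma = float(record["bregma_mm"])
    except (TypeError, ValueError):
        raise RegistryError(
            f"{where}: bregma_mm {record['bregma_mm']!r} is not a decimal number"
        ) from None
    return ROI(
        roi_id=str(record["roi_id"]),
        structure=str(record["structure"]),
        subdivision=str(record["subdivision"]),
        domain_label=str(record["domain_label"]),
        bregma_mm=bregma,
    )


def load_registry(path: str | Path) -> ROIRegistry:
    """Load a registry from CSV (header ``roi_id,structure,subdivision,
    domain_label,bregma_mm``) or JSON (array of objects with those keys).

    Raises
    ------
    RegistryError
        On a malformed row (named by position), a duplicate ``roi_id`` or an
        unknown structure code.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        rois = [_roi_from_record(rec, f"{path.name} entry {i}") for i, rec in enumerate(records)]
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(REGISTRY_COLUMNS) - set(reader.fieldnames):
                raise RegistryError(
                    f"{path.name}: expected header {','.join(REGISTRY_COLUMNS)}"
                )
            rois = [
                _roi_from_record(row, f"{path.name} row {i}")
                for i, row in enumerate(reader, start=2)
            ]
    return ROIRegistry(rois)


def pair_count(registry: ROIRegistry, structure_a: str, structure_b: str) -> int:
    """Number of unordered ROI pairs within or between two structures.

    For ``a == b`` with *k* ROIs this is ``k*(k-1)/2`` (no self-pairs); for
    ``a != b`` it is ``k_a * k_b``.  These denominators turn reliable-edge
    counts into connectivity-density percentages, e.g. 66 caudoputamen ROIs
    give 2145 within-CP pairs and, with 21 thalamic ROIs, 1386 CP-TH pairs.
    """
    counts = registry.structure_counts()
    for code in (structure_a, structure_b):
        if code not in STRUCTURES:
            raise RegistryError(f"unknown structure code {code!r}")
        if code not in counts:
            raise RegistryError(f"structure {code!r} absent from registry")
    if structure_a == structure_b:
        k = counts[structure_a]
        return k * (k - 1) // 2
    return counts[structure_a] * counts[structure_b]


# --------------------------------------------------------------- default map
# Per-structure layout of the shipped 176-ROI parcellation.  CP=66 and TH=21
# are fixed; SNr/GPe/MOTOR/PFC counts (25/27/18/19) are uniquely determined by
# the within- and between-structure density percentages together with their
# integer edge counts (see docs/methods.md).  The per-bregma grouping emulates
# the published scheme: a handful of domain ROIs per coronal level, rostral to
# caudal.
_DEFAULT_LAYOUT: dict[str, list[tuple[str, float, list[str]]]] = {
    # structure -> [(subdivision, bregma_mm, domain labels at that level), ...]
    "CP": [
        ("CPr", 1.3, ["imd", "imv", "m", "l", "vm"]),
        ("CPr", 0.9, ["imd", "imv", "m", "l", "vm", "ic"]),
        ("CPi", 0.5, ["dm.d", "dm.im", "dl.d", "dl.imd", "vm.v", "vm.vm", "vl.v"]),
        ("CPi", 0.1, ["dm.d", "dm.dm", "dm.im", "dl.d", "dl.imd", "dl.imv", "vm.v", "vm.vm", "vl.v"]),
        ("CPi", -0.2, ["dm.d", "dm.dm", "dm.im", "dm.dl", "dl.d", "dl.imd", "vm.v", "vm.cvm", "vl.imv"]),
        ("CPi", -0.5, ["dm.d", "dm.dm", "dm.cd", "dl.d", "dl.sc", "vm.v", "vl.v", "vl.vt"]),
        ("CPc", -0.8, ["d.dm", "d.dl", "d.vm", "i.d", "i.vm", "i.vl", "v.vm", "v.vl"]),
        ("CPc", -1.1, ["d.dm", "d.dl", "i.d", "i.vm", "i.vl", "v.vm", "v.vl"]),
        ("CPc", -1.4, ["d.dm", "d.dl", "i.d", "i.vm", "i.vl", "v.vm", "v.vl"]),
    ],
    "SNr": [
        ("SNr", -2.9, ["r.m", "r.dm", "r.l", "r.dl", "r.v", "r.vl", "r.c", "r.cd"]),
        ("SNr", -3.4, ["i.m", "i.dm", "i.l", "i.dl", "i.v", "i.vl", "i.c", "i.cd", "i.cv"]),
        ("SNr", -3.9, ["c.m", "c.dm", "c.l", "c.dl", "c.v", "c.vl", "c.c", "c.cd"]),
    ],
    "GPe": [
        ("GPe", -0.5, ["r.dm", "r.dl", "r.im", "r.il", "r.vm", "r.vl", "r.cd", "r.cv", "r.c"]),
        ("GPe", -0.8, ["i.dm", "i.dl", "i.im", "i.il", "i.vm", "i.vl", "i.cd", "i.cv", "i.c", "i.x"]),
        ("GPe", -1.1, ["c.dm", "c.dl", "c.im", "c.il", "c.vm", "c.vl", "c.cd", "c.cv"]),
    ],
    "MOTOR": [
        ("M2", 1.3, ["m2.m", "m2.l"]),
        ("M1", 1.3, ["m1.d", "m1.v"]),
        ("M2", 0.8, ["m2.m", "m2.l"]),
        ("M1", 0.8, ["m1.d", "m1.im", "m1.v"]),
        ("M2", 0.1, ["m2.m", "m2.l"]),
        ("M1", 0.1, ["m1.d", "m1.im", "m1.v"]),
        ("M2", -0.5, ["m2.m"]),
        ("M1", -0.5, ["m1.d", "m1.im", "m1.v"]),
    ],
    "PFC": [
        ("PrL", 1.8, ["prl.d", "prl.v"]),
        ("IL", 1.8, ["il"]),
        ("Cg1", 1.8, ["cg1"]),
        ("PrL", 1.3, ["prl.d", "prl.v"]),
        ("IL", 1.3, ["il"]),
        ("Cg1", 1.3, ["cg1.d", "cg1.v"]),
        ("Cg2", 1.3, ["cg2"]),
        ("Cg1", 0.8, ["cg1.d", "cg1.v"]),
        ("Cg2", 0.8, ["cg2.d", "cg2.v"]),
        ("Cg1", 0.1, ["cg1.d", "cg1.v"]),
        ("Cg2", 0.1, ["cg2.d", "cg2.v"]),
        ("Cg2", -0.5, ["cg2"]),
    ],
    "TH": [
        ("AD", -0.7, ["ad"]),
        ("AV", -0.7, ["av.d", "av.v"]),
        ("AM", -0.7, ["am"]),
        ("VA/VL", -0.7, ["va"]),
        ("AD", -1.2, ["ad"]),
        ("AV", -1.2, ["av"]),
        ("AM", -1.2, ["am"]),
        ("CM", -1.2, ["cm"]),
        ("MD", -1.2, ["md.m", "md.l"]),
        ("VA/VL", -1.2, ["vl.d", "vl.v"]),
        ("VM", -1.2, ["vm"]),
        ("CM", -1.7, ["cm"]),
        ("MD", -1.7, ["md.m", "md.l", "md.c"]),
        ("VA/VL", -1.7, ["vl.d", "vl.v"]),
        ("VM", -1.7, ["vm"]),
    ],
}

#: Expected per-structure sizes of the shipped registry.
DEFAULT_STRUCTURE_COUNTS = {"CP": 66, "SNr": 25, "GPe": 27, "MOTOR": 18, "PFC": 19, "TH": 21}


def default_registry_path() -> Path:
    """Path of the shipped registry CSV (identical to :func:`default_registry`)."""
    return Path(__file__).parent / "data" / "default_registry.csv"


def default_registry() -> ROIRegistry:
    """Build the shipped 176-ROI CBT parcellation.

    Deterministic: grouped by structure in canonical order, then by bregma
    level rostral to caudal, then by domain order within the level.
    """
    rois: list[ROI] = []
    for structure in STRUCTURES:
        levels = sorted(
            _DEFAULT_LAYOUT[structure],
            key=lambda lv: -lv[1],  # rostral (larger bregma) first
        )
        for subdivision, bregma, domains in levels:
            for domain in domains:
                roi_id = f"{subdivision}{bregma:+.1f}_{domain}"
                rois.append(
                    ROI(
                        roi_id=roi_id,
                        structure=structure,
                        subdivision=subdivision,
                        domain_label=f"{subdivision}.{domain}",
                        bregma_mm=bregma,
                    )
                )
    registry = ROIRegistry(rois)
    counts = registry.structure_counts()
    if counts != DEFAULT_STRUCTURE_COUNTS or len(registry) != 176:
        raise RegistryError(f"default registry inconsistent: {counts}")
    return registry
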