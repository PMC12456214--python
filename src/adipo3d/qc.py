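"""Post-segmentation mask quality control.

Three conjunctive filters applied in a fixed order: (1) discard cells
touching any stack border (they are truncated, so their volume and shape
are meaningless), (2) discard cells smaller than a voxel-count floor,
(3) discard cells below a sphericity floor (segmentation artefacts such
as ECM slivers). The defaults — 5000 voxels at the 1.15 µm acquisition
pitch (≈ 24.4 µm equivalent diameter) and sphericity 0.35 — are the
filter settings of the emulated study. Both inequalities are strict:
cells *under* the floor are removed, cells exactly at it retained.

Because the filters are conjunctive the retained set does not depend on
their order; only the attribution of removals in the report does (each
cell is counted against the first filter that removes it).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Physical volume of the default voxel-count floor at the reference
#: 1.15 µm isotropic pitch (5000 × 1.15³ µm³).
REFERENCE_MIN_VOLUME_UM3 = 5000 * 1.15**3


@dataclass
class QCParams:
    """Filter thresholds.

    ``min_voxels`` is a count at acquisition spacing (the study's floor is
    defined in voxels, not µm³); use :meth:`for_spacing` to carry the same
    physical floor to a stack acquired or simulated at another pitch.
    ``exclusion_list`` holds label_ids rejected by manual review.
    """

    min_voxels: int = 5000
    min_sphericity: float = 0.35
    drop_border: bool = True
    exclusion_list: tuple[int, ...] = ()

    def __post_init__(self):
        if self.min_voxels < 0:
            raise ValueError("min_voxels must be >= 0")
        if not 0.0 <= self.min_sphericity <= 1.0:
            raise ValueError("min_sphericity must be in [0, 1]")
        self.exclusion_list = tuple(int(i) for i in self.exclusion_list)

    @classmethod
    def for_spacing(cls, spacing, min_volume_um3: float = REFERENCE_MIN_VOLUME_UM3,
                    **kwargs) -> "QCParams":
        """Same physical volume floor expressed in voxels of ``spacing``."""
        voxel = float(np.prod(spacing))
        return cls(min_voxels=int(round(min_volume_um3 / voxel)), **kwargs)

    @property
    def min_volume_um3_at_reference(self) -> float:
        return self.min_voxels * 1.15**3


@dataclass
class QCReport:
    """Counts at each filter stage; conserves
    n_input = n_retained + n_removed_border + n_removed_volume
    + n_removed_sphericity + n_removed_manual."""

    n_input: int
    n_removed_border: int
    n_removed_volume: int
    n_removed_sphericity: int
    n_removed_manual: int
    n_retained: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        removed = (
            self.n_removed_border
            + self.n_removed_volume
            + self.n_removed_sphericity
            + self.n_removed_manual
        )
        assert self.n_input == self.n_retained + removed

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(missing)


def remove_border_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cell table into (interior cells, border-touching cells)."""
    _require(table, ["touches_border"])
    border = table["touches_border"].astype(bool)
    return table[~border].copy(), table[border].copy()


def apply_filters(
    table: pd.DataFrame, params: QCParams | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the QC filters and report per-stage removal counts.

    Order of attribution: manual exclusions, border contact, voxel count,
    sphericity. Inequalities are strict (``<`` the floor removes).
    """
    params = params or QCParams()
    _require(table, ["voxel_count", "sphericity"])
    if params.drop_border:
        _require(table, ["touches_border"])

    n_input = len(table)
    kept = table
    n_manual = 0
    if params.exclusion_list:
        _require(table, ["label_id"])
        manual = kept["label_id"].isin(params.exclusion_list)
        n_manual = int(manual.sum())
        kept = kept[~manual]
    n_border = 0
    if params.drop_border:
        kept, border = remove_border_labels(kept)
        n_border = len(border)
    small = kept["voxel_count"] < params.min_voxels
    n_volume = int(small.sum())
    kept = kept[~small]
    aspher = kept["sphericity"] < params.min_sphericity
    n_spher = int(aspher.sum())
    kept = kept[~aspher].copy()

    report = QCReport(
        n_input=n_input,
        n_removed_border=n_border,
        n_removed_volume=n_volume,
        n_removed_sphericity=n_spher,
        n_removed_manual=n_manual,
        n_retained=len(kept),
        params={
            "min_voxels": params.min_voxels,
            "min_volume_um3_at_reference_spacing": params.min_volume_um3_at_reference,
            "min_sphericity": params.min_sphericity,
            "drop_border": params.drop_border,
            "n_excluded_manually": n_manual,
        },
    )
    return kept, report
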