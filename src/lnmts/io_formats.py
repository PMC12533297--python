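"""Reading and writing the pipeline's external representations.

Two kinds of artifact cross the package boundary:

* instance-labeled 3D volumes (NIfTI) with acquisition geometry supplied
  either in the NIfTI header or in a YAML/JSON sidecar (sidecar wins), and
* cohort tables (CSV) with survival times, event flags and covariates.

Axis convention: array axis 0 is the slice index S (through-plane), axes
1 and 2 are in-plane rows/columns.  All geometry is in millimetres.
Readers never repair data silently: every rejected row or invalid volume
raises or is reported with its location.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

logger = logging.getLogger("lnmts")

BACKGROUND_LABEL = 0
TUMOR_LABEL = 1
FIRST_NODE_LABEL = 2


class VolumeFormatError(ValueError):
    """Raised when an input volume violates the label/geometry contract."""


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the row contract."""


@dataclass
class AnnotatedVolume:
    """Instance-labeled voxel grid plus acquisition geometry.

    ``voxels`` holds integer labels: 0 = background, 1 = tumor, >=2 = one
    label per lymph node.  ``pixel_spacing_row``/``pixel_spacing_col`` are
    the in-plane spacings (mm/pixel), ``slice_thickness_T`` the section
    thickness T (mm) and ``slice_gap_G`` the inter-section gap G (mm).
    """

    voxels: np.ndarray
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness_T: float
    slice_gap_G: float
    patient_id: str = "anonymous"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"{self.patient_id}: expected a 3D (slice, row, col) array, "
                f"got ndim={self.voxels.ndim}"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if np.issubdtype(self.voxels.dtype, np.floating) and np.all(
                self.voxels == np.round(self.voxels)
            ):
                self.voxels = self.voxels.astype(np.int32)
            else:
                raise VolumeFormatError(
                    f"{self.patient_id}: labels must be integers"
                )
        for name in ("pixel_spacing_row", "pixel_spacing_col", "slice_thickness_T"):
            value = float(getattr(self, name))
            if not value > 0:
                raise VolumeFormatError(
                    f"{self.patient_id}: {name} must be strictly positive, got {value}"
                )
            setattr(self, name, value)
        self.slice_gap_G = float(self.slice_gap_G)
        if self.slice_gap_G < 0:
            raise VolumeFormatError(
                f"{self.patient_id}: slice_gap_G must be >= 0, got {self.slice_gap_G}"
            )
        if self.voxels.min() < 0:
            raise VolumeFormatError(f"{self.patient_id}: negative labels present")
        if not np.any(self.voxels == TUMOR_LABEL):
            raise VolumeFormatError(f"{self.patient_id}: tumor label absent")

    @property
    def node_labels(self) -> list[int]:
        """Sorted instance labels of all lymph nodes (>= 2)."""
        labels = np.unique(self.voxels)
        return [int(l) for l in labels if l >= FIRST_NODE_LABEL]

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area p (mm^2), the per-pixel factor of V = N x p."""
        return self.pixel_spacing_row * self.pixel_spacing_col

    def geometry_dict(self) -> dict[str, float]:
        return {
            "pixel_spacing_row": self.pixel_spacing_row,
            "pixel_spacing_col": self.pixel_spacing_col,
            "slice_thickness_T": self.slice_thickness_T,
            "slice_gap_G": self.slice_gap_G,
        }


@dataclass
class CohortRecord:
    """One patient's survival record: OS/DFS time (days), event flags, covariates."""

    patient_id: str
    os_time: float
    os_event: int
    dfs_time: float | None = None
    dfs_event: int | None = None
    covariates: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.os_time = float(self.os_time)
        if self.os_time < 0:
            raise CohortFormatError(f"{self.patient_id}: negative os_time")
        if self.os_event not in (0, 1):
            raise CohortFormatError(
                f"{self.patient_id}: os_event must be 0 or 1, got {self.os_event}"
            )
        self.os_event = int(self.os_event)
        if self.dfs_time is not None:
            self.dfs_time = float(self.dfs_time)
            if self.dfs_time < 0:
                raise CohortFormatError(f"{self.patient_id}: negative dfs_time")
        if self.dfs_event is not None:
            if self.dfs_event not in (0, 1):
                raise CohortFormatError(
                    f"{self.patient_id}: dfs_event must be 0 or 1, got {self.dfs_event}"
                )
            self.dfs_event = int(self.dfs_event)


# 26-connectivity: any touching voxels (face, edge or corner) are one node
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def relabel_single_node_mask(voxels: np.ndarray) -> np.ndarray:
    """Split a merged single 'node' label into instances by 26-connectivity.

    Some exports collapse all nodes onto one label; nodes are annotated
    individually here, so a mask whose only non-tumor label is a single
    value is relabeled into connected components 2..K with a warning.
    """
    out = np.where(voxels >= FIRST_NODE_LABEL, 1, 0)
    components, n = ndimage.label(out, structure=_STRUCT_26)
    relabeled = np.where(voxels == TUMOR_LABEL, TUMOR_LABEL, 0).astype(np.int32)
    relabeled[components > 0] = components[components > 0] + 1
    warnings.warn(
        f"single node label split into {n} instances by 26-connectivity",
        stacklevel=2,
    )
    return relabeled


def _load_sidecar(path: Path) -> dict[str, Any]:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


_GEOMETRY_KEYS = (
    "pixel_spacing_row",
    "pixel_spacing_col",
    "slice_thickness_T",
    "slice_gap_G",
)


def read_annotated_volume(
    image_path: str | Path,
    metadata: str | Path | Mapping[str, Any] | None = None,
    patient_id: str | None = None,
    relabel_merged: bool = True,
) -> AnnotatedVolume:
    """Read a NIfTI instance-label volume plus geometry into an AnnotatedVolume.

    Geometry (pixel spacings, slice thickness T, slice gap G) is taken from
    ``metadata`` — a sidecar YAML/JSON path or a mapping — when given;
    otherwise spacings and thickness come from the NIfTI header with G = 0
    only if the sidecar explicitly permits none.  When both header and
    sidecar carry a value the sidecar wins (logged).  Missing thickness or
    spacing is a hard error; nothing is defaulted silently.
    """
    image_path = Path(image_path)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.all(data == np.round(data)):
            data = data.astype(np.int32)
        else:
            raise VolumeFormatError(f"{image_path}: non-integer labels")
    # NIfTI stores (x, y, z); our convention is (slice, row, col) = (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]

    meta: dict[str, Any] = {}
    if metadata is not None:
        if isinstance(metadata, (str, Path)):
            meta = dict(_load_sidecar(Path(metadata)))
        else:
            meta = dict(metadata)

    geometry: dict[str, float] = {}
    header_geometry = {
        "pixel_spacing_row": float(zooms[1]),
        "pixel_spacing_col": float(zooms[0]),
        # header voxel z-size is center-to-center spacing = T + G; without a
        # sidecar the split between T and G is unknowable, so require it
    }
    for key in _GEOMETRY_KEYS:
        if key in meta:
            if key in header_geometry and not np.isclose(
                meta[key], header_geometry[key]
            ):
                logger.info(
                    "%s: sidecar %s=%s overrides header value %s",
                    image_path.name, key, meta[key], header_geometry[key],
                )
            geometry[key] = float(meta[key])
        elif key in header_geometry:
            geometry[key] = header_geometry[key]
    missing = [k for k in _GEOMETRY_KEYS if k not in geometry]
    if missing:
        raise VolumeFormatError(
            f"{image_path}: missing geometry {missing}; supply a sidecar "
            "with slice_thickness_T and slice_gap_G (no silent defaults)"
        )

    pid = patient_id or meta.get("patient_id") or image_path.name.split(".")[0]

    node_values = np.unique(voxels[voxels >= FIRST_NODE_LABEL])
    if relabel_merged and len(node_values) == 1:
        n_components = ndimage.label(voxels == node_values[0], _STRUCT_26)[1]
        if n_components > 1:
            voxels = relabel_single_node_mask(voxels)

    return AnnotatedVolume(voxels=voxels, patient_id=str(pid), **geometry)


def write_annotated_volume(
    volume: AnnotatedVolume, image_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a volume as NIfTI (+ YAML sidecar); inverse of read_annotated_volume."""
    image_path = Path(image_path)
    data = np.transpose(volume.voxels.astype(np.int16), (2, 1, 0))
    affine = np.diag(
        [
            volume.pixel_spacing_col,
            volume.pixel_spacing_row,
            volume.slice_thickness_T + volume.slice_gap_G,
            1.0,
        ]
    )
    nib.save(nib.Nifti1Image(data, affine), str(image_path))
    if sidecar_path is not None:
        sidecar = {"patient_id": volume.patient_id, **volume.geometry_dict()}
        Path(sidecar_path).write_text(yaml.safe_dump(sidecar, sort_keys=True))


_DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "os_time": "os_time",
    "os_event": "os_event",
    "dfs_time": "dfs_time",
    "dfs_event": "dfs_event",
}


def read_cohort_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[CohortRecord]:
    """Read a cohort CSV into typed CohortRecords.

    ``columns`` maps the canonical field names (patient_id, os_time,
    os_event, dfs_time, dfs_event) to the file's column names.  Any other
    column becomes a covariate.  Malformed rows (bad event flag, negative
    time, missing mandatory field) raise when ``strict``; otherwise they
    are dropped with a row-level log report.  Duplicate patient ids are
    always an error.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    mandatory = [colmap["patient_id"], colmap["os_time"], colmap["os_event"]]
    for col in mandatory:
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing mandatory column {col!r}")
    known = {v for k, v in colmap.items() if v in df.columns}
    covariate_cols = [c for c in df.columns if c not in known]

    records: list[CohortRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            if any(pd.isna(row[c]) for c in mandatory):
                raise CohortFormatError("missing mandatory field")
            rec = CohortRecord(
                patient_id=str(row[colmap["patient_id"]]),
                os_time=row[colmap["os_time"]],
                os_event=row[colmap["os_event"]],
                dfs_time=(
                    row[colmap["dfs_time"]]
                    if colmap["dfs_time"] in df.columns
                    and not pd.isna(row[colmap["dfs_time"]])
                    else None
                ),
                dfs_event=(
                    row[colmap["dfs_event"]]
                    if colmap["dfs_event"] in df.columns
                    and not pd.isna(row[colmap["dfs_event"]])
                    else None
                ),
                covariates={c: row[c] for c in covariate_cols},
            )
        except (CohortFormatError, ValueError) as exc:
            if strict:
                raise CohortFormatError(f"{path} row {idx}: {exc}") from exc
            rejected.append((int(idx), str(exc)))
            continue
        records.append(rec)

    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortFormatError(f"{path}: duplicate patient_id(s) {dupes}")
    for idx, reason in rejected:
        logger.warning("%s row %d rejected: %s", path, idx, reason)
    return records


def write_cohort_table(records: list[CohortRecord], path: str | Path) -> None:
    """Write CohortRecords as CSV; inverse of read_cohort_table."""
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "patient_id": r.patient_id,
            "os_time": r.os_time,
            "os_event": r.os_event,
        }
        if r.dfs_time is not None:
            row["dfs_time"] = r.dfs_time
        if r.dfs_event is not None:
            row["dfs_event"] = r.dfs_event
        row.update(r.covariates)
        rows.append(row)
    # %.17g keeps write->read the identity for float fields
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records (covariates as columns) into a DataFrame indexed by row."""
    rows = []
    for r in records:
        row = dataclasses.asdict(r)
        row.update(row.pop("covariates"))
        rows.append(row)
    return pd.DataFrame(rows)
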