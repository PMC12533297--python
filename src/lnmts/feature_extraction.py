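"""Per-node and per-patient lymph-node imaging features.

Two quantitative features are computed from an instance-labeled MRI mask:

* **tLNV** (total lymph-node volume, mm^3): each node's volume is
  approximated as V = N x p, where N is its pixel count and p the in-plane
  pixel area; the patient total is V_total = sum_i V_i.
* **tLND** (total lymph-node drainage distance, mm): each node's distance
  to the tumor center is the Euclidean distance of the two centroids, with
  the through-plane term built from the slice-index difference dS, section
  thickness T and inter-section gap G as (dS*G + (dS-1)*T); the patient
  total is D_total = sum_i D_i.

The through-plane rule is applied exactly as formulated, except that the
same-slice case dS = 0 uses a zero through-plane term (the literal
expression would give (-T)^2 = T^2 for two structures on one slice, which
contradicts the plain 3D Euclidean definition it specializes; see
docs/methods.md).

Volume modes
------------
``accumulated`` (default)
    N = node voxels summed over all slices, V = N x p.
``max_cross_section``
    N = voxel count of the node's largest single-slice cross-section.
``voxel_volume``
    V = N_accumulated x p x (T + G), a true volumetric estimate.

The first two follow the published formulation, which labels V in mm^3
although N x p is dimensionally an area; the mode used is therefore carried
in every output so numbers stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import TUMOR_LABEL, AnnotatedVolume

VOLUME_MODES = ("accumulated", "max_cross_section", "voxel_volume")

# individual-node annotation defaults: 0.5 cm diameter, 5 cm distance
DEFAULT_SIZE_THRESHOLD_MM = 5.0
DEFAULT_DISTANCE_THRESHOLD_MM = 50.0


@dataclass
class NodeFeature:
    """One lymph node's count, volume, centroid and drainage distance."""

    node_label: int
    pixel_count: int = 0
    volume: float = 0.0
    max_cross_section_count: int = 0
    centroid_slice: float = float("nan")  # fractional slice index
    centroid_row_mm: float = float("nan")
    centroid_col_mm: float = float("nan")
    delta_S: int = 0
    distance: float = float("nan")
    size_class: str = ""      # S-LN / L-LN
    distance_class: str = ""  # N-LN / D-LN


@dataclass
class PatientFeatures:
    """Aggregated per-patient features: tLNV, tLND and the node count."""

    patient_id: str
    tlnv: float
    tlnd: float
    node_count: int
    nodes: list[NodeFeature] = field(default_factory=list)
    volume_mode: str = "accumulated"
    no_nodes_flag: bool = False


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (np.round ties to even)."""
    return int(np.floor(np.abs(x) + 0.5) * np.sign(x)) if x != 0 else 0


def _label_indices(volume: AnnotatedVolume, label: int) -> tuple[np.ndarray, ...]:
    idx = np.nonzero(volume.voxels == label)
    if idx[0].size == 0:
        raise ValueError(f"{volume.patient_id}: label {label} absent from mask")
    return idx


def _centroid(volume: AnnotatedVolume, label: int) -> tuple[float, float, float]:
    """(slice index, row mm, col mm) centroid of a structure's voxel centers."""
    s, r, c = _label_indices(volume, label)
    return (
        float(s.mean()),
        float(r.mean()) * volume.pixel_spacing_row,
        float(c.mean()) * volume.pixel_spacing_col,
    )


def through_plane_distance(delta_S: int, thickness_T: float, gap_G: float) -> float:
    """Through-plane offset (mm) for a slice-index difference of dS sections.

    dS x G + (dS - 1) x T for dS >= 1; zero for dS = 0 (same slice).
    """
    if delta_S < 0:
        raise ValueError("delta_S must be non-negative")
    if delta_S == 0:
        return 0.0
    return delta_S * gap_G + (delta_S - 1) * thickness_T


def node_volume(
    volume: AnnotatedVolume, node_label: int, mode: str = "accumulated"
) -> NodeFeature:
    """Compute a node's pixel count N and volume V = N x p (see module docs)."""
    if mode not in VOLUME_MODES:
        raise ValueError(f"unknown volume mode {mode!r}; expected one of {VOLUME_MODES}")
    s, _, _ = _label_indices(volume, node_label)
    n_total = int(s.size)
    per_slice = np.bincount(s)
    n_max = int(per_slice.max())
    p = volume.pixel_area
    if mode == "accumulated":
        n, v = n_total, n_total * p
    elif mode == "max_cross_section":
        n, v = n_max, n_max * p
    else:  # voxel_volume
        n = n_total
        v = n_total * p * (volume.slice_thickness_T + volume.slice_gap_G)
    return NodeFeature(
        node_label=int(node_label),
        pixel_count=n,
        volume=float(v),
        max_cross_section_count=n_max,
    )


def node_distance(volume: AnnotatedVolume, node_label: int) -> NodeFeature:
    """Drainage distance D (mm) from a node's centroid to the tumor centroid.

    In-plane terms use physical mm offsets of the two centroids; the
    through-plane term uses the rounded slice-index difference dS with
    thickness T and gap G (zero when dS = 0).
    """
    ns, nr, nc = _centroid(volume, node_label)
    ts, tr, tc = _centroid(volume, TUMOR_LABEL)
    delta_S = abs(_round_half_away(ns) - _round_half_away(ts))
    dz = through_plane_distance(delta_S, volume.slice_thickness_T, volume.slice_gap_G)
    d = float(np.sqrt((nr - tr) ** 2 + (nc - tc) ** 2 + dz**2))
    return NodeFeature(
        node_label=int(node_label),
        centroid_slice=ns,
        centroid_row_mm=nr,
        centroid_col_mm=nc,
        delta_S=delta_S,
        distance=d,
    )


def node_features(
    volume: AnnotatedVolume, node_label: int, mode: str = "accumulated"
) -> NodeFeature:
    """Full per-node feature record (volume + distance + classes)."""
    nv = node_volume(volume, node_label, mode=mode)
    nd = node_distance(volume, node_label)
    merged = NodeFeature(
        node_label=nv.node_label,
        pixel_count=nv.pixel_count,
        volume=nv.volume,
        max_cross_section_count=nv.max_cross_section_count,
        centroid_slice=nd.centroid_slice,
        centroid_row_mm=nd.centroid_row_mm,
        centroid_col_mm=nd.centroid_col_mm,
        delta_S=nd.delta_S,
        distance=nd.distance,
    )
    annotate_node_classes([merged], pixel_area=volume.pixel_area)
    return merged


def equivalent_diameter(max_cross_section_count: int, pixel_area: float) -> float:
    """Diameter (mm) of the circle with the node's maximal cross-section area."""
    area = max_cross_section_count * pixel_area
    return float(2.0 * np.sqrt(area / np.pi))


def annotate_node_classes(
    nodes: list[NodeFeature],
    pixel_area: float,
    size_threshold_mm: float = DEFAULT_SIZE_THRESHOLD_MM,
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
) -> list[NodeFeature]:
    """Annotate each node as S-LN/L-LN (by equivalent diameter, inclusive >=
    threshold) and N-LN/D-LN (by drainage distance, inclusive >= threshold).

    Defaults follow the 0.5 cm diameter and 5 cm distance dichotomies.
    Mutates and returns ``nodes``.
    """
    for node in nodes:
        diam = equivalent_diameter(node.max_cross_section_count, pixel_area)
        node.size_class = "L-LN" if diam >= size_threshold_mm else "S-LN"
        if np.isfinite(node.distance):
            node.distance_class = (
                "D-LN" if node.distance >= distance_threshold_mm else "N-LN"
            )
    return nodes


def patient_features(
    volume: AnnotatedVolume,
    mode: str = "accumulated",
    size_threshold_mm: float = DEFAULT_SIZE_THRESHOLD_MM,
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
) -> PatientFeatures:
    """Aggregate all nodes of one patient into tLNV, tLND and node count.

    A patient with zero visible nodes yields (0, 0, 0) with
    ``no_nodes_flag`` set — an empty sum, not an error.
    """
    nodes = [node_features(volume, lbl, mode=mode) for lbl in volume.node_labels]
    annotate_node_classes(
        nodes,
        pixel_area=volume.pixel_area,
        size_threshold_mm=size_threshold_mm,
        distance_threshold_mm=distance_threshold_mm,
    )
    return PatientFeatures(
        patient_id=volume.patient_id,
        tlnv=float(sum(n.volume for n in nodes)),
        tlnd=float(sum(n.distance for n in nodes)),
        node_count=len(nodes),
        nodes=nodes,
        volume_mode=mode,
        no_nodes_flag=(len(nodes) == 0),
    )


def features_to_frame(patients: list[PatientFeatures]) -> pd.DataFrame:
    """Per-patient feature table (one row per patient)."""
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "tlnv": p.tlnv,
                "tlnd": p.tlnd,
                "node_count": p.node_count,
                "volume_mode": p.volume_mode,
                "no_nodes": p.no_nodes_flag,
            }
            for p in patients
        ]
    )


def nodes_to_frame(patients: list[PatientFeatures]) -> pd.DataFrame:
    """Per-node feature table (one row per node, all patients)."""
    rows = []
    for p in patients:
        for n in p.nodes:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "node_label": n.node_label,
                    "pixel_count": n.pixel_count,
                    "volume": n.volume,
                    "max_cross_section_count": n.max_cross_section_count,
                    "delta_S": n.delta_S,
                    "distance": n.distance,
                    "size_class": n.size_class,
                    "distance_class": n.distance_class,
                }
            )
    return pd.DataFrame(rows)


class LymphNodeFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping AnnotatedVolumes to a per-patient feature table.

    Stateless (fit is a no-op); exists so feature extraction composes with
    scikit-learn pipelines feeding the risk stratifier.

    Parameters
    ----------
    mode : str
        Volume mode, one of ``accumulated``, ``max_cross_section``,
        ``voxel_volume``.
    size_threshold_mm, distance_threshold_mm : float
        Per-node S/L-LN and N/D-LN annotation thresholds.
    """

    def __init__(
        self,
        mode: str = "accumulated",
        size_threshold_mm: float = DEFAULT_SIZE_THRESHOLD_MM,
        distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
    ):
        self.mode = mode
        self.size_threshold_mm = size_threshold_mm
        self.distance_threshold_mm = distance_threshold_mm

    def fit(self, X: list[AnnotatedVolume], y=None) -> "LymphNodeFeatureExtractor":
        if self.mode not in VOLUME_MODES:
            raise ValueError(f"unknown volume mode {self.mode!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: list[AnnotatedVolume]) -> pd.DataFrame:
        extracted = [
            patient_features(
                v,
                mode=self.mode,
                size_threshold_mm=self.size_threshold_mm,
                distance_threshold_mm=self.distance_threshold_mm,
            )
            for v in X
        ]
        return features_to_frame(extracted).set_index("patient_id")
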