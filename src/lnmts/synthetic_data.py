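"""Synthetic inputs with known ground truth.

Two generators back the test- and demo-oracles of the pipeline:

* **Phantoms** — instance-labeled volumes containing one ellipsoidal tumor
  and ellipsoidal lymph nodes rasterized onto a slice grid with known
  geometry.  A voxel belongs to a shape iff its center lies inside the
  ellipsoid, so the emitted mask has exact, recountable ground truth.  The
  :class:`GroundTruth` for each phantom is computed by a deliberately
  plain, self-contained routine (explicit accumulation loops, no shared
  code with :mod:`lnmts.feature_extraction`) so that agreement between the
  two is a meaningful equivalence check.

* **Cohorts** — survival datasets whose hazards depend on planted subtype
  membership or on which side of planted feature cutpoints each subject
  falls, with censoring independent of the event process.  Baseline event
  times are exponential with a median of about five years (or Weibull),
  with administrative censoring at the follow-up horizon and an optional
  independent early-censoring process calibrated to a target marginal
  censoring fraction.

All randomness flows through explicit integer seeds; the same seed
reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotatedVolume, CohortRecord

FIVE_YEARS_DAYS = 1826.0
DEFAULT_HORIZON_DAYS = 3652.0  # ten-year administrative follow-up limit


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in physical mm: center (z, y, x) and radii."""

    center_mm: tuple[float, float, float]   # (through-plane z, row y, col x)
    radii_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.radii_mm):
            raise ValueError("radii must be non-negative")


@dataclass
class PhantomSpec:
    """Geometry of one synthetic patient volume."""

    shape: tuple[int, int, int]             # (slices, rows, cols)
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness_T: float
    slice_gap_G: float
    tumor: Ellipsoid = None  # type: ignore[assignment]
    nodes: list[Ellipsoid] = field(default_factory=list)
    patient_id: str = "phantom"

    @property
    def slice_pitch(self) -> float:
        """Center-to-center through-plane distance of adjacent slices."""
        return self.slice_thickness_T + self.slice_gap_G


@dataclass
class NodeGroundTruth:
    node_label: int
    voxel_count: int
    max_cross_section_count: int
    centroid_slice: float
    centroid_row_mm: float
    centroid_col_mm: float
    delta_S: int
    distance_mm: float


@dataclass
class GroundTruth:
    """Exact per-node counts, centroids and drainage distances of a phantom."""

    tumor_voxel_count: int
    tumor_centroid_slice: float
    nodes: list[NodeGroundTruth]

    @property
    def total_volume_pixels(self) -> int:
        return sum(n.voxel_count for n in self.nodes)

    @property
    def total_distance_mm(self) -> float:
        return sum(n.distance_mm for n in self.nodes)


def _inside(z: float, y: float, x: float, e: Ellipsoid, eps: float = 1e-9) -> bool:
    """Voxel-center membership; a zero radius collapses that axis to a plane."""
    total = 0.0
    for d, r in zip((z - e.center_mm[0], y - e.center_mm[1], x - e.center_mm[2]), e.radii_mm):
        if r == 0.0:
            if abs(d) > eps:
                return False
        else:
            total += (d / r) ** 2
    return total <= 1.0 + eps


def _rasterize(spec: PhantomSpec, e: Ellipsoid) -> np.ndarray:
    """Boolean mask of voxel centers inside the ellipsoid (vectorized)."""
    ns, nr, nc = spec.shape
    z = np.arange(ns) * spec.slice_pitch
    y = np.arange(nr) * spec.pixel_spacing_row
    x = np.arange(nc) * spec.pixel_spacing_col
    eps = 1e-9
    terms = []
    for coord, c, r in zip((z, y, x), e.center_mm, e.radii_mm):
        d = coord - c
        if r == 0.0:
            terms.append(np.where(np.abs(d) > eps, np.inf, 0.0))
        else:
            terms.append((d / r) ** 2)
    total = (
        terms[0][:, None, None] + terms[1][None, :, None] + terms[2][None, None, :]
    )
    return total <= 1.0 + eps


def make_phantom(spec: PhantomSpec) -> tuple[AnnotatedVolume, GroundTruth]:
    """Rasterize a phantom spec and compute its ground truth independently.

    Raises if the tumor and nodes overlap on the voxel grid, or if any
    shape rasterizes to zero voxels (it would violate the mask contract).
    """
    if spec.tumor is None:
        raise ValueError("phantom needs a tumor ellipsoid")
    voxels = np.zeros(spec.shape, dtype=np.int32)
    tumor_mask = _rasterize(spec, spec.tumor)
    if not tumor_mask.any():
        raise ValueError("tumor rasterizes to zero voxels")
    voxels[tumor_mask] = 1
    for i, node in enumerate(spec.nodes):
        mask = _rasterize(spec, node)
        if not mask.any():
            raise ValueError(f"node {i} rasterizes to zero voxels")
        if np.any(voxels[mask] != 0):
            raise ValueError(f"node {i} overlaps a previously placed shape")
        voxels[mask] = i + 2
    volume = AnnotatedVolume(
        voxels=voxels,
        pixel_spacing_row=spec.pixel_spacing_row,
        pixel_spacing_col=spec.pixel_spacing_col,
        slice_thickness_T=spec.slice_thickness_T,
        slice_gap_G=spec.slice_gap_G,
        patient_id=spec.patient_id,
    )
    return volume, _ground_truth_from_mask(spec, voxels)


def _ground_truth_from_mask(spec: PhantomSpec, voxels: np.ndarray) -> GroundTruth:
    """Brute-force recount/centroid/distance, written as plain loops.

    Kept intentionally naive and free of any geometry code shared with the
    feature-extraction module: this is the oracle the features are checked
    against.
    """
    labels = sorted(int(v) for v in np.unique(voxels) if v >= 1)

    def recount(label: int):
        count = 0
        s_sum = r_sum = c_sum = 0.0
        per_slice: dict[int, int] = {}
        for (s, r, c) in np.argwhere(voxels == label):
            count += 1
            s_sum += float(s)
            r_sum += float(r)
            c_sum += float(c)
            per_slice[int(s)] = per_slice.get(int(s), 0) + 1
        return count, s_sum / count, r_sum / count, c_sum / count, max(per_slice.values())

    t_count, t_s, t_r, t_c = recount(1)[:4]
    tumor_slice_idx = int(math.floor(abs(t_s) + 0.5))  # round half away from zero

    nodes: list[NodeGroundTruth] = []
    for label in labels:
        if label == 1:
            continue
        count, s_mean, r_mean, c_mean, max_cs = recount(label)
        node_slice_idx = int(math.floor(abs(s_mean) + 0.5))
        d_s = abs(node_slice_idx - tumor_slice_idx)
        dy = (r_mean - t_r) * spec.pixel_spacing_row
        dx = (c_mean - t_c) * spec.pixel_spacing_col
        if d_s == 0:
            dz = 0.0
        else:
            dz = d_s * spec.slice_gap_G + (d_s - 1) * spec.slice_thickness_T
        nodes.append(
            NodeGroundTruth(
                node_label=label,
                voxel_count=count,
                max_cross_section_count=max_cs,
                centroid_slice=s_mean,
                centroid_row_mm=r_mean * spec.pixel_spacing_row,
                centroid_col_mm=c_mean * spec.pixel_spacing_col,
                delta_S=d_s,
                distance_mm=math.sqrt(dy * dy + dx * dx + dz * dz),
            )
        )
    return GroundTruth(
        tumor_voxel_count=t_count,
        tumor_centroid_slice=t_s,
        nodes=nodes,
    )


def random_phantom_spec(
    seed: int | np.random.Generator,
    max_nodes: int = 6,
    shape: tuple[int, int, int] = (20, 64, 64),
    patient_id: str | None = None,
) -> PhantomSpec:
    """Draw a random, non-overlapping phantom spec.

    Spacings, thickness and gap are drawn from clinically plausible MRI
    ranges (0.4–1.0 mm in-plane, T 3–5 mm, G 0–1.5 mm).  Node centers are
    snapped to voxel centers so every node rasterizes to at least one
    voxel.  Placement is by rejection sampling on pairwise center
    distances.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ns, nr, nc = shape
    sp_r = float(rng.uniform(0.4, 1.0))
    sp_c = float(rng.uniform(0.4, 1.0))
    T = float(rng.uniform(3.0, 5.0))
    G = float(rng.uniform(0.0, 1.5))
    pitch = T + G

    def snap(z, y, x):
        return (
            round(z / pitch) * pitch,
            round(y / sp_r) * sp_r,
            round(x / sp_c) * sp_c,
        )

    extent = (pitch * (ns - 1), sp_r * (nr - 1), sp_c * (nc - 1))
    tumor_radii = (
        float(rng.uniform(1.0, 2.0)) * pitch,
        float(rng.uniform(3.0, 8.0)),
        float(rng.uniform(3.0, 8.0)),
    )
    tumor_center = snap(
        extent[0] * rng.uniform(0.35, 0.65),
        extent[1] * rng.uniform(0.35, 0.65),
        extent[2] * rng.uniform(0.35, 0.65),
    )
    shapes = [Ellipsoid(tumor_center, tumor_radii)]

    def fits(center, radii):
        for coord, c, r, e in zip(range(3), center, radii, extent):
            if c - r < 0 or c + r > e:
                return False
        for other in shapes:
            gap = math.dist(center, other.center_mm)
            if gap < max(radii) + max(other.radii_mm) + 1.0:
                return False
        return True

    n_nodes = int(rng.integers(1, max_nodes + 1))
    nodes: list[Ellipsoid] = []
    attempts = 0
    while len(nodes) < n_nodes and attempts < 400:
        attempts += 1
        radii = (
            float(rng.uniform(0.4, 1.2)) * pitch,
            float(rng.uniform(0.8, 3.0)),
            float(rng.uniform(0.8, 3.0)),
        )
        center = snap(
            extent[0] * rng.uniform(0.1, 0.9),
            extent[1] * rng.uniform(0.1, 0.9),
            extent[2] * rng.uniform(0.1, 0.9),
        )
        if fits(center, radii):
            node = Ellipsoid(center, radii)
            shapes.append(node)
            nodes.append(node)
    pid = patient_id or f"phantom-{rng.integers(1, 10**9)}"
    return PhantomSpec(
        shape=shape,
        pixel_spacing_row=sp_r,
        pixel_spacing_col=sp_c,
        slice_thickness_T=T,
        slice_gap_G=G,
        tumor=shapes[0],
        nodes=nodes,
        patient_id=pid,
    )


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Design of a simulated three-subtype survival cohort.

    Baseline hazard is exponential with ``baseline_median_days`` (default
    about five years) unless ``weibull_shape`` is given, in which case
    event times are Weibull with that shape and the scale implied by the
    median.  ``hr_mrs``/``hr_hrs`` multiply the hazard for the moderate-
    and high-risk subtypes relative to low-risk.  ``censoring_rate`` is
    the target marginal fraction censored before the administrative
    horizon, realized by an independent exponential censoring process.
    """

    n_per_subtype: int = 100
    baseline_median_days: float = FIVE_YEARS_DAYS
    weibull_shape: float | None = None
    hr_mrs: float = 1.0
    hr_hrs: float = 1.0
    censoring_rate: float = 0.0
    horizon_days: float = DEFAULT_HORIZON_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subtype < 1:
            raise ValueError("n_per_subtype must be >= 1")
        if self.baseline_median_days <= 0:
            raise ValueError("baseline_median_days must be > 0")
        if self.hr_mrs <= 0 or self.hr_hrs <= 0:
            raise ValueError("hazard ratios must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")


def _draw_event_times(
    rng: np.random.Generator,
    n: int,
    hazard_multiplier: np.ndarray,
    median_days: float,
    weibull_shape: float | None,
) -> np.ndarray:
    """Event times with S(t) = exp(-H0(t) * m) for subject multiplier m."""
    u = rng.exponential(1.0, size=n)  # unit-rate exponentials
    if weibull_shape is None:
        lam = math.log(2.0) / median_days
        return u / (lam * hazard_multiplier)
    scale = median_days / math.log(2.0) ** (1.0 / weibull_shape)
    return scale * (u / hazard_multiplier) ** (1.0 / weibull_shape)


def _censoring_times(
    rng: np.random.Generator,
    n: int,
    censoring_rate: float,
    median_days: float,
    horizon_days: float,
) -> np.ndarray:
    """Independent censoring: optional exponential early loss + admin horizon.

    The exponential rate lam_c = lam_e * r / (1 - r) gives a marginal
    pre-horizon censoring fraction of about r against an exponential
    baseline with rate lam_e; r = 1 censors everyone immediately.
    """
    admin = np.full(n, horizon_days)
    if censoring_rate <= 0.0:
        return admin
    if censoring_rate >= 1.0:
        return np.zeros(n)
    lam_e = math.log(2.0) / median_days
    lam_c = lam_e * censoring_rate / (1.0 - censoring_rate)
    return np.minimum(admin, rng.exponential(1.0 / lam_c, size=n))


SUBTYPE_ORDER = ("LRS", "MRS", "HRS")


def simulate_cohort(spec: CohortSimSpec) -> tuple[list[CohortRecord], np.ndarray]:
    """Simulate a cohort with planted subtype hazards.

    Returns the cohort records (OS and DFS share the simulated endpoint)
    and the true subtype label per record.
    """
    rng = np.random.default_rng(spec.seed)
    n = 3 * spec.n_per_subtype
    subtype = np.repeat(SUBTYPE_ORDER, spec.n_per_subtype)
    multiplier = np.select(
        [subtype == "LRS", subtype == "MRS", subtype == "HRS"],
        [1.0, spec.hr_mrs, spec.hr_hrs],
    )
    t_event = _draw_event_times(
        rng, n, multiplier, spec.baseline_median_days, spec.weibull_shape
    )
    t_censor = _censoring_times(
        rng, n, spec.censoring_rate, spec.baseline_median_days, spec.horizon_days
    )
    observed = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    records = [
        CohortRecord(
            patient_id=f"sim-{i:05d}",
            os_time=float(observed[i]),
            os_event=int(event[i]),
            dfs_time=float(observed[i]),
            dfs_event=int(event[i]),
            covariates={"true_subtype": subtype[i]},
        )
        for i in range(n)
    ]
    return records, subtype


def survival_from_features(
    features: pd.DataFrame,
    cutpoints: dict[str, float],
    hazard_ratios: dict[str, float],
    seed: int,
    baseline_median_days: float = FIVE_YEARS_DAYS,
    censoring_rate: float = 0.0,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> pd.DataFrame:
    """Plant survival on an existing feature table.

    A subject's hazard is the baseline times the product of
    ``hazard_ratios[f]`` over features at or above ``cutpoints[f]`` (the
    favorable side is inclusive, matching downstream dichotomization).
    Returns a copy of ``features`` with ``os_time``/``os_event`` appended.
    """
    if set(hazard_ratios) - set(cutpoints):
        raise ValueError("hazard_ratios keys must be a subset of cutpoints")
    rng = np.random.default_rng(seed)
    df = features.copy()
    n = len(df)
    multiplier = np.ones(n)
    for name, cut in cutpoints.items():
        above = df[name].to_numpy(float) >= cut
        multiplier *= np.where(above, hazard_ratios.get(name, 1.0), 1.0)
    t_event = _draw_event_times(rng, n, multiplier, baseline_median_days, None)
    t_censor = _censoring_times(rng, n, censoring_rate, baseline_median_days, horizon_days)
    df["os_time"] = np.minimum(t_event, t_censor)
    df["os_event"] = (t_event <= t_censor).astype(int)
    return df


def simulate_feature_cohort(
    n: int,
    cutpoints: dict[str, float],
    hazard_ratios: dict[str, float],
    seed: int,
    baseline_median_days: float = FIVE_YEARS_DAYS,
    censoring_rate: float = 0.0,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> pd.DataFrame:
    """Simulate continuous features with survival driven by planted cutpoints.

    Each feature ``f`` is drawn Uniform(0, 2 * cutpoints[f]) so the planted
    threshold sits mid-range; a subject's hazard is the baseline times the
    product of ``hazard_ratios[f]`` over the features for which the subject
    lies at or above the cutpoint (the favorable side is inclusive,
    matching the downstream dichotomization).

    Returns a patient table with the feature columns, ``os_time``,
    ``os_event`` and a ``true_high_<f>`` indicator per feature.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if set(hazard_ratios) - set(cutpoints):
        raise ValueError("hazard_ratios keys must be a subset of cutpoints")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"patient_id": [f"fc-{i:05d}" for i in range(n)]})
    multiplier = np.ones(n)
    for name, cut in cutpoints.items():
        values = rng.uniform(0.0, 2.0 * cut, size=n)
        above = values >= cut
        df[name] = values
        df[f"true_high_{name}"] = above.astype(int)
        multiplier *= np.where(above, hazard_ratios.get(name, 1.0), 1.0)
    t_event = _draw_event_times(rng, n, multiplier, baseline_median_days, None)
    t_censor = _censoring_times(rng, n, censoring_rate, baseline_median_days, horizon_days)
    df["os_time"] = np.minimum(t_event, t_censor)
    df["os_event"] = (t_event <= t_censor).astype(int)
    return df
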