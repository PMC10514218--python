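"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
CN/MCI cohort aged roughly 60-90 with a roughly normal age distribution,
~24% amyloid-positive CN and ~46% amyloid-positive MCI, a nonlinear
(quadratic) age-related decline of gray matter, a subtle amyloid-related
GM reduction in CN, and focal MCI atrophy concentrated in the medial
temporal and temporal ROIs. Volumes live on a small block-parcellated
grid; nothing here is anatomically realistic — the point is that every
downstream stage (reference construction, Z/W maps, extents, ROC) can be
exercised and validated without clinical data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .volumes import GMVolume, ROIAtlas, ROI_NAMES, write_atlas, write_volume

#: florbetapir SUVR above which a subject is labeled amyloid-positive
SUVR_CUTOFF = 1.11


@dataclass
class SubjectRecord:
    """Demographics and labels driving reference selection and evaluation."""

    id: str
    age: float
    sex: str  # "M" | "F"
    group: str  # "CN" | "MCI"
    amyloid_suvr: float

    @property
    def amyloid_positive(self) -> bool:
        return self.amyloid_suvr > SUVR_CUTOFF


@dataclass
class TrajectoryParams:
    """Quadratic age trajectory g(age) = g0*(1 - r1*(age-a_ref) - r2*(age-a_ref)^2).

    ``g0`` is the GM concentration at the reference age; ``r1`` and ``r2``
    are the linear and quadratic fractional decline rates per year. The
    quadratic term makes decline accelerate with age, which is what breaks
    a single all-ages reference group.
    """

    g0: float = 0.8
    r1: float = 0.004
    r2: float = 0.0004
    a_ref: float = 70.0


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the study scale this pipeline targets: 141 CN aged
    73.45 +/- 5.75 y (24% amyloid-positive) and 91 MCI aged 70.84 +/- 7.50 y
    (46% amyloid-positive), ages truncated to [60, 90]. The MCI effect is
    focal (15% GM reduction in MTL, 10% in temporal GM); the amyloid effect
    in CN is a uniform 2% reduction. Noise: lognormal between-subject scale
    (sigma ``subject_sd``) plus additive Gaussian voxel noise.
    """

    n_cn: int = 141
    n_mci: int = 91
    cn_age_mean: float = 73.45
    cn_age_sd: float = 5.75
    mci_age_mean: float = 70.84
    mci_age_sd: float = 7.50
    age_min: float = 60.0
    age_max: float = 90.0
    p_amyloid_pos_cn: float = 0.24
    p_amyloid_pos_mci: float = 0.46
    trajectory: dict[str, TrajectoryParams] = field(
        default_factory=lambda: {roi: TrajectoryParams() for roi in ROI_NAMES}
    )
    amyloid_effect: dict[str, float] = field(
        default_factory=lambda: {roi: 0.02 for roi in ROI_NAMES}
    )
    mci_effect: dict[str, float] = field(
        default_factory=lambda: {"MTL": 0.15, "temporal": 0.10}
    )
    subject_sd: float = 0.05
    voxel_sd: float = 0.05
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cn < 1 or self.n_mci < 0:
            raise ParameterError("need n_cn >= 1 and n_mci >= 0")
        for p in (self.p_amyloid_pos_cn, self.p_amyloid_pos_mci):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability out of [0,1]: {p}")
        for d in (self.amyloid_effect, self.mci_effect):
            for roi, e in d.items():
                if not 0.0 <= e < 1.0:
                    raise ParameterError(f"effect for {roi} out of [0,1): {e}")
        if self.subject_sd < 0 or self.voxel_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if not self.age_min < self.age_max:
            raise ParameterError("need age_min < age_max")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trajectory"] = {k: asdict(v) for k, v in self.trajectory.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "trajectory" in d:
            d["trajectory"] = {
                k: v if isinstance(v, TrajectoryParams) else TrajectoryParams(**v)
                for k, v in d["trajectory"].items()
            }
        for key in ("grid_shape", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    records: list[SubjectRecord]
    volumes: dict[str, GMVolume]
    atlas: ROIAtlas
    spec: CohortSpec

    def table(self) -> pd.DataFrame:
        rows = [
            dict(
                id=r.id, age=r.age, sex=r.sex, group=r.group,
                amyloid_suvr=r.amyloid_suvr, amyloid_positive=r.amyloid_positive,
            )
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        """Write cohort CSV, atlas (+label TSV) and one NIfTI per subject."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(out / "cohort.csv", index=False)
        write_atlas(self.atlas, out / "atlas.nii.gz")
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for sid, vol in self.volumes.items():
            write_volume(vol, vol_dir / f"{sid}.nii.gz")


def generate_atlas(
    grid_shape=(24, 24, 24), voxel_size=(2.0, 2.0, 2.0)
) -> ROIAtlas:
    """Deterministic block-layout atlas with the six stand-in ROIs.

    The interior of the grid (2-voxel background margin on each face) is
    split into six equal slabs along the last axis, one per ROI. Blocks are
    stand-ins, not anatomy; they give each ROI a contiguous, disjoint
    voxel set of useful size.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 16:
        raise ParameterError(
            f"grid must be 3-D with every axis >= 16 to host 6 ROI blocks, got {grid_shape}"
        )
    labels = np.zeros(grid_shape, dtype=np.int32)
    margin = 2
    lo = [margin] * 3
    hi = [n - margin for n in grid_shape]
    depth = hi[2] - lo[2]
    edges = [lo[2] + (depth * i) // 6 for i in range(7)]
    for i in range(6):
        labels[lo[0]:hi[0], lo[1]:hi[1], edges[i]:edges[i + 1]] = i + 1
    table = {i + 1: name for i, name in enumerate(ROI_NAMES)}
    return ROIAtlas(labels, table, voxel_size)


def aging_trajectory(age: float, params: TrajectoryParams) -> float:
    """GM level at a given age under the quadratic decline model, clipped at 0."""
    d = age - params.a_ref
    return float(max(0.0, params.g0 * (1.0 - params.r1 * d - params.r2 * d * d)))


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # Stable per-subject stream: cohorts are extensible without reshuffling.
    digest = hashlib.sha256(subject_id.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def generate_subject_volume(
    record: SubjectRecord,
    atlas: ROIAtlas,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> GMVolume:
    """Draw one subject's GM volume from the generative model.

    Voxel value inside ROI r:
        g_r(age) * (1 - amyloid_effect_r * [A+]) * (1 - mci_effect_r * [MCI])
        * subject_scale + N(0, voxel_sd), truncated at 0.
    Background voxels are exactly 0.
    """
    if not spec.age_min <= record.age <= spec.age_max:
        raise ParameterError(
            f"age {record.age} outside spec range [{spec.age_min}, {spec.age_max}]"
        )
    if rng is None:
        rng = _subject_rng(spec.seed, record.id)
    subject_scale = float(np.exp(rng.normal(0.0, spec.subject_sd))) if spec.subject_sd > 0 else 1.0
    data = np.zeros(atlas.labels.shape, dtype=np.float64)
    for label, roi in atlas.label_table.items():
        level = aging_trajectory(record.age, spec.trajectory[roi])
        if record.amyloid_positive:
            level *= 1.0 - spec.amyloid_effect.get(roi, 0.0)
        if record.group == "MCI":
            level *= 1.0 - spec.mci_effect.get(roi, 0.0)
        data[atlas.labels == label] = level * subject_scale
    if spec.voxel_sd > 0:
        inside = atlas.labels > 0
        data[inside] += rng.normal(0.0, spec.voxel_sd, size=int(inside.sum()))
    np.clip(data, 0.0, None, out=data)
    return GMVolume(data, spec.voxel_size)


def _draw_ages(rng, n, mean, sd, lo, hi) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    ages = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.round(ages, 1)  # ages recorded to 0.1 y


def _draw_suvr(rng, positive: np.ndarray) -> np.ndarray:
    # SUVR consistent with the 1.11 positivity cut-off by construction.
    n = positive.size
    neg = SUVR_CUTOFF - 0.01 - np.abs(rng.normal(0.0, 0.10, size=n))
    pos = SUVR_CUTOFF + 0.01 + np.abs(rng.normal(0.0, 0.15, size=n))
    return np.round(np.where(positive, pos, neg), 3)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate records, atlas and volumes; exactly reproducible per seed."""
    atlas = generate_atlas(spec.grid_shape, spec.voxel_size)
    demo_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    records: list[SubjectRecord] = []
    for group, n, mean, sd, p_pos in (
        ("CN", spec.n_cn, spec.cn_age_mean, spec.cn_age_sd, spec.p_amyloid_pos_cn),
        ("MCI", spec.n_mci, spec.mci_age_mean, spec.mci_age_sd, spec.p_amyloid_pos_mci),
    ):
        ages = _draw_ages(demo_rng, n, mean, sd, spec.age_min, spec.age_max)
        sexes = np.where(demo_rng.random(n) < 0.5, "M", "F")
        positive = demo_rng.random(n) < p_pos
        suvr = _draw_suvr(demo_rng, positive)
        for i in range(n):
            records.append(
                SubjectRecord(
                    id=f"{group}{i + 1:04d}",
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    group=group,
                    amyloid_suvr=float(suvr[i]),
                )
            )
    volumes = {
        r.id: generate_subject_volume(r, atlas, spec, _subject_rng(spec.seed, r.id))
        for r in records
    }
    return SyntheticCohort(records, volumes, atlas, spec)


def load_cohort_table(path) -> list[SubjectRecord]:
    """Read a cohort CSV (id, age, sex, group, amyloid_suvr[, amyloid_positive])."""
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "group", "amyloid_suvr"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    return [
        SubjectRecord(
            id=str(row.id), age=float(row.age), sex=str(row.sex),
            group=str(row.group), amyloid_suvr=float(row.amyloid_suvr),
        )
        for row in df.itertuples()
    ]
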