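"""Normative reference models.

Three reference-group strategies are supported for the voxel-wise
Z-statistic:

* ``standard`` — one mean/SD map from all eligible CN, regardless of age;
* ``bracket`` — per-subject mean/SD maps from the k CN nearest in age
  within a fixed half-width window (half-width 5 y for "10-year brackets",
  2.5 y for "5-year brackets"); subjects at the age extremes may have too
  few eligible CN and are skipped by callers;

plus a regression-based W-score model that fits a per-voxel ordinary
least-squares line of GM on age in CN and standardizes by the residual SD.

Each strategy can be restricted to amyloid-negative CN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import SubjectRecord
from .errors import CoverageError, ParameterError
from .volumes import GMVolume, assert_same_grid, read_volume, write_volume


@dataclass
class ReferenceModel:
    """Voxel-wise mean and sample SD maps plus provenance."""

    mean_map: GMVolume
    sd_map: GMVolume
    member_ids: list[str]
    ref_type: str  # "standard" | "bracket"
    age_center: float | None = None
    half_width: float | None = None
    amyloid_filter: str = "all"  # "all" | "negative_only"

    @property
    def k(self) -> int:
        return len(self.member_ids)

    def describe(self) -> str:
        if self.ref_type == "bracket":
            return (
                f"bracket(k={self.k}, center={self.age_center:g}, "
                f"hw={self.half_width:g}, {self.amyloid_filter})"
            )
        return f"standard(k={self.k}, {self.amyloid_filter})"

    def save(self, out_dir, name: str = "reference") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.mean_map, out / f"{name}_mean.nii.gz")
        write_volume(self.sd_map, out / f"{name}_sd.nii.gz")
        meta = dict(
            member_ids=self.member_ids, ref_type=self.ref_type,
            age_center=self.age_center, half_width=self.half_width,
            k=self.k, amyloid_filter=self.amyloid_filter,
        )
        (out / f"{name}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir, name: str = "reference") -> "ReferenceModel":
        out = Path(out_dir)
        meta = json.loads((out / f"{name}.json").read_text())
        return cls(
            mean_map=read_volume(out / f"{name}_mean.nii.gz"),
            sd_map=read_volume(out / f"{name}_sd.nii.gz"),
            member_ids=list(meta["member_ids"]),
            ref_type=meta["ref_type"],
            age_center=meta["age_center"],
            half_width=meta["half_width"],
            amyloid_filter=meta["amyloid_filter"],
        )


@dataclass
class WScoreModel:
    """Per-voxel OLS of GM on age in CN: intercept, slope, residual SD maps."""

    intercept_map: GMVolume
    slope_map: GMVolume
    resid_sd_map: GMVolume
    member_ids: list[str]
    mean_age: float

    @property
    def k(self) -> int:
        return len(self.member_ids)

    def predict(self, age: float) -> np.ndarray:
        return self.intercept_map.data + self.slope_map.data * age

    def save(self, out_dir, name: str = "wscore") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.intercept_map, out / f"{name}_intercept.nii.gz")
        write_volume(self.slope_map, out / f"{name}_slope.nii.gz")
        write_volume(self.resid_sd_map, out / f"{name}_resid_sd.nii.gz")
        meta = dict(member_ids=self.member_ids, mean_age=self.mean_age)
        (out / f"{name}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir, name: str = "wscore") -> "WScoreModel":
        out = Path(out_dir)
        meta = json.loads((out / f"{name}.json").read_text())
        return cls(
            intercept_map=read_volume(out / f"{name}_intercept.nii.gz"),
            slope_map=read_volume(out / f"{name}_slope.nii.gz"),
            resid_sd_map=read_volume(out / f"{name}_resid_sd.nii.gz"),
            member_ids=list(meta["member_ids"]),
            mean_age=float(meta["mean_age"]),
        )


def eligible_cn(
    records: list[SubjectRecord],
    amyloid_filter: str = "all",
    exclude_id: str | None = None,
) -> list[SubjectRecord]:
    """CN records after the optional amyloid-negative filter and self-exclusion."""
    if amyloid_filter not in ("all", "negative_only"):
        raise ParameterError(f"unknown amyloid_filter {amyloid_filter!r}")
    out = [r for r in records if r.group == "CN" and r.id != exclude_id]
    if amyloid_filter == "negative_only":
        out = [r for r in out if not r.amyloid_positive]
    return out


def select_bracket_members(
    cn_records: list[SubjectRecord],
    target_age: float,
    half_width: float,
    k: int = 20,
    exclude_id: str | None = None,
) -> list[str]:
    """Ids of the k CN nearest in age within the strict |age - target| < half_width window.

    Ties in age distance break by ascending id, making selection fully
    deterministic. Raises :class:`CoverageError` when fewer than k CN are
    eligible — the caller skips that subject, mirroring the loss of
    coverage at the extremes of a normally distributed age range.
    """
    if k < 2:
        raise ParameterError(f"need k >= 2, got {k}")
    if half_width <= 0:
        raise ParameterError(f"need half_width > 0, got {half_width}")
    window = [
        r for r in cn_records
        if r.id != exclude_id and abs(r.age - target_age) < half_width
    ]
    if len(window) < k:
        raise CoverageError(target_age, len(window), k)
    window.sort(key=lambda r: (abs(r.age - target_age), r.id))
    return [r.id for r in window[:k]]


def build_reference(
    volumes: list[GMVolume],
    member_ids: list[str],
    ref_type: str = "standard",
    age_center: float | None = None,
    half_width: float | None = None,
    amyloid_filter: str = "all",
) -> ReferenceModel:
    """Voxel-wise arithmetic mean and sample SD (denominator n-1) over members."""
    if len(volumes) < 2:
        raise ParameterError(f"need >= 2 member volumes, got {len(volumes)}")
    if len(volumes) != len(member_ids):
        raise ParameterError("one member id per volume required")
    first = volumes[0]
    for v in volumes[1:]:
        assert_same_grid(first, v)
    stack = np.stack([v.data for v in volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return ReferenceModel(
        mean_map=first.like(mean),
        sd_map=first.like(sd),
        member_ids=list(member_ids),
        ref_type=ref_type,
        age_center=age_center,
        half_width=half_width,
        amyloid_filter=amyloid_filter,
    )


def build_standard_reference(
    records: list[SubjectRecord],
    volumes: dict[str, GMVolume],
    amyloid_filter: str = "all",
    exclude_id: str | None = None,
) -> ReferenceModel:
    """Reference over all eligible CN (one mean/SD map for every subject)."""
    members = eligible_cn(records, amyloid_filter, exclude_id)
    ids = sorted(r.id for r in members)
    return build_reference(
        [volumes[i] for i in ids], ids,
        ref_type="standard", amyloid_filter=amyloid_filter,
    )


def build_bracket_reference(
    records: list[SubjectRecord],
    volumes: dict[str, GMVolume],
    target_age: float,
    half_width: float,
    k: int = 20,
    amyloid_filter: str = "all",
    exclude_id: str | None = None,
) -> ReferenceModel:
    """Age-bracket reference for one target age (nearest-k within window)."""
    pool = eligible_cn(records, amyloid_filter)
    ids = select_bracket_members(pool, target_age, half_width, k, exclude_id)
    return build_reference(
        [volumes[i] for i in ids], ids,
        ref_type="bracket", age_center=target_age,
        half_width=half_width, amyloid_filter=amyloid_filter,
    )


def coverage_ages(
    cn_records: list[SubjectRecord],
    half_width: float,
    k: int = 20,
) -> tuple[int, int] | None:
    """Maximal contiguous integer-age range where bracket selection succeeds.

    Scans whole years over the CN age range padded by the half-width on
    each side (a target age slightly outside the observed CN ages can
    still have k CN within its window); returns (min_age, max_age) of the
    widest contiguous covered run, or None when no integer age is covered.
    """
    if not cn_records:
        return None
    lo = int(np.floor(min(r.age for r in cn_records) - half_width))
    hi = int(np.ceil(max(r.age for r in cn_records) + half_width))
    covered = []
    for age in range(lo, hi + 1):
        try:
            select_bracket_members(cn_records, float(age), half_width, k)
        except CoverageError:
            covered.append(False)
        else:
            covered.append(True)
    best: tuple[int, int] | None = None
    start = None
    for i, ok in enumerate(covered + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            run = (lo + start, lo + i - 1)
            if best is None or run[1] - run[0] > best[1] - best[0]:
                best = run
            start = None
    return best


def fit_wscore_model(
    cn_volumes: list[GMVolume],
    cn_ages: list[float],
    member_ids: list[str] | None = None,
) -> WScoreModel:
    """Per-voxel OLS of GM concentration on age over CN subjects.

    Residual SD uses denominator n-2 (two fitted parameters). Raises on
    degenerate age spread, where the slope is unidentifiable.
    """
    n = len(cn_volumes)
    if n < 3:
        raise ParameterError(f"need >= 3 CN to fit a W-score model, got {n}")
    if len(cn_ages) != n:
        raise ParameterError("one age per volume required")
    ages = np.asarray(cn_ages, dtype=np.float64)
    if np.ptp(ages) == 0:
        raise ParameterError("constant ages: W-score regression is rank-deficient")
    first = cn_volumes[0]
    for v in cn_volumes[1:]:
        assert_same_grid(first, v)
    Y = np.stack([v.data for v in cn_volumes]).reshape(n, -1)
    a_mean = ages.mean()
    ac = ages - a_mean
    sxx = float(ac @ ac)
    slope = (ac @ (Y - Y.mean(axis=0))) / sxx
    intercept = Y.mean(axis=0) - slope * a_mean
    resid = Y - (intercept + np.outer(ages, slope))
    resid_sd = np.sqrt((resid ** 2).sum(axis=0) / (n - 2))
    shape = first.data.shape
    if member_ids is None:
        member_ids = [f"CN{i}" for i in range(n)]
    return WScoreModel(
        intercept_map=first.like(intercept.reshape(shape)),
        slope_map=first.like(slope.reshape(shape)),
        resid_sd_map=first.like(resid_sd.reshape(shape)),
        member_ids=list(member_ids),
        mean_age=float(a_mean),
    )
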