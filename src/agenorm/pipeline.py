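"""End-to-end orchestration over the factorial grid.

A run scores every subject under each configured reference strategy
(standard, 10-year bracket, 5-year bracket, optionally the W-score
regression model), for each smoothing kernel, Z-threshold and ROI, then
evaluates CN-vs-MCI discrimination per grid cell (ROC/AUC with Youden
cut-offs), compares strategies with paired DeLong tests on the subject
intersection, and tabulates Wilcoxon group differences with the
Bonferroni interpretation alongside.

References are rebuilt from smoothed member volumes for every kernel:
each kernel is a separate analysis condition, and smoothing is applied to
GM maps before standardization, never to Z-maps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, SubjectRecord, SyntheticCohort, generate_cohort
from .errors import CoverageError, ParameterError
from .references import (
    build_bracket_reference,
    build_standard_reference,
    eligible_cn,
    fit_wscore_model,
)
from .stats import bonferroni_alpha, delong_test, roc_auc, wilcoxon_rank_sum
from .volumes import (
    GMVolume,
    ROIAtlas,
    gaussian_smooth,
    make_brain_mask,
)
from .zmaps import DEFAULT_SD_FLOOR, compute_wmap, compute_zmap, extent_row, extent_table

#: bracket strategies and their age-window half-widths in years
HALF_WIDTHS = {"bracket_10y": 5.0, "bracket_5y": 2.5}

KNOWN_STRATEGIES = ("standard", "bracket_10y", "bracket_5y", "wscore")

#: per-comparison significance level and its family-wise interpretation
RAW_ALPHA = 0.0001


@dataclass
class RunConfig:
    """Configuration of one factorial run."""

    reference_types: tuple[str, ...] = ("standard", "bracket_10y", "bracket_5y")
    amyloid_filter: str = "all"  # "all" | "negative_only"
    k: int = 20
    thresholds: tuple[float, ...] = (-2.5, -3.5, -4.5)
    kernels_mm: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    rois: tuple[str, ...] | None = None  # None = all atlas ROIs + "total"
    exclude_self: bool = False
    sd_floor: float = DEFAULT_SD_FLOOR
    epsilon: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.reference_types:
            raise ParameterError("at least one reference type required")
        unknown = set(self.reference_types) - set(KNOWN_STRATEGIES)
        if unknown:
            raise ParameterError(f"unknown reference types: {sorted(unknown)}")
        if not self.thresholds or not self.kernels_mm:
            raise ParameterError("at least one threshold and one kernel required")
        if any(t >= 0 for t in self.thresholds):
            raise ParameterError("Z thresholds must be negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    extents: pd.DataFrame
    auc_grid: pd.DataFrame
    group_tests: pd.DataFrame
    comparisons: pd.DataFrame
    skips: list[dict]
    config: RunConfig
    version: str = __version__

    def save(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("extents", self.extents), ("auc_grid", self.auc_grid),
            ("group_tests", self.group_tests), ("comparisons", self.comparisons),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        skip_path = out / "skips.jsonl"
        skip_path.write_text("".join(json.dumps(s) + "\n" for s in self.skips))
        paths["skips"] = str(skip_path)
        snap = dict(config=self.config.to_dict(), version=self.version)
        cfg_path = out / "config.json"
        cfg_path.write_text(json.dumps(snap, indent=2, default=str))
        paths["config"] = str(cfg_path)
        return paths


def _zmaps_for_strategy(
    strategy: str,
    records: list[SubjectRecord],
    volumes: dict[str, GMVolume],
    config: RunConfig,
    mask,
):
    """Yield (record, ZMap | None, skip_info | None) for every subject."""
    if strategy == "standard":
        if not config.exclude_self:
            ref = build_standard_reference(records, volumes, config.amyloid_filter)
        for rec in records:
            if config.exclude_self:
                r = build_standard_reference(
                    records, volumes, config.amyloid_filter, exclude_id=rec.id
                )
            else:
                r = ref
            yield rec, compute_zmap(
                volumes[rec.id], r, config.sd_floor, mask, rec.id, config.epsilon
            ), None
    elif strategy in HALF_WIDTHS:
        hw = HALF_WIDTHS[strategy]
        for rec in records:
            exclude = rec.id if config.exclude_self else None
            try:
                ref = build_bracket_reference(
                    records, volumes, rec.age, hw, config.k,
                    config.amyloid_filter, exclude_id=exclude,
                )
            except CoverageError as err:
                yield rec, None, dict(
                    subject_id=rec.id, age=rec.age, group=rec.group,
                    reference_type=strategy, reason=str(err),
                )
                continue
            yield rec, compute_zmap(
                volumes[rec.id], ref, config.sd_floor, mask, rec.id, config.epsilon
            ), None
    elif strategy == "wscore":
        pool = eligible_cn(records, config.amyloid_filter)
        model = fit_wscore_model(
            [volumes[r.id] for r in pool], [r.age for r in pool],
            [r.id for r in pool],
        )
        for rec in records:
            if config.exclude_self and rec.group == "CN":
                sub = [r for r in pool if r.id != rec.id]
                m = fit_wscore_model(
                    [volumes[r.id] for r in sub], [r.age for r in sub],
                    [r.id for r in sub],
                )
            else:
                m = model
            yield rec, compute_wmap(
                volumes[rec.id], rec.age, m, config.sd_floor, mask, rec.id, config.epsilon
            ), None
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ParameterError(f"unknown strategy {strategy!r}")


def score_cohort(
    records: list[SubjectRecord],
    volumes: dict[str, GMVolume],
    atlas: ROIAtlas,
    config: RunConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Extent table over subjects x ROIs x thresholds x kernels x strategies.

    Subjects without bracket coverage at their age are skipped for that
    strategy and logged — skips are data, not failures.
    """
    rois = tuple(config.rois) if config.rois else tuple(atlas.roi_names) + ("total",)
    groups = {r.id: r.group for r in records}
    rows: list[dict] = []
    skips: list[dict] = []
    for fwhm in config.kernels_mm:
        if fwhm == 0:
            sm = volumes
        else:
            sm = {sid: gaussian_smooth(v, fwhm) for sid, v in volumes.items()}
        # one mask per kernel, shared by all strategies so extents compare
        pool = eligible_cn(records, config.amyloid_filter)
        mean = np.mean([sm[r.id].data for r in pool], axis=0)
        mask = make_brain_mask(sm[pool[0].id].like(mean), config.epsilon)
        for strategy in config.reference_types:
            for rec, zmap, skip in _zmaps_for_strategy(strategy, records, sm, config, mask):
                if skip is not None:
                    skips.append({**skip, "fwhm_mm": fwhm})
                    continue
                rows.extend(extent_row(
                    zmap, atlas, rois, config.thresholds, fwhm,
                    strategy, groups[rec.id],
                ))
    return extent_table(rows), skips


def _cells(df: pd.DataFrame):
    return df.groupby(["reference_type", "roi", "z_threshold", "fwhm_mm"], sort=True)


def evaluate_auc_grid(extents: pd.DataFrame) -> pd.DataFrame:
    """ROC per grid cell, plus a paired DeLong p against the standard strategy.

    The DeLong comparison is restricted to subjects scored under both the
    cell's strategy and the standard one (bracket coverage shrinks the
    sample; pairing demands the intersection).
    """
    std = extents[extents.reference_type == "standard"]
    rows = []
    for (ref_type, roi, thr, fwhm), cell in _cells(extents):
        labels = (cell.group == "MCI").astype(int).to_numpy()
        if labels.min() == labels.max():
            continue
        scores = cell.n_subthreshold.to_numpy(dtype=float)
        roc = roc_auc(scores, labels)
        p_vs_std = np.nan
        if ref_type != "standard" and len(std):
            base = std[(std.roi == roi) & (std.z_threshold == thr) & (std.fwhm_mm == fwhm)]
            merged = cell.merge(base, on="subject_id", suffixes=("_a", "_b"))
            if len(merged):
                lab = (merged.group_a == "MCI").astype(int).to_numpy()
                if lab.min() != lab.max():
                    res = delong_test(
                        merged.n_subthreshold_a.to_numpy(dtype=float),
                        merged.n_subthreshold_b.to_numpy(dtype=float),
                        lab,
                    )
                    p_vs_std = res.p
        rows.append(dict(
            reference_type=ref_type, roi=roi, z_threshold=thr, fwhm_mm=fwhm,
            auc=roc.auc, ci_low=roc.ci_low, ci_high=roc.ci_high,
            cutoff=roc.optimal_cutoff, sensitivity=roc.sensitivity,
            specificity=roc.specificity, n_used=roc.n_pos + roc.n_neg,
            delong_p_vs_standard=p_vs_std,
        ))
    return pd.DataFrame(rows)


def group_difference_table(extents: pd.DataFrame, m_comparisons: int | None = None) -> pd.DataFrame:
    """Wilcoxon rank-sum CN-vs-MCI per grid cell with Bonferroni framing.

    Significance uses the raw per-comparison alpha 0.0001; the implied
    family-wise alpha over the grid is reported alongside.
    """
    rows = []
    n_cells = _cells(extents).ngroups
    m = m_comparisons if m_comparisons is not None else max(n_cells, 1)
    fw_alpha = bonferroni_alpha(RAW_ALPHA, m)
    for (ref_type, roi, thr, fwhm), cell in _cells(extents):
        cn = cell.loc[cell.group == "CN", "n_subthreshold"].to_numpy(dtype=float)
        mci = cell.loc[cell.group == "MCI", "n_subthreshold"].to_numpy(dtype=float)
        if len(cn) == 0 or len(mci) == 0:
            continue
        u, p = wilcoxon_rank_sum(cn, mci)
        rows.append(dict(
            reference_type=ref_type, roi=roi, z_threshold=thr, fwhm_mm=fwhm,
            cn_mean=cn.mean(), cn_sd=cn.std(ddof=1) if len(cn) > 1 else 0.0,
            mci_mean=mci.mean(), mci_sd=mci.std(ddof=1) if len(mci) > 1 else 0.0,
            u=u, p=p, significant=p < RAW_ALPHA,
            raw_alpha=RAW_ALPHA, familywise_alpha=fw_alpha,
        ))
    return pd.DataFrame(rows)


def compare_reference_strategies(
    extents: pd.DataFrame,
    strategy_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired DeLong tests between reference strategies per grid cell.

    Each comparison is restricted to the intersection of subjects scored
    under both strategies. Cells with an empty intersection or one class
    missing are marked non-comparable.
    """
    strategies = sorted(extents.reference_type.unique())
    if strategy_pairs is None:
        strategy_pairs = [
            (a, b) for i, a in enumerate(strategies) for b in strategies[i + 1:]
        ]
    rows = []
    for a, b in strategy_pairs:
        da = extents[extents.reference_type == a]
        db = extents[extents.reference_type == b]
        for (roi, thr, fwhm), cell_a in da.groupby(["roi", "z_threshold", "fwhm_mm"]):
            cell_b = db[(db.roi == roi) & (db.z_threshold == thr) & (db.fwhm_mm == fwhm)]
            merged = cell_a.merge(cell_b, on="subject_id", suffixes=("_a", "_b"))
            base = dict(strategy_a=a, strategy_b=b, roi=roi,
                        z_threshold=thr, fwhm_mm=fwhm, n_used=len(merged))
            if len(merged) == 0:
                rows.append({**base, "auc_a": np.nan, "auc_b": np.nan,
                             "z": np.nan, "p": np.nan, "comparable": False})
                continue
            labels = (merged.group_a == "MCI").astype(int).to_numpy()
            if labels.min() == labels.max():
                rows.append({**base, "auc_a": np.nan, "auc_b": np.nan,
                             "z": np.nan, "p": np.nan, "comparable": False})
                continue
            res = delong_test(
                merged.n_subthreshold_a.to_numpy(dtype=float),
                merged.n_subthreshold_b.to_numpy(dtype=float),
                labels,
            )
            rows.append({**base, "auc_a": res.auc_a, "auc_b": res.auc_b,
                         "z": res.z, "p": res.p,
                         "comparable": not res.degenerate})
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
    cohort_spec: CohortSpec | None = None,
    records: list[SubjectRecord] | None = None,
    volumes: dict[str, GMVolume] | None = None,
    atlas: ROIAtlas | None = None,
    out_dir=None,
) -> RunReport:
    """Full run: score, evaluate, compare; optionally persist all artifacts.

    Input is either a :class:`SyntheticCohort`, a :class:`CohortSpec` to
    generate one (seeded, hence byte-reproducible), or explicit
    records/volumes/atlas loaded from files.
    """
    if cohort is None and cohort_spec is not None:
        cohort = generate_cohort(cohort_spec)
    if cohort is not None:
        records, volumes, atlas = cohort.records, cohort.volumes, cohort.atlas
    if records is None or volumes is None or atlas is None:
        raise ParameterError("provide a cohort, a cohort spec, or records+volumes+atlas")
    extents, skips = score_cohort(records, volumes, atlas, config)
    auc_grid = evaluate_auc_grid(extents)
    group_tests = group_difference_table(extents)
    comparisons = compare_reference_strategies(extents)
    report = RunReport(extents, auc_grid, group_tests, comparisons, skips, config)
    if out_dir is not None:
        report.save(out_dir)
    return report
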