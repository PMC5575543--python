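"""Evaluation harness, summary statistics, agreement limits and reports.

The harness runs methods x studies x metrics into a tidy result table,
summarises per-method performance (means over studies, spread across
methods), derives per-metric agreement limits, quantifies robustness
(per-lesion SD along an acquisition/reconstruction axis) and discriminative
power (spread across methods), runs the contour-perturbation specificity
analysis, and renders Local (single-study) and Global (whole-database)
structured reports in Markdown or HTML.

Conventions:

- Signed error metrics (volume and uptake errors) are summarised on their
  absolute values, and agreement-limit containment is tested on |value|.
- Standard deviations are sample SDs (ddof = 1).
- Metrics undefined for a contour (e.g. PPV of an empty mask) are recorded
  as missing with a reason and excluded from means; they are never silently
  zeroed, which would bias the agreement limits.
- Global summaries and agreement limits only include methods with the
  complete-run flag (evaluated on every study with every metric), which
  guards against cherry-picking favourable cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Study, StudyDatabase, VoiMask
from .metrics import METRICS, EmptyMaskError, compute_metric
from .perturbation import SPECIFICITY_LABELS

__all__ = [
    "evaluate",
    "complete_methods",
    "MethodSummary",
    "method_summary",
    "AgreementLimits",
    "agreement_limits",
    "agreement_limits_from_summary",
    "within_limits",
    "robustness",
    "discriminative_power",
    "SpecificityResult",
    "specificity_analysis",
    "local_report",
    "global_report",
]

RESULT_COLUMNS = ["study_id", "method_id", "metric", "level", "value",
                  "units", "missing_reason"]

#: metrics used in the contour-perturbation specificity analysis
SPECIFICITY_METRICS = ["volume_error", "mean_uptake_error", "dsc",
                       "sensitivity", "ppv", "hd_mod"]


def evaluate(db: StudyDatabase,
             contours: Mapping[str, Mapping[str, VoiMask]],
             metrics: Sequence[str] | str = "all") -> pd.DataFrame:
    """Score every supplied contour against its study's reference contour.

    ``contours`` maps study id -> method id -> mask. One row is produced
    per (study, method, metric); metrics that are undefined for a contour
    are recorded as missing with a reason.
    """
    names = list(METRICS) if metrics == "all" else list(metrics)
    for n in names:
        if n not in METRICS:
            raise KeyError(f"unknown metric {n!r}; known: {sorted(METRICS)}")
    rows = []
    for study in db:
        per_method = contours.get(study.study_id, {})
        rc = study.reference
        for method_id, mask in per_method.items():
            if not study.image.same_grid(mask):
                raise ValueError(
                    f"contour {method_id!r} does not share the grid of study "
                    f"{study.study_id!r}"
                )
            for name in names:
                info = METRICS[name]
                value, reason = np.nan, ""
                try:
                    value = compute_metric(name, rc, mask, image=study.image)
                except EmptyMaskError as exc:
                    reason = str(exc)
                rows.append((study.study_id, method_id, name, info.level,
                             value, info.units, reason))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    dup = table.duplicated(subset=["study_id", "method_id", "metric"])
    if dup.any():
        raise ValueError("duplicate (study, method, metric) keys in result table")
    return table


def complete_methods(table: pd.DataFrame) -> set[str]:
    """Methods with a row for every study x metric present in the table."""
    studies = table["study_id"].unique()
    metric_names = table["metric"].unique()
    full = len(studies) * len(metric_names)
    counts = table.groupby("method_id").size()
    return set(counts[counts == full].index)


@dataclass
class MethodSummary:
    """Per-method means +/- SD per metric, and cross-method spread."""

    per_method: pd.DataFrame  # MultiIndex columns (metric, {mean, sd, n})
    across: pd.DataFrame      # index metric: median, sd, range_min, range_max
    methods: list[str]
    n_missing: pd.DataFrame   # method x metric count of missing values


def _summarised_value(metric: str, values: pd.Series) -> pd.Series:
    return values.abs() if METRICS[metric].signed else values


def method_summary(table: pd.DataFrame,
                   require_complete: bool = True) -> MethodSummary:
    """Summarise a result table.

    Per-method means are taken over studies (absolute values for signed
    error metrics); the across-method median, sample SD and range are taken
    over the per-method means. With ``require_complete`` (default) only
    methods with the complete-run flag enter the summary.
    """
    if table.empty:
        raise ValueError("result table is empty")
    methods = sorted(table["method_id"].unique())
    if require_complete:
        keep = complete_methods(table)
        methods = [m for m in methods if m in keep]
        if not methods:
            raise ValueError("no method has a complete run over all studies "
                             "and metrics")
    sub = table[table["method_id"].isin(methods)]
    metric_names = [m for m in METRICS if m in set(sub["metric"])]

    per_rows, miss_rows = {}, {}
    for method in methods:
        mt = sub[sub["method_id"] == method]
        row, miss = {}, {}
        for metric in metric_names:
            vals = mt.loc[mt["metric"] == metric, "value"].dropna()
            vals = _summarised_value(metric, vals)
            n = len(vals)
            row[(metric, "mean")] = vals.mean() if n else np.nan
            row[(metric, "sd")] = vals.std(ddof=1) if n > 1 else np.nan
            row[(metric, "n")] = n
            miss[metric] = int(mt.loc[mt["metric"] == metric, "value"]
                               .isna().sum())
        per_rows[method] = row
        miss_rows[method] = miss
    per_method = pd.DataFrame.from_dict(per_rows, orient="index")
    per_method.columns = pd.MultiIndex.from_tuples(per_method.columns)
    n_missing = pd.DataFrame.from_dict(miss_rows, orient="index")

    across = {}
    for metric in metric_names:
        means = per_method[(metric, "mean")].dropna()
        across[metric] = {
            "median": means.median(),
            "sd": means.std(ddof=1) if len(means) > 1 else np.nan,
            "range_min": means.min(),
            "range_max": means.max(),
            "n_methods": len(means),
        }
    return MethodSummary(per_method, pd.DataFrame.from_dict(across, orient="index"),
                         methods, n_missing)


@dataclass
class AgreementLimits:
    """Per-metric interval a new method's mean is judged against.

    The raw interval is median +/- 1 SD across methods; the side whose
    direction corresponds to *better-than-typical* performance is then
    clamped to the metric's best achievable value (0 for error and distance
    metrics, 1 for the overlap metrics DSC/S/PPV).
    """

    metric: str
    lower: float
    upper: float
    median: float
    sd: float
    clamped_side: str = "none"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")


def agreement_limits(metric: str, median: float, sd: float) -> AgreementLimits:
    """Interval = median +/- 1 SD, clamped at the metric's best value."""
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    if not math.isfinite(sd):
        raise ValueError(f"SD undefined for metric {metric!r}")
    info = METRICS[metric]
    lower, upper = median - sd, median + sd
    if info.clamp_side == "lower":
        lower = info.clamp_value
    else:
        upper = info.clamp_value
    return AgreementLimits(metric, lower, upper, median, sd, info.clamp_side)


def agreement_limits_from_summary(summary: MethodSummary,
                                  ) -> dict[str, AgreementLimits]:
    out = {}
    for metric, row in summary.across.iterrows():
        if math.isfinite(row["sd"]):
            out[metric] = agreement_limits(metric, row["median"], row["sd"])
    return out


def within_limits(value: float, al: AgreementLimits) -> bool:
    """Boundary-inclusive containment; |value| for signed error metrics."""
    v = abs(value) if METRICS[al.metric].signed else value
    return al.lower <= v <= al.upper


_AXIS_FIELDS = {
    "acquisition_instance": "acquisition_instance",
    "reconstruction": "reconstruction_id",
    "voxel_sampling": "voxel_sampling_id",
    "geometry": "lesion",
}


def _lesion_id(study: Study) -> str:
    return f"{study.dataset}/{study.reference.label}"


def robustness(table: pd.DataFrame, db: StudyDatabase,
               axis: str) -> pd.DataFrame:
    """Per-method robustness along an axis.

    For each lesion, the SD of each metric across the studies that differ
    only along ``axis`` (e.g. acquisition instances) is computed; the mean
    of these SDs per (method, metric) is returned. Groups with a single
    study are flagged via the ``n_groups`` column and excluded.
    """
    if axis not in _AXIS_FIELDS:
        raise KeyError(
            f"unknown robustness axis {axis!r}; known: {sorted(_AXIS_FIELDS)}"
        )
    keys = {}
    for study in db:
        fields = {
            "lesion": _lesion_id(study),
            "acquisition_instance": study.acquisition_instance,
            "reconstruction_id": study.reconstruction_id,
            "voxel_sampling_id": study.voxel_sampling_id,
        }
        fields.pop(_AXIS_FIELDS[axis])
        keys[study.study_id] = tuple(sorted(fields.items()))
    t = table.dropna(subset=["value"]).copy()
    t["group"] = t["study_id"].map(keys)
    if t["group"].isna().any():
        raise KeyError(f"result table contains studies absent from the database")
    rows = []
    for (method, metric), grp in t.groupby(["method_id", "metric"]):
        sds = grp.groupby("group")["value"].agg(["std", "count"])
        usable = sds[sds["count"] > 1]
        if usable.empty:
            continue
        rows.append({"method_id": method, "metric": metric,
                     "mean_sd": usable["std"].mean(),
                     "n_groups": len(usable)})
    if not rows:
        raise ValueError(
            f"axis {axis!r} has a single study per lesion; robustness undefined"
        )
    return pd.DataFrame(rows)


def discriminative_power(summary: MethodSummary) -> pd.DataFrame:
    """Range and SD of per-method means per metric (+ SD as % of median)."""
    if len(summary.methods) < 2:
        raise ValueError("discriminative power needs >= 2 methods")
    df = summary.across.copy()
    df["sd_pct_of_median"] = 100.0 * df["sd"] / df["median"].abs()
    return df[["range_min", "range_max", "sd", "sd_pct_of_median"]]


@dataclass
class SpecificityResult:
    """Metric values and per-metric rankings of the perturbed contours."""

    values: pd.DataFrame  # index: contour label, columns: metrics
    ranks: pd.DataFrame   # rank 1 = closest to the reference


def _badness(metric: str, v: pd.Series) -> pd.Series:
    info = METRICS[metric]
    if info.signed:
        return v.abs()
    if info.best == 1.0:
        return 1.0 - v
    return v


def specificity_analysis(study: Study,
                         suite: Sequence[tuple[str, VoiMask]],
                         metrics: Sequence[str] = SPECIFICITY_METRICS,
                         ) -> SpecificityResult:
    """Score each perturbed contour against the study's reference contour.

    Signed errors keep their sign in ``values`` (the sign distinguishes
    over- from under-segmentation); rankings use the distance from the best
    achievable value.
    """
    rc = study.reference
    rows = {}
    for label, mask in suite:
        rows[label] = {m: compute_metric(m, rc, mask, image=study.image)
                       for m in metrics}
    values = pd.DataFrame.from_dict(rows, orient="index")
    ranks = pd.DataFrame({m: _badness(m, values[m]).rank(method="min")
                          for m in metrics}, index=values.index)
    return SpecificityResult(values, ranks)


# ------------------------------------------------------------------ reports

def _md_table(df: pd.DataFrame, float_fmt: str = "{:.4g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return "" if math.isnan(v) else float_fmt.format(v)
        return str(v)

    header = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row]) + " |")
    return "\n".join(lines)


def _render_table(df: pd.DataFrame, fmt: str) -> str:
    if fmt == "html":
        return df.to_html(float_format=lambda v: f"{v:.4g}", na_rep="")
    return _md_table(df)


def _pivot(table: pd.DataFrame, level: str,
           study_id: str | None = None) -> pd.DataFrame:
    t = table if study_id is None else table[table["study_id"] == study_id]
    t = t[t["level"] == level]
    return t.pivot_table(index="method_id", columns="metric", values="value",
                         aggfunc="mean", dropna=False)


def _metric_plot(df: pd.DataFrame, metric: str, path: Path) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(4, 3))
    ax = fig.subplots()
    vals = df[metric].dropna()
    ax.bar(vals.index.astype(str), vals.values, color="#4878a8")
    ax.set_ylabel(f"{metric} ({METRICS[metric].units})")
    ax.set_title(metric)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=100)


def _section(title: str, body: str, fmt: str, depth: int = 2) -> str:
    if fmt == "html":
        return f"<h{depth}>{title}</h{depth}>\n{body}\n"
    return f"\n{'#' * depth} {title}\n\n{body}\n"


def _report_core(table: pd.DataFrame, fmt: str, title: str,
                 details: list[str], study_id: str | None,
                 out_dir: Path | None) -> list[str]:
    parts = []
    if fmt == "html":
        parts.append(f"<html><head><title>{title}</title></head><body>"
                     f"<h1>{title}</h1>")
    else:
        parts.append(f"# {title}\n")
    body = ("<ul>" + "".join(f"<li>{d}</li>" for d in details) + "</ul>"
            if fmt == "html" else "\n".join(f"- {d}" for d in details))
    parts.append(_section("Analysis details", body, fmt))
    for level, name in (("I", "Level I analysis"), ("II", "Level II analysis")):
        piv = _pivot(table, level, study_id)
        chunk = _render_table(piv, fmt)
        if out_dir is not None:
            imgs = []
            for metric in piv.columns:
                fname = f"{'all' if study_id is None else study_id}_{metric}.png"
                _metric_plot(piv, metric, out_dir / fname)
                imgs.append(f'<img src="{fname}" alt="{metric}">'
                            if fmt == "html" else f"![{metric}]({fname})")
            chunk += "\n" + "\n".join(imgs)
        parts.append(_section(name, chunk, fmt))
    return parts


def local_report(study: Study, table: pd.DataFrame, fmt: str = "html",
                 out_dir: str | Path | None = None) -> str:
    """Single-study structured report: analysis details + per-level tables/plots.

    ``fmt`` is "html" or "md"; "pdf" is produced as print-ready HTML.
    Output is a deterministic function of the inputs (no timestamps).
    """
    fmt = "html" if fmt in {"html", "pdf", "doc"} else "md"
    t = table[table["study_id"] == study.study_id]
    if t.empty:
        raise ValueError(f"result table has no rows for study {study.study_id!r}")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    details = [
        f"Image: {study.study_id} (dataset {study.dataset}, site {study.site})",
        "Contours: " + ", ".join(sorted(t["method_id"].unique())),
        "Metrics: " + ", ".join(t["metric"].unique()),
    ]
    parts = _report_core(t, fmt, f"Local report — {study.study_id}",
                         details, study.study_id, out_dir)
    if fmt == "html":
        parts.append("</body></html>")
    doc = "\n".join(parts)
    if out_dir is not None:
        (out_dir / f"local_{study.study_id}.{fmt}").write_text(doc)
    return doc


def global_report(db: StudyDatabase, table: pd.DataFrame, fmt: str = "html",
                  out_dir: str | Path | None = None) -> str:
    """Whole-database report: local sections plus cross-case summaries.

    Adds (a) mean +/- SD of each metric per method across all cases,
    (b) per-dataset mean metric values, and (c) means grouped by data type
    (clinical vs nonclinical) and tumor site.
    """
    fmt = "html" if fmt in {"html", "pdf", "doc"} else "md"
    if table.empty:
        raise ValueError("result table is empty")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    details = [
        f"Studies: {len(db)} across datasets " +
        ", ".join(sorted(db.by_dataset())),
        "Contours: " + ", ".join(sorted(table["method_id"].unique())),
        "Metrics: " + ", ".join(table["metric"].unique()),
    ]
    parts = _report_core(table, fmt, "Global report", details, None, out_dir)

    summary = method_summary(table, require_complete=True)
    mean_sd = pd.DataFrame({
        metric: summary.per_method[(metric, "mean")].map(lambda v: f"{v:.4g}")
        + " ± " + summary.per_method[(metric, "sd")].map(
            lambda v: "n/a" if math.isnan(v) else f"{v:.3g}")
        for metric in summary.across.index
    })
    parts.append(_section("Mean and SD across cases (per method)",
                          _render_table(mean_sd, fmt), fmt))

    meta = pd.DataFrame([{
        "study_id": s.study_id, "dataset": s.dataset, "site": s.site,
        "group": "clinical" if s.data_type == "clinical" else "nonclinical",
    } for s in db])
    merged = table.dropna(subset=["value"]).merge(meta, on="study_id")
    per_ds = merged.pivot_table(index="dataset", columns="metric",
                                values="value", aggfunc="mean")
    parts.append(_section("Mean metric values per dataset",
                          _render_table(per_ds, fmt), fmt))
    per_grp = merged.pivot_table(index=["group", "site"], columns="metric",
                                 values="value", aggfunc="mean")
    parts.append(_section("By data type and tumor site",
                          _render_table(per_grp, fmt), fmt))
    if fmt == "html":
        parts.append("</body></html>")
    doc = "\n".join(parts)
    if out_dir is not None:
        (out_dir / f"global.{fmt}").write_text(doc)
    return doc
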