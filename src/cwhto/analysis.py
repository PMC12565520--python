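"""Cohort-level batch simulation, summary tables, and group comparisons.

Summary tables follow the study's table conventions: mean ± SD per
technique × correction angle, a percent-of-conventional column computed as
the ratio of cell means (not the mean of per-knee ratios), and — for the
non-overlap area — a percent-of-proximal column relative to the same
technique's mean proximal cut area.  Percents are rounded to one decimal
for display, matching the printed tables.

Two-sample comparisons default to the Mann–Whitney U test (exact null
distribution for small samples), with Student's/Welch's t, Pearson's χ²
and Fisher's exact test available; significance is declared at p < 0.05
(strict).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .errors import BatchError, ParameterError, StatError
from .geometry import DEFAULT_SCANLINE_STEP, SimulationResult, simulate_knee
from .phantoms import KneeRecord, LandmarkSet
from .planning import Technique

__all__ = [
    "DEFAULT_THETAS",
    "ComparisonResult",
    "run_cohort",
    "results_to_frame",
    "summarize",
    "compare_groups",
    "subgroup_split",
    "compare_subgroups",
    "write_report",
]

DEFAULT_THETAS = (12.0, 15.0, 18.0)
DEFAULT_METRICS = (
    "proximal_area",
    "distal_area",
    "wedge_volume",
    "medial_gap_volume",
    "nonoverlap_magnitude",
)
SIGNIFICANCE_LEVEL = 0.05


def run_cohort(
    cohort: list[tuple[KneeRecord, trimesh.Trimesh, LandmarkSet]],
    techniques: list[Technique | str] | None = None,
    thetas: tuple[float, ...] = DEFAULT_THETAS,
    scanline_step: float = DEFAULT_SCANLINE_STEP,
    kerf: float = 0.0,
) -> tuple[list[SimulationResult], list[dict]]:
    """Simulate every knee × technique × angle cell.

    Per-cell failures are recorded (knee id, technique, theta, error) and
    the batch continues; a :class:`BatchError` is raised only if every
    cell failed.  Ordering is deterministic: knees in cohort order, then
    techniques, then angles.
    """
    if not cohort:
        raise ParameterError("empty cohort")
    techniques = [Technique(t) for t in (techniques or list(Technique))]
    results: list[SimulationResult] = []
    failures: list[dict] = []
    for record, mesh, landmarks in cohort:
        for technique in techniques:
            for theta in thetas:
                try:
                    results.append(
                        simulate_knee(mesh, landmarks, technique, theta,
                                      knee_id=record.knee_id,
                                      scanline_step=scanline_step,
                                      kerf=kerf)
                    )
                except Exception as exc:  # noqa: BLE001 - fault isolation
                    failures.append({
                        "knee_id": record.knee_id,
                        "technique": technique.value,
                        "theta": float(theta),
                        "error": f"{type(exc).__name__}: {exc}",
                    })
    if not results:
        raise BatchError(f"all {len(failures)} simulation cells failed")
    return results, failures


def results_to_frame(results: list[SimulationResult]) -> pd.DataFrame:
    """Tidy per-simulation DataFrame with a derived non-overlap magnitude."""
    df = pd.DataFrame([r.to_dict() for r in results])
    df["nonoverlap_magnitude"] = df["nonoverlap_signed"].abs()
    return df


def summarize(
    results: list[SimulationResult] | pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """Per-(technique, theta, metric) mean ± SD plus percent ratios.

    ``percent_of_conventional`` is 100 × mean / (conventional mean at the
    same theta); ``percent_of_proximal`` (non-overlap magnitude only) is
    100 × mean / (the technique's mean proximal area pooled over thetas).
    Sample SD uses the n−1 denominator and is reported as missing for
    n = 1.  Percents are rounded to one decimal.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if Technique.CONVENTIONAL.value not in set(df["technique"]):
        raise StatError("percent-of-conventional undefined: no conventional cells")
    rows = []
    proximal_means = df.groupby("technique")["proximal_area"].mean()
    for (technique, theta), cell in df.groupby(["technique", "theta"], sort=True):
        for metric in metrics:
            values = cell[metric].to_numpy(dtype=float)
            conv = df[(df["technique"] == Technique.CONVENTIONAL.value)
                      & (df["theta"] == theta)][metric].mean()
            mean = float(np.mean(values))
            pct_conv = round(100.0 * mean / conv, 1) if conv else np.nan
            pct_prox = np.nan
            if metric == "nonoverlap_magnitude":
                pct_prox = round(100.0 * mean / proximal_means[technique], 1)
            rows.append({
                "technique": technique,
                "theta": float(theta),
                "metric": metric,
                "n": len(values),
                "mean": mean,
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
                "percent_of_conventional": pct_conv,
                "percent_of_proximal": pct_prox,
            })
    out = pd.DataFrame(rows)
    order = [t.value for t in Technique]
    out["technique"] = pd.Categorical(out["technique"], categories=order, ordered=True)
    return out.sort_values(["metric", "theta", "technique"]).reset_index(drop=True)


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def compare_groups(
    sample_a,
    sample_b,
    test: str = "mann_whitney",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-group comparison.

    Continuous tests (``student_t``, ``welch_t``, ``mann_whitney``) take
    numeric samples of size ≥ 2; the Mann–Whitney U uses the exact null
    distribution when min(n_a, n_b) ≤ 8 and there are no ties, otherwise
    the tie- and continuity-corrected normal approximation.  Categorical
    tests (``chi_square`` without Yates correction, ``fisher_exact``
    two-sided) take a 2×2 count table as ``sample_a`` (``sample_b``
    ignored).
    """
    if test in ("chi_square", "fisher_exact"):
        table = np.asarray(sample_a, dtype=float)
        if table.shape != (2, 2) or (table < 0).any():
            raise StatError(f"{test} needs a non-negative 2x2 table")
        if test == "fisher_exact":
            res = stats.fisher_exact(table, alternative="two-sided")
            return ComparisonResult(label_a, label_b, test,
                                    float(res.statistic), float(res.pvalue))
        res = stats.chi2_contingency(table, correction=False)
        return ComparisonResult(label_a, label_b, test,
                                float(res.statistic), float(res.pvalue))

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatError(f"{test} needs >= 2 observations per group "
                        f"(got {len(a)}, {len(b)})")
    if test == "student_t":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise StatError(f"unknown test {test!r}")
    return ComparisonResult(label_a, label_b, test,
                            float(res.statistic), float(res.pvalue))


def subgroup_split(
    records: list[KneeRecord],
    criterion: str,
    mpta_threshold: float = 83.0,
    jlca_threshold: float = 7.0,
) -> dict[str, list[str]]:
    """Partition knee ids by sex, proximal tibia vara, or high JLCA.

    Boundary handling is inclusive on the pathological side: MPTA ≤ 83°
    counts as vara and JLCA ≥ 7° counts as high.  An empty subgroup emits
    a warning (comparisons on it should be skipped).
    """
    if criterion == "sex":
        groups = {
            "male": [r.knee_id for r in records if r.sex == "male"],
            "female": [r.knee_id for r in records if r.sex == "female"],
        }
    elif criterion == "mpta_vara":
        groups = {
            "vara": [r.knee_id for r in records if r.mpta <= mpta_threshold],
            "non_vara": [r.knee_id for r in records if r.mpta > mpta_threshold],
        }
    elif criterion == "high_jlca":
        groups = {
            "high_jlca": [r.knee_id for r in records if r.jlca >= jlca_threshold],
            "low_jlca": [r.knee_id for r in records if r.jlca < jlca_threshold],
        }
    else:
        raise ParameterError(
            f"criterion must be one of sex/mpta_vara/high_jlca, got {criterion!r}"
        )
    for label, ids in groups.items():
        if not ids:
            warnings.warn(f"subgroup {label!r} is empty; comparisons will be skipped",
                          stacklevel=2)
    return groups


def compare_subgroups(
    results: list[SimulationResult] | pd.DataFrame,
    records: list[KneeRecord],
    criterion: str,
    metrics: tuple[str, ...] = ("proximal_area", "distal_area",
                                "nonoverlap_magnitude", "wedge_volume"),
    test: str = "mann_whitney",
    mpta_threshold: float = 83.0,
    jlca_threshold: float = 7.0,
) -> pd.DataFrame:
    """Subgroup comparison of every technique × theta × metric cell."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    groups = subgroup_split(records, criterion, mpta_threshold, jlca_threshold)
    (label_a, ids_a), (label_b, ids_b) = groups.items()
    rows = []
    for (technique, theta, metric) in (
        (t, th, m)
        for t in df["technique"].unique()
        for th in sorted(df["theta"].unique())
        for m in metrics
    ):
        cell = df[(df["technique"] == technique) & (df["theta"] == theta)]
        a = cell[cell["knee_id"].isin(ids_a)][metric].to_numpy()
        b = cell[cell["knee_id"].isin(ids_b)][metric].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        cmp = compare_groups(a, b, test=test, label_a=label_a, label_b=label_b)
        rows.append({
            "criterion": criterion, "technique": technique, "theta": theta,
            "metric": metric, "group_a": label_a, "n_a": len(a),
            "group_b": label_b, "n_b": len(b), "test": cmp.test,
            "statistic": cmp.statistic, "p_value": cmp.p_value,
            "significant": cmp.significant,
        })
    return pd.DataFrame(rows)


def write_report(
    summary: pd.DataFrame,
    comparisons: pd.DataFrame | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write summary.csv, comparisons.csv and report.json under ``directory``.

    The JSON report carries the same rows plus a ``significant`` flag
    (p < 0.05, strict) on each comparison.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"summary": directory / "summary.csv"}
    summary.to_csv(paths["summary"], index=False)
    payload = {"summary": summary.to_dict(orient="records")}
    if comparisons is not None and len(comparisons):
        paths["comparisons"] = directory / "comparisons.csv"
        comparisons.to_csv(paths["comparisons"], index=False)
        payload["comparisons"] = comparisons.to_dict(orient="records")
    paths["report"] = directory / "report.json"
    paths["report"].write_text(json.dumps(payload, indent=2, default=float))
    return paths
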