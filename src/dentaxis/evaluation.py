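"""Leave-one-out accuracy evaluation of root-axis prediction.

The evaluation protocol mirrors how the method is validated clinically:

* **full-dentition scenario** -- each individual in turn is excluded, a
  shape model is trained on the remaining individuals, the excluded case's
  crown landmarks (all 14 teeth of the jaw) serve as the observation, and
  the predicted root axes of all 14 teeth are scored against the actual
  root landmarks;
* **missing-tooth scenario** -- additionally the crown landmarks of one
  designated tooth are removed from the observation, so that tooth's axis
  must be inferred purely from the neighbours; run once per tooth this
  yields 14 reconstruction scenarios per jaw.

Accuracy per (case, tooth) is angle alpha, Distance A and Distance B; the
summary reports per-tooth and pooled per-jaw mean +/- sd.  Scenario
differences are assessed with paired t-tests, Holm-adjusted across the
family of all teeth x metrics of a jaw.

A *mean-shape baseline* -- predicting every case with the training mean,
ignoring all shape covariation -- is available as the no-information
reference the model must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .axes import AxisErrorMetrics, axis_errors
from .dentition import DentitionDataset, DentitionLandmarks
from .model import (
    DentalShapeModel,
    PartialObservation,
    ReconstructionConfig,
    ShapeModelResults,
    reconstruct,
)
from .protocol import Jaw, LandmarkKind, LandmarkLabel, ToothId

__all__ = [
    "Scenario",
    "ScenarioConfig",
    "CaseResult",
    "EvaluationSummary",
    "PairedTestResult",
    "loocv",
    "run_all_missing_tooth_scenarios",
    "summarize",
    "paired_t_test",
    "holm_adjust",
    "compare_scenarios",
    "results_to_dataframe",
    "summary_to_dataframe",
    "comparison_to_dataframe",
]

METRICS = ("angle_alpha_deg", "distance_A_mm", "distance_B_mm")


class Scenario(str, Enum):
    FULL_DENTITION = "full_dentition"
    MISSING_TOOTH = "missing_tooth"


@dataclass(frozen=True)
class ScenarioConfig:
    """One evaluation condition.

    ``missing_tooth`` is required iff ``scenario == MISSING_TOOTH`` and must
    belong to ``jaw``.  ``evaluate_all_teeth`` widens the missing-tooth
    evaluation from the removed tooth (default) to all 14.  With
    ``mean_shape_baseline`` the reconstruction uses zero modes, i.e. the
    posed training mean.
    """

    jaw: Jaw
    scenario: Scenario = Scenario.FULL_DENTITION
    missing_tooth: ToothId | None = None
    reconstruction: ReconstructionConfig = ReconstructionConfig()
    variance_fraction: float = 0.98
    evaluate_all_teeth: bool = False
    mean_shape_baseline: bool = False

    def __post_init__(self) -> None:
        if self.scenario is Scenario.MISSING_TOOTH:
            if self.missing_tooth is None:
                raise ValueError("missing_tooth required for the missing-tooth scenario")
            if self.missing_tooth.jaw is not self.jaw:
                raise ValueError(
                    f"missing tooth {self.missing_tooth} is not in the {self.jaw.value} jaw")
        elif self.missing_tooth is not None:
            raise ValueError("missing_tooth only applies to the missing-tooth scenario")


@dataclass(frozen=True)
class CaseResult:
    """Accuracy of one predicted tooth in one LOOCV fold."""

    individual_id: str
    tooth: ToothId
    metrics: AxisErrorMetrics
    scenario: ScenarioConfig
    train_ids: tuple[str, ...]


def _strip_modes(results: ShapeModelResults) -> ShapeModelResults:
    """The mean-shape baseline: same mean and pose logic, zero modes."""
    return replace(results, modes=results.modes[:, :0],
                   variances=results.variances[:0], gpa=None, model=None)


def _observation_labels(dentition: DentitionLandmarks,
                        config: ScenarioConfig) -> tuple[LandmarkLabel, ...]:
    labels = [l for l in dentition.protocol.labels_of_jaw(config.jaw)
              if l.kind is LandmarkKind.CROWN]
    if config.scenario is Scenario.MISSING_TOOTH:
        labels = [l for l in labels if l.tooth != config.missing_tooth]
    return tuple(labels)


def _root_points(dentition: DentitionLandmarks, tooth: ToothId) -> np.ndarray:
    return np.stack([
        dentition[LandmarkLabel(tooth, LandmarkKind.ROOT, k)] for k in range(1, 5)
    ])


def loocv(dataset: DentitionDataset, config: ScenarioConfig) -> list[CaseResult]:
    """Leave-one-out cross-validation of axis prediction.

    For every individual: a shape model is fitted to all *other*
    individuals (the excluded case contributes nothing to its own training
    fold), the observation is formed from the excluded case's crown
    landmarks per the scenario, the configuration is reconstructed, and the
    predicted root landmarks LM-1..LM-4 of every evaluated tooth are scored
    against the actual ones.
    """
    if dataset.n_individuals < 3:
        raise ValueError("LOOCV needs at least 3 individuals")
    if config.scenario is Scenario.MISSING_TOOTH and not config.evaluate_all_teeth:
        evaluated: tuple[ToothId, ...] = (config.missing_tooth,)
    else:
        evaluated = dataset.protocol.teeth_of_jaw(config.jaw)

    out: list[CaseResult] = []
    for held_out in dataset:
        train = dataset.drop_individual(held_out.individual_id)
        train_ids = tuple(ind.individual_id for ind in train)
        assert held_out.individual_id not in train_ids
        fitted = DentalShapeModel(
            train, config.jaw, variance_fraction=config.variance_fraction).fit()
        if config.mean_shape_baseline:
            fitted = _strip_modes(fitted)
        obs = PartialObservation.from_dentition(
            held_out, _observation_labels(held_out, config))
        rec = reconstruct(fitted, obs, config.reconstruction)
        for tooth in evaluated:
            metrics = axis_errors(
                tooth,
                predicted_root=_root_points(rec.full_configuration, tooth),
                actual_root=_root_points(held_out, tooth),
            )
            out.append(CaseResult(held_out.individual_id, tooth, metrics,
                                  config, train_ids))
    return out


def run_all_missing_tooth_scenarios(
        dataset: DentitionDataset, jaw: Jaw,
        reconstruction: ReconstructionConfig | None = None,
        variance_fraction: float = 0.98,
        evaluate_all_teeth: bool = False,
) -> dict[ToothId, list[CaseResult]]:
    """Run the missing-tooth LOOCV once per tooth of the jaw (14 scenarios)."""
    reconstruction = reconstruction or ReconstructionConfig()
    out: dict[ToothId, list[CaseResult]] = {}
    for tooth in dataset.protocol.teeth_of_jaw(jaw):
        config = ScenarioConfig(
            jaw=jaw, scenario=Scenario.MISSING_TOOTH, missing_tooth=tooth,
            reconstruction=reconstruction, variance_fraction=variance_fraction,
            evaluate_all_teeth=evaluate_all_teeth)
        out[tooth] = loocv(dataset, config)
    return out


@dataclass(frozen=True)
class MetricStats:
    mean: float
    sd: float
    n: int

    @property
    def sd_defined(self) -> bool:
        return self.n > 1


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-tooth and pooled per-jaw mean +/- sd of the three metrics."""

    jaw: Jaw
    per_tooth: Mapping[ToothId, Mapping[str, MetricStats]]
    per_jaw: Mapping[str, MetricStats]
    n_cases: int


def _stats(values: Sequence[float]) -> MetricStats:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    # n=1: sd undefined; reported as 0 with the n flag so tables stay total
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return MetricStats(mean=float(arr.mean()), sd=sd, n=n)


def summarize(results: Sequence[CaseResult], jaw: Jaw) -> EvaluationSummary:
    """Aggregate case results into the per-tooth / per-jaw accuracy table.

    The per-jaw aggregate pools every (case, tooth) measurement of the jaw,
    so it equals the measurement-weighted mean of the per-tooth means.
    """
    results = [r for r in results if r.tooth.jaw is jaw]
    if not results:
        raise ValueError(f"no results for the {jaw.value} jaw")
    per_tooth_vals: dict[ToothId, dict[str, list[float]]] = {}
    pooled: dict[str, list[float]] = {m: [] for m in METRICS}
    for r in results:
        bucket = per_tooth_vals.setdefault(r.tooth, {m: [] for m in METRICS})
        for m in METRICS:
            v = getattr(r.metrics, m)
            bucket[m].append(v)
            pooled[m].append(v)
    per_tooth = {
        tooth: {m: _stats(vals[m]) for m in METRICS}
        for tooth, vals in sorted(per_tooth_vals.items())
    }
    per_jaw = {m: _stats(pooled[m]) for m in METRICS}
    return EvaluationSummary(jaw=jaw, per_tooth=per_tooth, per_jaw=per_jaw,
                             n_cases=len(results))


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test on per-pair differences."""

    t_statistic: float
    degrees_of_freedom: int
    p_value_raw: float
    n_pairs: int
    p_value_adjusted: float | None = None
    zero_variance: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """t = mean(d) / (sd(d)/sqrt(n)) on d = x - y, two-sided p, df = n - 1.

    Degenerate differences (zero variance) are reported rather than raised:
    identical samples give t = 0, p = 1; a constant nonzero shift gives
    t = +/-inf with p = 0 and the ``zero_variance`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.isclose(d.std(ddof=1), 0.0):
        if np.isclose(d.mean(), 0.0):
            return PairedTestResult(0.0, n - 1, 1.0, n, zero_variance=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTestResult(float(t), n - 1, 0.0, n, zero_variance=True)
    res = stats.ttest_rel(x, y)
    return PairedTestResult(float(res.statistic), n - 1, float(res.pvalue), n)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adjusted]


def compare_scenarios(full_results: Sequence[CaseResult],
                      missing_results: Sequence[CaseResult],
                      ) -> dict[tuple[ToothId, str], PairedTestResult]:
    """Per-tooth, per-metric paired tests between the two scenarios.

    Pairs are matched on (individual, tooth); a mismatch in pairing raises
    with the unmatched keys.  Holm adjustment runs across the whole family
    of tests performed here (all compared teeth x 3 metrics).
    """
    def index(results):
        idx: dict[tuple[str, ToothId], AxisErrorMetrics] = {}
        for r in results:
            idx[(r.individual_id, r.tooth)] = r.metrics
        return idx

    full_idx = index(full_results)
    miss_idx = index(missing_results)
    teeth = sorted({t for (_, t) in miss_idx})
    tests: dict[tuple[ToothId, str], tuple[list[float], list[float]]] = {}
    unmatched = sorted(
        (i, t.fdi_code) for (i, t) in miss_idx if (i, t) not in full_idx)
    if unmatched:
        raise ValueError(f"unmatched (individual, tooth) pairs: {unmatched}")
    for tooth in teeth:
        pairs = sorted(i for (i, t) in miss_idx if t == tooth)
        for m in METRICS:
            x = [getattr(full_idx[(i, tooth)], m) for i in pairs]
            y = [getattr(miss_idx[(i, tooth)], m) for i in pairs]
            tests[(tooth, m)] = (x, y)

    keys = list(tests)
    raw = [paired_t_test(*tests[k]) for k in keys]
    adjusted = holm_adjust([r.p_value_raw for r in raw])
    return {
        k: replace(r, p_value_adjusted=adj)
        for k, r, adj in zip(keys, raw, adjusted)
    }


# ---------------------------------------------------------------------------
# tabular reports


def results_to_dataframe(results: Sequence[CaseResult]) -> pd.DataFrame:
    """Long-format table of every (case, tooth) measurement."""
    rows = []
    for r in results:
        rows.append({
            "individual_id": r.individual_id,
            "fdi_code": r.tooth.fdi_code,
            "jaw": r.tooth.jaw.value,
            "scenario": r.scenario.scenario.value,
            "missing_tooth": (r.scenario.missing_tooth.fdi_code
                              if r.scenario.missing_tooth else ""),
            "angle_alpha_deg": r.metrics.angle_alpha_deg,
            "distance_A_mm": r.metrics.distance_A_mm,
            "distance_B_mm": r.metrics.distance_B_mm,
        })
    return pd.DataFrame(rows)


def summary_to_dataframe(summary: EvaluationSummary) -> pd.DataFrame:
    """Accuracy table: one row per tooth plus a pooled per-jaw row."""
    rows = []
    for tooth, stats_by_metric in summary.per_tooth.items():
        row = {"fdi_code": tooth.fdi_code}
        for m in METRICS:
            row[f"mean_{m}"] = stats_by_metric[m].mean
            row[f"sd_{m}"] = stats_by_metric[m].sd
            row[f"n_{m}"] = stats_by_metric[m].n
        rows.append(row)
    row = {"fdi_code": f"all_{summary.jaw.value}"}
    for m in METRICS:
        row[f"mean_{m}"] = summary.per_jaw[m].mean
        row[f"sd_{m}"] = summary.per_jaw[m].sd
        row[f"n_{m}"] = summary.per_jaw[m].n
    rows.append(row)
    return pd.DataFrame(rows)


def comparison_to_dataframe(
        comparison: Mapping[tuple[ToothId, str], PairedTestResult]) -> pd.DataFrame:
    rows = []
    for (tooth, metric), res in comparison.items():
        rows.append({
            "fdi_code": tooth.fdi_code, "metric": metric,
            "t_statistic": res.t_statistic, "df": res.degrees_of_freedom,
            "p_raw": res.p_value_raw, "p_holm": res.p_value_adjusted,
            "n_pairs": res.n_pairs, "zero_variance": res.zero_variance,
        })
    return pd.DataFrame(rows)
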