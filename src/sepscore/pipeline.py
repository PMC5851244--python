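"""End-to-end analysis: score a cohort, compute the diagnostic metric
panel, and run paired score comparisons.

Accepts either a patient-level :class:`~sepscore.cohort_io.CohortFile`
(every metric and paired test available) or the grouped-count
:class:`~sepscore.cohort_io.Table2Fixture` (marginal metrics only: the
published grouped tables do not determine the within-patient joint
distribution of two scores, so paired tests are reported as unavailable
with the reason rather than approximated).

Display rounding — integer percent for proportions, 3-decimal AUC, half-up
— happens at serialization only; internal values stay at full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Union

import numpy as np

from . import diagnostics as dx
from .cohort_io import CohortFile, Table2Fixture, expand_grouped
from .errors import DegenerateInputError
from .scores import Outcome, score_record

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ScoreMetrics", "MetricPanel", "run_analysis",
           "round_half_up"]


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the metric panel: the positivity cutoff (score >= cutoff),
    the lactate threshold in mmol/L, CI estimators, and which score pairs
    to compare."""

    cutoff: float = 2
    lactate_threshold: float = 2.0
    ci_method: dx.CiMethod = dx.CiMethod.WALD
    auc_ci_method: dx.AucCiMethod = dx.AucCiMethod.DELONG
    ci_level: float = 0.95
    comparisons: tuple[tuple[str, str], ...] = (
        ("qsofa_lactate", "qsofa"),
        ("qsofa_lactate", "sofa"),
    )

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.lactate_threshold <= 0:
            raise ValueError("lactate threshold must be > 0")


@dataclass(frozen=True)
class ScoreMetrics:
    name: str
    performance: Optional[dx.DiagnosticPerformance] = None
    auroc: Optional[dx.AurocEstimate] = None
    unavailable_reason: str = ""

    @property
    def available(self) -> bool:
        return self.performance is not None


@dataclass(frozen=True)
class ComparisonEntry:
    pair: tuple[str, str]
    delong: Optional[dx.PairedComparison] = None
    sens_spec: Optional[dx.PairedSensSpecResult] = None
    unavailable_reason: str = ""


@dataclass(frozen=True)
class MetricPanel:
    """Per-score diagnostic metrics, per-pair comparisons, cohort summary."""

    scores: tuple[ScoreMetrics, ...]
    comparisons: tuple[ComparisonEntry, ...]
    n: int
    deaths: int
    exclusions: int

    def score(self, name: str) -> ScoreMetrics:
        for s in self.scores:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        """Report-shaped dict with display rounding applied (integer %,
        3-decimal AUC, half-up)."""
        out: dict = {
            "cohort": {"n": self.n, "deaths": self.deaths,
                       "mortality_pct": round_half_up(100 * self.deaths / self.n, 1),
                       "exclusions": self.exclusions},
            "scores": {},
            "comparisons": {},
        }
        for s in self.scores:
            if not s.available:
                out["scores"][s.name] = {"unavailable": True,
                                         "reason": s.unavailable_reason}
                continue
            perf, auc = s.performance, s.auroc
            out["scores"][s.name] = {
                "sensitivity_pct": int(round_half_up(100 * perf.sensitivity)),
                "specificity_pct": int(round_half_up(100 * perf.specificity)),
                "sens_ci_pct": [int(round_half_up(100 * v)) for v in perf.sens_ci],
                "spec_ci_pct": [int(round_half_up(100 * v)) for v in perf.spec_ci],
                "auroc": round_half_up(auc.auc, 3),
                "auroc_ci": [round_half_up(auc.ci_low, 3), round_half_up(auc.ci_high, 3)],
                "counts": {"tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn},
            }
        for c in self.comparisons:
            key = f"{c.pair[0]}_vs_{c.pair[1]}"
            if c.delong is None:
                out["comparisons"][key] = {"unavailable": True,
                                           "reason": c.unavailable_reason}
            else:
                entry = {
                    "auc_delta": round_half_up(c.delong.delta, 4),
                    "delong_p": round_half_up(c.delong.p, 4),
                }
                if c.sens_spec is not None:
                    entry["sens_mcnemar_p"] = round_half_up(c.sens_spec.sensitivity.p, 4)
                    entry["spec_mcnemar_p"] = round_half_up(c.sens_spec.specificity.p, 4)
                    entry["joint_wls_p"] = round_half_up(c.sens_spec.joint.p, 4)
                out["comparisons"][key] = entry
        return out


_FIXTURE_UNAVAILABLE = ("grouped marginal tables do not determine the "
                        "within-patient joint distribution of two scores")


def _panel_from_fixture(fixture: Table2Fixture, config: AnalysisConfig) -> MetricPanel:
    tables = {
        "lactate": fixture.lactate_binary_table,
        "qsofa": fixture.qsofa_table,
        "qsofa_lactate": fixture.qsofa_lactate_table,
    }
    scores = []
    for name, table in tables.items():
        # the binary lactate indicator is positive at level 1
        cutoff = 1 if name == "lactate" else config.cutoff
        perf = dx.sens_spec_from_grouped(table, cutoff, config.ci_level, config.ci_method)
        s, y = expand_grouped(table)
        auc = dx.auroc_with_ci(s, y, config.ci_level, config.auc_ci_method)
        scores.append(ScoreMetrics(name=name, performance=perf, auroc=auc))
    for name in ("sirs", "sofa"):
        scores.append(ScoreMetrics(name=name, unavailable_reason="inputs not in the grouped fixture"))
    comparisons = tuple(
        ComparisonEntry(pair=pair, unavailable_reason=_FIXTURE_UNAVAILABLE)
        for pair in config.comparisons)
    for c in comparisons:
        logger.info("comparison %s vs %s skipped: %s", c.pair[0], c.pair[1],
                    c.unavailable_reason)
    return MetricPanel(scores=tuple(scores), comparisons=comparisons,
                       n=fixture.n_total, deaths=fixture.n_pos, exclusions=0)


def _panel_from_cohort(cohort: CohortFile, config: AnalysisConfig) -> MetricPanel:
    if not cohort.records:
        raise DegenerateInputError("empty cohort")
    labels = np.array([1 if r.outcome is Outcome.DIED else 0 for r in cohort.records])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateInputError("cohort contains a single outcome class")

    panels = [score_record(r, lactate_threshold=config.lactate_threshold)
              for r in cohort.records]
    vectors: dict[str, Optional[np.ndarray]] = {
        "lactate": np.array([p.lactate_point for p in panels], dtype=float),
        "qsofa": np.array([p.qsofa for p in panels], dtype=float),
        "qsofa_lactate": np.array([p.qsofa_lactate for p in panels], dtype=float),
        "sirs": (np.array([p.sirs.score for p in panels], dtype=float)
                 if all(p.sirs is not None for p in panels) else None),
        "sofa": (np.array([p.sofa.total for p in panels], dtype=float)
                 if all(p.sofa is not None for p in panels) else None),
    }

    scores = []
    for name, vec in vectors.items():
        if vec is None:
            scores.append(ScoreMetrics(name=name,
                                       unavailable_reason="required inputs missing from cohort"))
            continue
        cutoff = 1 if name == "lactate" else config.cutoff
        try:
            perf = dx.sens_spec_at_cutoff(vec, labels, cutoff, config.ci_level,
                                          config.ci_method)
            auc = dx.auroc_with_ci(vec, labels, config.ci_level, config.auc_ci_method)
        except DegenerateInputError as exc:
            scores.append(ScoreMetrics(name=name, unavailable_reason=str(exc)))
            continue
        scores.append(ScoreMetrics(name=name, performance=perf, auroc=auc))

    comparisons = []
    for pair in config.comparisons:
        a, b = (vectors.get(p) for p in pair)
        if a is None or b is None:
            comparisons.append(ComparisonEntry(
                pair=pair, unavailable_reason="one of the scores is unavailable"))
            continue
        delong = dx.paired_delong_test(a, b, labels)
        cutoff_a = 1 if pair[0] == "lactate" else config.cutoff
        cutoff_b = 1 if pair[1] == "lactate" else config.cutoff
        ss = dx.paired_sens_spec_test(a >= cutoff_a, b >= cutoff_b, labels)
        comparisons.append(ComparisonEntry(pair=pair, delong=delong, sens_spec=ss))

    return MetricPanel(scores=tuple(scores), comparisons=tuple(comparisons),
                       n=len(cohort.records), deaths=int(labels.sum()),
                       exclusions=len(cohort.exclusions))


def run_analysis(cohort: Union[CohortFile, Table2Fixture],
                 config: AnalysisConfig = AnalysisConfig()) -> MetricPanel:
    """Compute the full metric panel for a cohort or the grouped fixture.

    For each available score (lactate-binary, SIRS, qSOFA, qSOFA+lactate,
    full SOFA): sensitivity/specificity at the cutoff and AUROC with CIs.
    Paired DeLong and paired sensitivity/specificity tests run for each
    configured score pair when patient-level scores exist; with fixture
    input they are marked unavailable with the reason.
    """
    if isinstance(cohort, Table2Fixture):
        return _panel_from_fixture(cohort, config)
    return _panel_from_cohort(cohort, config)
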