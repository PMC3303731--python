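"""Disease-vs-neutral discrimination from conformer ΔΔG values.

Implements the classification rule (a substitution is called disease when
its |ΔΔG| exceeds the threshold, i.e. perturbing in either direction), the
contingency-table metrics (MCC, accuracy, specificity, sensitivity), and
five conformer-selection strategies: every cell at once ("global"), the
per-substitution minimum / maximum / mean, and a resampled random-conformer
baseline with an empirical one-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .ensemble_stats import ThresholdConfig, summarize_sas
from .variant_io import DdgMatrix, SasKey, SasRecord

STRATEGIES = ("global", "min", "max", "mean", "random")

#: Table layout order used in reports.
STRATEGY_DISPLAY = {
    "global": "Global",
    "min": "Minimum",
    "max": "Maximum",
    "mean": "Average",
    "random": "Random",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts with disease as the positive class, perturbing as predicted positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.total < 1:
            raise ValueError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    mcc: float
    accuracy: float
    specificity: Optional[float]  # None when tn + fp == 0
    sensitivity: Optional[float]  # None when tp + fn == 0
    table: ContingencyTable


@dataclass
class StrategyResult:
    strategy: str
    metrics: EvalMetrics
    n_sas: int
    n_resamples: Optional[int] = None
    seed: Optional[int] = None
    resample_mccs: Optional[np.ndarray] = None
    p_value_vs_reference: Optional[float] = None


def predict_label(ddg: float, config: ThresholdConfig = ThresholdConfig()) -> str:
    """"disease" iff |ΔΔG| > tau — stabilizing and destabilizing both perturb."""
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    return "disease" if abs(ddg) > config.tau else "neutral"


def predict_label_destabilizing_only(
    ddg: float, config: ThresholdConfig = ThresholdConfig()
) -> str:
    """One-sided variant: only ΔΔG > tau counts as perturbing."""
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    return "disease" if ddg > config.tau else "neutral"


def mcc(table: ContingencyTable) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = table.tp, table.tn, table.fp, table.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def metrics_from_table(table: ContingencyTable) -> EvalMetrics:
    tp, tn, fp, fn = table.tp, table.tn, table.fp, table.fn
    return EvalMetrics(
        mcc=mcc(table),
        accuracy=(tp + tn) / table.total,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else None,
        sensitivity=tp / (tp + fn) if (tp + fn) > 0 else None,
        table=table,
    )


def tabulate(labels: Sequence[str], predictions: Sequence[str]) -> ContingencyTable:
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    tp = tn = fp = fn = 0
    for truth, pred in zip(labels, predictions):
        if truth == "disease":
            if pred == "disease":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "disease":
                fp += 1
            else:
                tn += 1
    return ContingencyTable(tp=tp, tn=tn, fp=fp, fn=fn)


def _label_map(labels: Iterable[SasRecord]) -> dict[SasKey, str]:
    return {r.key: r.label for r in labels}


def _check_coverage(matrix: DdgMatrix, label_by_key: Mapping[SasKey, str]) -> None:
    missing = [k for k in matrix.sas_keys if k not in label_by_key]
    if missing:
        raise ValueError(f"substitutions without labels: {missing[:5]}")


def _mean_metrics(metrics_list: Sequence[EvalMetrics]) -> EvalMetrics:
    """Average of metric values over resamples; counts averaged and rounded."""
    def _avg(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    if all(m == metrics_list[0] for m in metrics_list[1:]):
        return metrics_list[0]  # keeps the degenerate single-conformer case exact

    table = ContingencyTable(
        tp=round(np.mean([m.table.tp for m in metrics_list])),
        tn=round(np.mean([m.table.tn for m in metrics_list])),
        fp=round(np.mean([m.table.fp for m in metrics_list])),
        fn=round(np.mean([m.table.fn for m in metrics_list])),
    )
    return EvalMetrics(
        mcc=float(np.mean([m.mcc for m in metrics_list])),
        accuracy=float(np.mean([m.accuracy for m in metrics_list])),
        specificity=_avg([m.specificity for m in metrics_list]),
        sensitivity=_avg([m.sensitivity for m in metrics_list]),
        table=table,
    )


def evaluate_strategy(
    matrix: DdgMatrix,
    labels: Sequence[SasRecord],
    strategy: str,
    config: ThresholdConfig = ThresholdConfig(),
    seed: int = 0,
    n_resamples: int = 1000,
) -> StrategyResult:
    """Evaluate one conformer-selection strategy against the phenotype labels.

    * ``global``: every (substitution, conformer) cell is an independent
      prediction paired with its substitution's label.
    * ``min`` / ``max`` / ``mean``: one prediction per substitution from the
      corresponding per-substitution summary statistic.
    * ``random``: for each of ``n_resamples`` resamples, one uniformly chosen
      conformer value per substitution; reported metrics are resample means.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    label_by_key = _label_map(labels)
    _check_coverage(matrix, label_by_key)
    rows = list(matrix.rows())

    if strategy == "global":
        truths, preds = [], []
        for key, values in rows:
            for v in values.values():
                truths.append(label_by_key[key])
                preds.append(predict_label(v, config))
        metrics = metrics_from_table(tabulate(truths, preds))
        return StrategyResult(strategy=strategy, metrics=metrics, n_sas=len(rows))

    if strategy in ("min", "max", "mean"):
        truths, preds = [], []
        for key, values in rows:
            s = summarize_sas(values.values())
            stat = {"min": s.ddg_min, "max": s.ddg_max, "mean": s.ddg_mean}[strategy]
            truths.append(label_by_key[key])
            preds.append(predict_label(stat, config))
        metrics = metrics_from_table(tabulate(truths, preds))
        return StrategyResult(strategy=strategy, metrics=metrics, n_sas=len(rows))

    # random
    rng = np.random.default_rng(seed)
    truths = [label_by_key[key] for key, _ in rows]
    value_arrays = [np.fromiter(values.values(), dtype=float) for _, values in rows]
    resample_metrics = []
    resample_mccs = np.empty(n_resamples)
    for b in range(n_resamples):
        preds = [
            predict_label(vals[rng.integers(len(vals))], config)
            for vals in value_arrays
        ]
        m = metrics_from_table(tabulate(truths, preds))
        resample_metrics.append(m)
        resample_mccs[b] = m.mcc
    return StrategyResult(
        strategy=strategy,
        metrics=_mean_metrics(resample_metrics),
        n_sas=len(rows),
        n_resamples=n_resamples,
        seed=seed,
        resample_mccs=resample_mccs,
    )


def random_significance(
    matrix: DdgMatrix,
    labels: Sequence[SasRecord],
    config: ThresholdConfig = ThresholdConfig(),
    reference_strategy: str = "max",
    seed: int = 0,
    n_resamples: int = 1000,
) -> float:
    """Empirical one-sided p-value of the reference strategy vs random draws.

    p = (k + 1) / (n_resamples + 1) where k counts resampled MCC values
    greater than or equal to the reference strategy's MCC.
    """
    reference = evaluate_strategy(
        matrix, labels, reference_strategy, config, seed=seed, n_resamples=n_resamples
    )
    random_result = evaluate_strategy(
        matrix, labels, "random", config, seed=seed, n_resamples=n_resamples
    )
    k = int(np.sum(random_result.resample_mccs >= reference.metrics.mcc - 1e-12))
    return (k + 1) / (n_resamples + 1)


def evaluate_all_strategies(
    matrix: DdgMatrix,
    labels: Sequence[SasRecord],
    config: ThresholdConfig = ThresholdConfig(),
    seed: int = 0,
    n_resamples: int = 1000,
    reference_strategy: str = "max",
) -> list[StrategyResult]:
    """All five strategies in report order, with the random-baseline p-value."""
    results = [
        evaluate_strategy(matrix, labels, s, config, seed=seed, n_resamples=n_resamples)
        for s in STRATEGIES
    ]
    by_name = {r.strategy: r for r in results}
    random_result = by_name["random"]
    reference = by_name[reference_strategy]
    k = int(np.sum(random_result.resample_mccs >= reference.metrics.mcc - 1e-12))
    random_result.p_value_vs_reference = (k + 1) / (random_result.n_resamples + 1)
    return results


def per_conformer_metrics(
    matrix: DdgMatrix,
    labels: Sequence[SasRecord],
    protein_id: str,
    config: ThresholdConfig = ThresholdConfig(),
) -> dict[str, EvalMetrics]:
    """Metrics per conformer using only that conformer's ΔΔG column."""
    label_by_key = _label_map(labels)
    block = [
        (key, values) for key, values in matrix.rows() if key[0] == protein_id
    ]
    if not block:
        raise KeyError(protein_id)
    out: dict[str, EvalMetrics] = {}
    for conformer_id in matrix.conformers_for(protein_id):
        truths, preds = [], []
        for key, values in block:
            if conformer_id in values:
                truths.append(label_by_key[key])
                preds.append(predict_label(values[conformer_id], config))
        if not truths:
            continue  # column entirely missing for this protein
        out[conformer_id] = metrics_from_table(tabulate(truths, preds))
    return out


def mcc_range(metrics: Mapping[str, EvalMetrics]) -> tuple[float, float]:
    vals = [m.mcc for m in metrics.values()]
    return min(vals), max(vals)


def perfect_conformer_fraction(
    matrix: DdgMatrix,
    labels: Sequence[SasRecord],
    config: ThresholdConfig = ThresholdConfig(),
) -> float:
    """Fraction of substitutions with >= 1 conformer predicting the true label."""
    label_by_key = _label_map(labels)
    _check_coverage(matrix, label_by_key)
    n_total = 0
    n_perfect = 0
    for key, values in matrix.rows():
        n_total += 1
        truth = label_by_key[key]
        if any(predict_label(v, config) == truth for v in values.values()):
            n_perfect += 1
    return n_perfect / n_total


def bound_state_enrichment(
    matrix: DdgMatrix, bound_flags: Mapping[str, bool]
) -> float:
    """Fraction of flagged proteins whose max-ΔΔG conformer is ligand bound.

    For each protein the conformer attaining the maximum ΔΔG over all of its
    substitutions is identified; ties count as bound if any tied conformer
    is bound. Proteins whose conformers carry no flags are excluded.
    """
    n_proteins = 0
    n_bound = 0
    for protein_id in matrix.proteins:
        block = matrix.protein_block(protein_id)
        flagged = [c for c in block.columns if c in bound_flags]
        if not flagged:
            continue
        col_max = block.max(axis=0)  # NaN-skipping per-conformer maximum
        overall = col_max.max()
        tied = col_max.index[col_max == overall]
        known_tied = [c for c in tied if c in bound_flags]
        if not known_tied:
            continue
        n_proteins += 1
        if any(bound_flags[c] for c in known_tied):
            n_bound += 1
    if n_proteins == 0:
        raise ValueError("no proteins with bound/unbound flags")
    return n_bound / n_proteins


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    result = stats.ks_2samp(x, y, method="asymp")
    return float(result.statistic), float(result.pvalue)
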