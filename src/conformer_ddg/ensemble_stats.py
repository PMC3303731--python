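"""Per-substitution aggregation of conformer ΔΔG values and ensemble ambiguity.

A substitution's stability call can change with the conformer used to
estimate it. This module summarizes each substitution over its conformers
(min / max / mean / spread), classifies stability at a symmetric threshold,
flags substitutions whose class depends on the conformer, lifts the flag to
the protein level, and bins the signed ΔASA against the ΔΔG spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_io import DdgMatrix, SasKey, SasRecord

STABILIZING = "stabilizing"
NEUTRAL = "neutral"
DESTABILIZING = "destabilizing"


@dataclass(frozen=True)
class ThresholdConfig:
    """Symmetric stability cutoff in kcal/mol (default 2.0, alternative 1.0)."""

    tau: float = 2.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class SasSummary:
    ddg_min: float
    ddg_max: float
    ddg_mean: float
    n_conformers_used: int

    @property
    def ddg_spread(self) -> float:
        return self.ddg_max - self.ddg_min


def _clean(ddg_row: Iterable[Optional[float]]) -> list[float]:
    values = [v for v in ddg_row if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not values:
        raise ValueError("no non-missing ΔΔG values for this substitution")
    return values


def summarize_sas(ddg_row: Iterable[Optional[float]]) -> SasSummary:
    """Min/max/mean ΔΔG over the non-missing conformer values of one substitution."""
    values = _clean(ddg_row)
    return SasSummary(
        ddg_min=min(values),
        ddg_max=max(values),
        ddg_mean=float(np.mean(values)),
        n_conformers_used=len(values),
    )


def classify_stability(ddg: float, config: ThresholdConfig = ThresholdConfig()) -> str:
    """Three-way stability call; |ΔΔG| equal to tau counts as neutral."""
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    if ddg > config.tau:
        return DESTABILIZING
    if ddg < -config.tau:
        return STABILIZING
    return NEUTRAL


def is_ambiguous(
    ddg_row: Iterable[Optional[float]], config: ThresholdConfig = ThresholdConfig()
) -> bool:
    """True iff the stability class differs between conformers."""
    classes = {classify_stability(v, config) for v in _clean(ddg_row)}
    return len(classes) >= 2


def sas_summary_table(matrix: DdgMatrix) -> pd.DataFrame:
    """One row per substitution: min/max/mean/spread and conformers used."""
    rows = []
    for key, values in matrix.rows():
        s = summarize_sas(values.values())
        rows.append(
            {
                "protein_id": key[0],
                "position": key[1],
                "wt_aa": key[2],
                "mut_aa": key[3],
                "ddg_min": s.ddg_min,
                "ddg_max": s.ddg_max,
                "ddg_mean": s.ddg_mean,
                "ddg_spread": s.ddg_spread,
                "n_conformers_used": s.n_conformers_used,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AmbiguityReport:
    per_protein: pd.DataFrame  # protein_id, n_sas, n_ambiguous, ambiguous flag
    fraction_ambiguous_proteins: float
    composition: dict[str, float]  # label -> fraction among ambiguous substitutions
    mean_rmsd_max_ambiguous: Optional[float] = None
    mean_rmsd_max_unambiguous: Optional[float] = None


def protein_ambiguity(
    matrix: DdgMatrix,
    labels: Optional[Sequence[SasRecord]] = None,
    config: ThresholdConfig = ThresholdConfig(),
    rmsd_max: Optional[Mapping[str, float]] = None,
) -> AmbiguityReport:
    """Fraction of proteins with >= 1 conformer-ambiguous substitution.

    When labels are supplied the label composition of the ambiguous
    substitutions is reported; when per-protein RMSDmax values are supplied
    the mean RMSDmax is split by the protein's ambiguity flag.
    """
    label_by_key = {r.key: r.label for r in labels} if labels else {}
    per_protein: dict[str, dict] = {}
    ambiguous_labels: list[str] = []
    for key, values in matrix.rows():
        entry = per_protein.setdefault(
            key[0], {"protein_id": key[0], "n_sas": 0, "n_ambiguous": 0}
        )
        entry["n_sas"] += 1
        if is_ambiguous(values.values(), config):
            entry["n_ambiguous"] += 1
            if key in label_by_key:
                ambiguous_labels.append(label_by_key[key])
    df = pd.DataFrame(sorted(per_protein.values(), key=lambda e: e["protein_id"]))
    df["ambiguous"] = df["n_ambiguous"] > 0
    fraction = float(df["ambiguous"].mean())
    composition: dict[str, float] = {}
    if ambiguous_labels:
        total = len(ambiguous_labels)
        for label in ("disease", "neutral"):
            composition[label] = ambiguous_labels.count(label) / total
    report = AmbiguityReport(
        per_protein=df,
        fraction_ambiguous_proteins=fraction,
        composition=composition,
    )
    if rmsd_max:
        amb = [rmsd_max[p] for p in df.loc[df["ambiguous"], "protein_id"] if p in rmsd_max]
        unamb = [rmsd_max[p] for p in df.loc[~df["ambiguous"], "protein_id"] if p in rmsd_max]
        report.mean_rmsd_max_ambiguous = float(np.mean(amb)) if amb else None
        report.mean_rmsd_max_unambiguous = float(np.mean(unamb)) if unamb else None
    return report


def signed_delta_asa(
    ddg_row: Mapping[str, float], asa_row: Mapping[str, float]
) -> Optional[float]:
    """Signed ΔASA oriented by the conformer pair with the largest ΔΔG gap.

    Over conformers present in both maps, picks the pair (hi, lo) attaining
    the maximal ΔΔG difference and returns ASA(hi) - ASA(lo). Returns None
    when fewer than two conformers carry both a ΔΔG and an ASA value.
    """
    shared = [c for c in ddg_row if c in asa_row]
    if len(shared) < 2:
        return None
    hi = max(shared, key=lambda c: ddg_row[c])
    lo = min(shared, key=lambda c: ddg_row[c])
    return asa_row[hi] - asa_row[lo]


def binned_dasa_ddg(
    pairs: Iterable[tuple[float, float]], bin_width: float = 10.0
) -> pd.DataFrame:
    """Bin (ΔASA, ΔΔG-spread) pairs into half-open ΔASA bins of ``bin_width``.

    Returns one row per non-empty bin: center, n, mean spread, standard error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    buckets: dict[int, list[float]] = {}
    for dasa, spread in pairs:
        k = math.floor(dasa / bin_width)
        buckets.setdefault(k, []).append(spread)
    rows = []
    for k in sorted(buckets):
        vals = np.asarray(buckets[k], dtype=float)
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "bin_center": k * bin_width + bin_width / 2.0,
                "n": len(vals),
                "mean": float(vals.mean()),
                "se": se,
            }
        )
    return pd.DataFrame(rows, columns=["bin_center", "n", "mean", "se"])
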