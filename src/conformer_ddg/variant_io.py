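"""Readers and writers for substitution annotations and ΔΔG tables.

The ΔΔG table carries one value per (substitution, conformer) pair in
kcal/mol, produced by an external stability engine. Positive values are
destabilizing. Missing cells are written as the literal ``NA``.
"""

from __future__ import annotations

import datetime
import json
import logging
import shlex
import subprocess
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

LABEL_ALIASES = {
    "disease": "disease",
    "neutral": "neutral",
    "polymorphism": "neutral",
}

SAS_COLUMNS = ["protein_id", "position", "wt_aa", "mut_aa", "label"]
DDG_COLUMNS = ["protein_id", "position", "wt_aa", "mut_aa", "conformer_id", "ddg_kcal_mol"]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class VariantTableError(ValueError):
    """Raised for malformed substitution or ΔΔG tables."""


@dataclass(frozen=True)
class SasRecord:
    """One single amino acid substitution with its phenotype label."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str  # "disease" | "neutral"

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise VariantTableError(
                f"residues must be one-letter amino acids, got "
                f"{self.wt_aa!r}/{self.mut_aa!r}"
            )
        if self.wt_aa == self.mut_aa:
            raise VariantTableError(
                f"{self.protein_id} position {self.position}: wild-type and "
                "substituted residue are identical"
            )
        if self.position < 1:
            raise VariantTableError("position must be >= 1")
        if self.label not in ("disease", "neutral"):
            raise VariantTableError(f"unknown label {self.label!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


SasKey = tuple[str, int, str, str]


class DdgMatrix:
    """ΔΔG values indexed by (substitution, conformer id), kcal/mol.

    Backed by a long-form table; missing (substitution, conformer) pairs are
    simply absent. Every substitution must have at least one finite value.
    """

    def __init__(self, table: pd.DataFrame):
        missing_cols = [c for c in DDG_COLUMNS if c not in table.columns]
        if missing_cols:
            raise VariantTableError(f"ΔΔG table missing columns: {missing_cols}")
        table = table[DDG_COLUMNS].copy()
        table["position"] = table["position"].astype(int)
        table["ddg_kcal_mol"] = pd.to_numeric(table["ddg_kcal_mol"])
        table = table.dropna(subset=["ddg_kcal_mol"]).reset_index(drop=True)
        if not np.all(np.isfinite(table["ddg_kcal_mol"].to_numpy())):
            raise VariantTableError("ΔΔG values must be finite")
        dup = table.duplicated(subset=DDG_COLUMNS[:5])
        if dup.any():
            raise VariantTableError(
                f"duplicate (substitution, conformer) rows at {list(table.index[dup])}"
            )
        if table.empty:
            raise VariantTableError("ΔΔG table has no non-missing values")
        self._table = table

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def sas_keys(self) -> list[SasKey]:
        seen: dict[SasKey, None] = {}
        for row in self._table.itertuples(index=False):
            seen.setdefault((row.protein_id, row.position, row.wt_aa, row.mut_aa))
        return list(seen)

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self._table["protein_id"]))

    def conformers_for(self, protein_id: str) -> list[str]:
        sub = self._table[self._table["protein_id"] == protein_id]
        return list(dict.fromkeys(sub["conformer_id"]))

    def row(self, key: SasKey) -> dict[str, float]:
        """Non-missing conformer values for one substitution."""
        t = self._table
        mask = (
            (t["protein_id"] == key[0])
            & (t["position"] == key[1])
            & (t["wt_aa"] == key[2])
            & (t["mut_aa"] == key[3])
        )
        sub = t[mask]
        if sub.empty:
            raise KeyError(key)
        return dict(zip(sub["conformer_id"], sub["ddg_kcal_mol"]))

    def rows(self) -> Iterable[tuple[SasKey, dict[str, float]]]:
        for key, sub in self._table.groupby(
            ["protein_id", "position", "wt_aa", "mut_aa"], sort=False
        ):
            yield tuple(key), dict(zip(sub["conformer_id"], sub["ddg_kcal_mol"]))

    def protein_block(self, protein_id: str) -> pd.DataFrame:
        """Wide (substitution x conformer) frame for one protein; NaN = missing."""
        sub = self._table[self._table["protein_id"] == protein_id]
        if sub.empty:
            raise KeyError(protein_id)
        wide = sub.pivot_table(
            index=["protein_id", "position", "wt_aa", "mut_aa"],
            columns="conformer_id",
            values="ddg_kcal_mol",
            sort=False,
            aggfunc="first",
        )
        return wide[self.conformers_for(protein_id)]

    def __len__(self) -> int:
        return len(self._table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DdgMatrix):
            return NotImplemented
        return self._table.equals(other._table)


def read_sas_table(path) -> list[SasRecord]:
    """Read a TSV of substitutions with header protein_id/position/wt_aa/mut_aa/label.

    Labels are normalized case-insensitively ("Disease" -> disease,
    "Polymorphism" -> neutral); anything else is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAS_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"substitution table missing columns: {missing}")
    records: list[SasRecord] = []
    seen: set[SasKey] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw_label = str(row.label).strip().lower()
        if raw_label not in LABEL_ALIASES:
            raise VariantTableError(f"line {i}: unknown label {row.label!r}")
        rec = SasRecord(
            protein_id=str(row.protein_id).strip(),
            position=int(row.position),
            wt_aa=str(row.wt_aa).strip().upper(),
            mut_aa=str(row.mut_aa).strip().upper(),
            label=LABEL_ALIASES[raw_label],
        )
        if rec.key in seen:
            raise VariantTableError(
                f"line {i}: duplicate substitution {rec.key}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def write_sas_table(records: Iterable[SasRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=SAS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_ddg_table(path, ensemble_conformers: Optional[dict[str, list[str]]] = None) -> DdgMatrix:
    """Read a long-form ΔΔG TSV; the literal ``NA`` marks a missing cell.

    If ``ensemble_conformers`` maps protein ids to known conformer ids,
    rows referencing unknown conformers are kept but logged as warnings.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "conformer_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    missing = [c for c in DDG_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"ΔΔG table missing columns: {missing}")
    try:
        df["ddg_kcal_mol"] = pd.to_numeric(df["ddg_kcal_mol"])
    except (ValueError, TypeError) as exc:
        raise VariantTableError(f"non-numeric ΔΔG value: {exc}") from exc
    present = df.dropna(subset=["ddg_kcal_mol"])
    all_keys = set(map(tuple, df[DDG_COLUMNS[:4]].itertuples(index=False)))
    with_values = set(map(tuple, present[DDG_COLUMNS[:4]].itertuples(index=False)))
    orphans = all_keys - with_values
    if orphans:
        raise VariantTableError(
            f"substitutions with zero conformer values: {sorted(orphans)[:5]}"
        )
    if ensemble_conformers is not None:
        for row in present.itertuples(index=False):
            known = ensemble_conformers.get(row.protein_id)
            if known is not None and row.conformer_id not in known:
                logger.warning(
                    "conformer %s not in ensemble of %s; row kept",
                    row.conformer_id, row.protein_id,
                )
    return DdgMatrix(present)


def write_ddg_table(matrix: DdgMatrix, path) -> None:
    matrix.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_humsavar(path) -> list[SasRecord]:
    """Convenience reader for the fixed-width human-variant list dialect.

    Expects data lines of the form
    ``GENE  ACCESSION  FTID  p.Trp24Cys  Disease|Polymorphism ...``;
    unclassified rows are skipped.
    """
    records = []
    seen: set[SasKey] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5 or not parts[3].startswith("p."):
                continue
            change = parts[3][2:]
            wt3, pos, mut3 = change[:3].upper(), change[3:-3], change[-3:].upper()
            if wt3 not in THREE_TO_ONE or mut3 not in THREE_TO_ONE or not pos.isdigit():
                continue
            raw_label = parts[4].strip().lower()
            if raw_label not in LABEL_ALIASES:
                continue
            rec = SasRecord(
                protein_id=parts[1],
                position=int(pos),
                wt_aa=THREE_TO_ONE[wt3],
                mut_aa=THREE_TO_ONE[mut3],
                label=LABEL_ALIASES[raw_label],
            )
            if rec.key not in seen:
                seen.add(rec.key)
                records.append(rec)
    return records


# ---------------------------------------------------------------------------
# External stability-engine adapter


@dataclass
class EngineResult:
    value: Optional[float]  # kcal/mol; None when the engine failed
    provenance: dict


def run_external_engine(
    command_template: str,
    structure_path: str,
    sas: SasRecord,
    engine_name: str = "external",
) -> EngineResult:
    """Invoke an external ΔΔG engine and capture one numeric value.

    The template may reference ``{structure}``, ``{position}``, ``{wt}`` and
    ``{mut}``. The value is passed through untouched; a nonzero exit or
    unparsable output yields a missing cell plus a log entry.
    """
    command = command_template.format(
        structure=structure_path, position=sas.position, wt=sas.wt_aa, mut=sas.mut_aa
    )
    provenance = {
        "engine": engine_name,
        "command_template": command_template,
        "structure": structure_path,
        "sas": list(sas.key),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    try:
        proc = subprocess.run(
            shlex.split(command), capture_output=True, text=True, check=False
        )
    except OSError as exc:
        logger.warning("engine invocation failed for %s: %s", sas.key, exc)
        provenance["error"] = str(exc)
        return EngineResult(None, provenance)
    if proc.returncode != 0:
        logger.warning(
            "engine exited %d for %s; cell marked missing", proc.returncode, sas.key
        )
        provenance["error"] = f"exit status {proc.returncode}"
        return EngineResult(None, provenance)
    try:
        value = float(proc.stdout.strip().split()[-1])
    except (ValueError, IndexError):
        logger.warning(
            "unparsable engine output %r for %s; cell marked missing",
            proc.stdout.strip(), sas.key,
        )
        provenance["error"] = "unparsable output"
        return EngineResult(None, provenance)
    return EngineResult(value, provenance)


def write_provenance(results: Iterable[EngineResult], path) -> None:
    payload = {
        "n_cells": 0,
        "n_missing": 0,
        "runs": [],
    }
    for res in results:
        payload["n_cells"] += 1
        if res.value is None:
            payload["n_missing"] += 1
        payload["runs"].append({"value": res.value, **res.provenance})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
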