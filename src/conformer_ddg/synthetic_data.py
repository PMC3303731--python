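"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator draws a hierarchical model: each protein gets a conformer
count from a shifted, truncated negative binomial (mean ~8.6, range 2-73);
each substitution gets a class label (disease fraction ~0.60) and a base
ΔΔG from its class model; each (substitution, conformer) cell adds a
conformer-level Gaussian deviation. Defaults are calibrated so the
class-conditional means of the per-substitution minimum and maximum ΔΔG
land near 1.47 / 4.63 kcal/mol (disease) and 0.38 / 1.86 kcal/mol
(neutral) at the 119-protein scale.

Also writes toy multi-conformer PDB fixtures whose pairwise C-alpha RMSD
is known in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .variant_io import AMINO_ACIDS, DdgMatrix, SasRecord


@dataclass(frozen=True)
class EffectModel:
    """Class-conditional model of the substitution-level base ΔΔG.

    A two-component Gaussian mixture: with probability ``1 - stab_weight``
    draw from Normal(loc, scale); otherwise from the minority stabilizing
    component Normal(stab_loc, stab_scale).
    """

    loc: float
    scale: float
    stab_weight: float = 0.0
    stab_loc: float = 0.0
    stab_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale < 0 or self.stab_scale < 0:
            raise ValueError("scales must be nonnegative")
        if not 0.0 <= self.stab_weight <= 1.0:
            raise ValueError("stab_weight must lie in [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        base = rng.normal(self.loc, self.scale, size=n)
        if self.stab_weight > 0:
            minority = rng.normal(self.stab_loc, self.stab_scale, size=n)
            pick = rng.random(n) < self.stab_weight
            base = np.where(pick, minority, base)
        return base


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dataset generator; seed fixes everything."""

    n_proteins: int = 119
    conformer_mean: float = 8.6
    conformer_min: int = 2
    conformer_max: int = 73
    conformer_dispersion: float = 1.2  # negative-binomial shape r
    sas_mean: float = 6.75  # target total ~803 at 119 proteins
    disease_fraction: float = 0.60
    disease_effect: EffectModel = field(
        default_factory=lambda: EffectModel(
            loc=2.815, scale=2.4, stab_weight=0.05, stab_loc=-2.5, stab_scale=1.0
        )
    )
    neutral_effect: EffectModel = field(
        default_factory=lambda: EffectModel(loc=0.93, scale=1.8)
    )
    disease_conformer_sigma: float = 1.339
    neutral_conformer_sigma: float = 0.627
    #: gamma shape of the standardized conformer deviation; values near 1 give
    #: a right skew (a few conformers report much larger ΔΔG), which is what
    #: makes the per-substitution maximum informative.
    conformer_skew_shape: float = 1.0
    missing_rate: float = 0.0
    bound_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.disease_fraction <= 1.0:
            raise ValueError("disease_fraction must lie in [0, 1]")
        if self.disease_conformer_sigma < 0 or self.neutral_conformer_sigma < 0:
            raise ValueError("conformer sigmas must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not self.conformer_min >= 1:
            raise ValueError("conformer_min must be >= 1")

    def scaled_sigma(self, factor: float) -> "GeneratorConfig":
        """Copy with both conformer-level sigmas multiplied by ``factor``."""
        d = asdict(self)
        d["disease_effect"] = self.disease_effect
        d["neutral_effect"] = self.neutral_effect
        d["disease_conformer_sigma"] *= factor
        d["neutral_conformer_sigma"] *= factor
        return GeneratorConfig(**d)


@dataclass
class SyntheticDataset:
    conformer_table: pd.DataFrame  # protein_id, conformer_id, bound
    sas_records: list[SasRecord]
    ddg: DdgMatrix
    bound_flags: dict[str, bool]  # conformer_id -> bound
    config: GeneratorConfig


def _skewed_deviations(rng: np.random.Generator, shape: float, n: int) -> np.ndarray:
    """Mean-zero, unit-variance, right-skewed conformer deviations.

    Standardized gamma draws: skewness 2/sqrt(shape). Degenerate (all-zero)
    when the caller multiplies by a zero sigma.
    """
    if shape <= 0:
        raise ValueError("conformer_skew_shape must be positive")
    return (rng.gamma(shape, 1.0, size=n) - shape) / math.sqrt(shape)


def _draw_conformer_counts(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    """Shifted negative binomial truncated to [conformer_min, conformer_max]."""
    r = config.conformer_dispersion
    mean_excess = config.conformer_mean - config.conformer_min
    p = r / (r + mean_excess)
    counts = config.conformer_min + rng.negative_binomial(r, p, size=config.n_proteins)
    # resample the rare overflow rather than clipping, to keep the tail shape
    for _ in range(100):
        over = counts > config.conformer_max
        if not over.any():
            break
        counts[over] = config.conformer_min + rng.negative_binomial(r, p, size=int(over.sum()))
    return np.minimum(counts, config.conformer_max)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset from ``config``.

    Reruns with an identical config (including the seed) are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    aa = sorted(AMINO_ACIDS)
    counts = _draw_conformer_counts(rng, config)
    conformer_rows = []
    ddg_rows = []
    sas_records: list[SasRecord] = []
    bound_flags: dict[str, bool] = {}
    for i in range(config.n_proteins):
        protein_id = f"SYN{i:04d}"
        conformer_ids = [f"{protein_id}_c{j:02d}" for j in range(counts[i])]
        for cid in conformer_ids:
            bound = bool(rng.random() < config.bound_fraction)
            bound_flags[cid] = bound
            conformer_rows.append(
                {"protein_id": protein_id, "conformer_id": cid, "bound": bound}
            )
        n_sas = 1 + rng.poisson(max(config.sas_mean - 1.0, 0.0))
        positions = rng.choice(np.arange(1, 10 * n_sas + 2), size=n_sas, replace=False)
        is_disease = rng.random(n_sas) < config.disease_fraction
        for s in range(n_sas):
            wt, mut = rng.choice(aa, size=2, replace=False)
            label = "disease" if is_disease[s] else "neutral"
            rec = SasRecord(
                protein_id=protein_id,
                position=int(positions[s]),
                wt_aa=str(wt),
                mut_aa=str(mut),
                label=label,
            )
            sas_records.append(rec)
            model = config.disease_effect if is_disease[s] else config.neutral_effect
            sigma = (
                config.disease_conformer_sigma
                if is_disease[s]
                else config.neutral_conformer_sigma
            )
            base = float(model.sample(rng, 1)[0])
            values = base + sigma * _skewed_deviations(
                rng, config.conformer_skew_shape, len(conformer_ids)
            )
            missing = rng.random(len(conformer_ids)) < config.missing_rate
            if missing.all():
                missing[rng.integers(len(conformer_ids))] = False  # keep >= 1 value
            for cid, value, drop in zip(conformer_ids, values, missing):
                if drop:
                    continue
                ddg_rows.append(
                    {
                        "protein_id": protein_id,
                        "position": rec.position,
                        "wt_aa": rec.wt_aa,
                        "mut_aa": rec.mut_aa,
                        "conformer_id": cid,
                        "ddg_kcal_mol": round(float(value), 6),
                    }
                )
    return SyntheticDataset(
        conformer_table=pd.DataFrame(conformer_rows),
        sas_records=sas_records,
        ddg=DdgMatrix(pd.DataFrame(ddg_rows)),
        bound_flags=bound_flags,
        config=config,
    )


# ---------------------------------------------------------------------------
# Toy structure fixtures


_BACKBONE_OFFSETS = {
    # idealized local geometry relative to each residue's C-alpha, Angstrom
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
    "CB": np.array([0.0, -1.53, 0.0]),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_CA_SPACING = 3.8

#: period-4 displacement sign pattern; each block of 4 consecutive residues
#: is balanced both in sum and in first moment along the chain axis, so the
#: optimal superposition of a displaced copy onto the base stays the identity.
_SIGN_PATTERN = (1.0, -1.0, -1.0, 1.0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _pdb_atom_line(serial: int, name: str, resseq: int, coords: np.ndarray,
                   element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field} ALA A{resseq:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def generate_toy_structures(
    out_dir,
    n_conformers: int,
    n_residues: int,
    displacement: float,
    seed: int = 0,
    apply_rigid_motion: bool = True,
) -> tuple[list[Path], np.ndarray]:
    """Write poly-alanine conformer PDB files with known pairwise RMSD.

    Conformer ``k`` displaces each C-alpha along z by
    ``displacement * k / (n_conformers - 1)`` times the balanced +--+ sign
    pattern, then (optionally) applies a random rigid motion. When
    ``n_residues`` is a multiple of 4 the expected Kabsch RMSD between
    conformers j and k is ``displacement * |s_j - s_k|``; the expected
    matrix is returned and saved next to the files as JSON.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    if displacement < 0:
        raise ValueError("displacement must be nonnegative")
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    signs = np.array(
        [_SIGN_PATTERN[i % 4] for i in range(n_residues)]
    )
    scales = (
        np.linspace(0.0, 1.0, n_conformers) if n_conformers > 1 else np.zeros(1)
    )
    expected = displacement * np.abs(scales[:, None] - scales[None, :])
    paths = []
    for k in range(n_conformers):
        lines = []
        serial = 1
        for r in range(n_residues):
            ca = np.array([r * _CA_SPACING, 0.0, 0.0])
            dz = np.array([0.0, 0.0, displacement * scales[k] * signs[r]])
            for name in ("N", "CA", "C", "O", "CB"):
                coords = ca + _BACKBONE_OFFSETS[name] + dz
                lines.append(
                    _pdb_atom_line(serial, name, r + 1, coords, _ELEMENT[name])
                )
                serial += 1
        if apply_rigid_motion and k > 0:
            rot = _random_rotation(rng)
            trans = rng.uniform(-20, 20, size=3)
            moved = []
            for line in lines:
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                new = rot @ xyz + trans
                moved.append(
                    line[:30]
                    + f"{new[0]:8.3f}{new[1]:8.3f}{new[2]:8.3f}"
                    + line[54:]
                )
            lines = moved
        path = out_dir / f"toy_conf{k:02d}.pdb"
        path.write_text("".join(lines) + "END\n")
        paths.append(path)
    with open(out_dir / "expected_rmsd.json", "w") as fh:
        json.dump(
            {
                "n_conformers": n_conformers,
                "n_residues": n_residues,
                "displacement": displacement,
                "exact": n_residues % 4 == 0,
                "expected_rmsd": expected.tolist(),
            },
            fh,
            indent=2,
        )
    return paths, expected
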