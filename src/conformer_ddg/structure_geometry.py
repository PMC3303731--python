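"""Multi-conformer structure parsing and geometric descriptors.

Parses single- and multi-model PDB files, superposes conformer pairs with
the Kabsch algorithm on commonly resolved C-alpha positions, and computes
per-residue solvent-accessible surface area (ASA) with a deterministic
Shrake-Rupley sphere sampling. Derived descriptors: maximum pairwise RMSD
over an ensemble, exposure classes (buried/exposed at 20 A^2) and the
per-position spread of ASA across conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Conformer",
    "ConformerEnsemble",
    "EnsembleGeometry",
    "PdbParseError",
    "VDW_RADII",
    "EXPOSURE_THRESHOLD",
    "parse_pdb_conformer",
    "parse_pdb_conformers",
    "kabsch_rmsd",
    "ensemble_rmsd",
    "shrake_rupley_asa",
    "classify_exposure",
    "delta_asa_max",
]

#: van der Waals radii in Angstrom for the elements that dominate
#: heavy-atom protein structures; unknown elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

#: Buried/exposed ASA boundary in A^2; the boundary itself counts as exposed.
EXPOSURE_THRESHOLD = 20.0

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class PdbParseError(ValueError):
    """Raised for malformed or unusable PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with everything ASA and RMSD need."""

    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float
    vdw_radius: float
    residue_index: int
    atom_name: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class Conformer:
    """One structure of a protein: the atoms of a single chain.

    ``bound`` is an externally supplied ligand flag; parsing never sets it.
    """

    conformer_id: str
    atoms: list[AtomRecord]
    bound: Optional[bool] = None
    _resolved: set[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        resolved = {a.residue_index for a in self.atoms if a.atom_name == "CA"}
        if not resolved:
            raise ValueError(f"conformer {self.conformer_id!r} has no CA atoms")
        self._resolved = resolved

    @property
    def resolved_positions(self) -> set[int]:
        return set(self._resolved)

    def ca_coords(self, positions: Sequence[int]) -> np.ndarray:
        """C-alpha coordinates at ``positions`` as an (N, 3) array."""
        ca = {a.residue_index: a.coords for a in self.atoms if a.atom_name == "CA"}
        return np.array([ca[p] for p in positions])


@dataclass
class ConformerEnsemble:
    protein_id: str
    conformers: list[Conformer]
    sequence_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble needs at least one conformer")
        if self.sequence_length is None:
            self.sequence_length = max(
                max(c.resolved_positions) for c in self.conformers
            )
        ids = [c.conformer_id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate conformer ids in {self.protein_id}: {ids}")

    @property
    def conformer_ids(self) -> list[str]:
        return [c.conformer_id for c in self.conformers]


@dataclass
class EnsembleGeometry:
    """RMSD matrix plus per-conformer, per-residue ASA for one ensemble."""

    protein_id: str
    conformer_ids: list[str]
    rmsd_matrix: np.ndarray  # symmetric, zero diagonal, Angstrom
    asa: dict[str, dict[int, float]]  # conformer_id -> {position: ASA A^2}

    @property
    def rmsd_max(self) -> float:
        n = len(self.conformer_ids)
        if n < 2:
            raise ValueError("RMSDmax undefined for one conformer")
        iu = np.triu_indices(n, k=1)
        return float(self.rmsd_matrix[iu].max())

    def delta_asa_max(self, position: int) -> float:
        return delta_asa_max(self.asa, position)

    def positions_with_delta(self) -> dict[int, float]:
        """ΔASA_max for every position resolved in >= 2 conformers."""
        counts: dict[int, int] = {}
        for per_res in self.asa.values():
            for pos in per_res:
                counts[pos] = counts.get(pos, 0) + 1
        return {
            pos: delta_asa_max(self.asa, pos)
            for pos, n in sorted(counts.items())
            if n >= 2
        }


# ---------------------------------------------------------------------------
# PDB parsing


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper()
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        # Element column absent in some legacy files; infer from the atom name.
        element = next((ch for ch in name if ch.isalpha()), "C").upper()
    return {
        "name": name,
        "altloc": altloc,
        "resname": resname,
        "chain": chain,
        "resseq": resseq,
        "coords": (x, y, z),
        "occupancy": occupancy,
        "element": element,
    }


def _build_conformer(raw_atoms: list[dict], chain: str, conformer_id: str,
                     seen_chains: set[str]) -> Conformer:
    selected = [a for a in raw_atoms if a["chain"] == chain]
    if not selected:
        raise PdbParseError(
            f"chain {chain!r} not found; available chains: "
            + ", ".join(sorted(seen_chains))
        )
    # Alternate locations: highest occupancy wins, ties go to the
    # lexicographically first altloc identifier.
    best: dict[tuple[int, str], dict] = {}
    for a in selected:
        key = (a["resseq"], a["name"])
        cur = best.get(key)
        if cur is None or (a["occupancy"], _altloc_rank(a["altloc"])) > (
            cur["occupancy"], _altloc_rank(cur["altloc"])
        ):
            best[key] = a
    atoms = []
    for a in best.values():
        if a["element"] == "H" or a["element"] == "D":
            continue  # hydrogens excluded from the ASA atom set
        atoms.append(
            AtomRecord(
                element=a["element"],
                coords=np.array(a["coords"], dtype=float),
                occupancy=min(max(a["occupancy"], 0.0), 1.0),
                vdw_radius=VDW_RADII.get(a["element"], DEFAULT_VDW_RADIUS),
                residue_index=a["resseq"],
                atom_name=a["name"],
            )
        )
    atoms.sort(key=lambda at: (at.residue_index, at.atom_name))
    if not any(a.atom_name == "CA" for a in atoms):
        raise PdbParseError(f"no CA atoms found in chain {chain!r}")
    return Conformer(conformer_id=conformer_id, atoms=atoms)


def _altloc_rank(altloc: str) -> float:
    # Empty altloc ranks above 'A'; among letters, 'A' beats 'B', so rank
    # by negative ordinal for max() comparisons.
    return 1.0 if not altloc else -ord(altloc)


def parse_pdb_conformers(path, chain: Optional[str] = None) -> list[Conformer]:
    """Parse a PDB file into one conformer per MODEL (or a single one).

    Waters and HETATM ligands are excluded; alternate locations are reduced
    to the highest-occupancy copy; the ``bound`` flag is left unset.
    """
    models: list[list[dict]] = []
    current: list[dict] = []
    seen_chains: set[str] = set()
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model and current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec == "ATOM":
                atom = _parse_atom_line(line, lineno)
                seen_chains.add(atom["chain"])
                if atom["resname"] not in WATER_RESNAMES:
                    current.append(atom)
            elif rec == "HETATM":
                # ligands and waters are excluded from the ASA atom set
                continue
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PdbParseError(f"no ATOM records found in {path}")
    if chain is None:
        chain = min(seen_chains)
    stem = _file_stem(path)
    out = []
    for i, raw in enumerate(models):
        cid = stem if len(models) == 1 else f"{stem}_model{i + 1}"
        out.append(_build_conformer(raw, chain, cid, seen_chains))
    return out


def parse_pdb_conformer(path, chain: Optional[str] = None) -> Conformer:
    """Parse a single-conformer PDB file (first model if several)."""
    return parse_pdb_conformers(path, chain)[0]


def _file_stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD between two matched point sets over rigid motions.

    Centers both sets, finds the optimal proper rotation via SVD of the
    cross-covariance matrix, and returns the residual RMSD in the units of
    the input coordinates.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected (N, 3) coordinate arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    cov = ac.T @ bc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    # Residual sum of squares via the singular values: avoids building the
    # rotation matrix and is numerically tidy near zero.
    e0 = (ac ** 2).sum() + (bc ** 2).sum()
    rss = e0 - 2.0 * (s[0] + s[1] + d * s[2])
    return math.sqrt(max(rss, 0.0) / n)


def ensemble_rmsd(ensemble: ConformerEnsemble) -> tuple[np.ndarray, float]:
    """All-vs-all C-alpha RMSD over a conformer ensemble.

    Each pair is superposed on the intersection of its resolved positions.
    Returns the symmetric RMSD matrix and its maximum off-diagonal entry.
    """
    confs = ensemble.conformers
    n = len(confs)
    if n < 2:
        raise ValueError("RMSDmax undefined for one conformer")
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(confs[i].resolved_positions & confs[j].resolved_positions)
            if len(shared) < 3:
                raise ValueError(
                    f"conformers {confs[i].conformer_id!r} and "
                    f"{confs[j].conformer_id!r} share only {len(shared)} "
                    "resolved positions (need >= 3)"
                )
            r = kabsch_rmsd(confs[i].ca_coords(shared), confs[j].ca_coords(shared))
            matrix[i, j] = matrix[j, i] = r
    iu = np.triu_indices(n, k=1)
    return matrix, float(matrix[iu].max())


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent accessibility


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_asa(
    conformer: Conformer,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[int, float]:
    """Per-residue solvent-accessible surface area in A^2.

    Each atom's expanded sphere (vdW + probe) is sampled with a golden-spiral
    lattice of ``n_points``; a sample point is accessible if it lies outside
    every neighboring expanded sphere. Deterministic for a fixed point count.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    atoms = conformer.atoms
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    sphere = _golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_residue: dict[int, float] = {}
    for idx, atom in enumerate(atoms):
        r = radii[idx]
        pts = coords[idx] + r * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[idx], r + max_r) if j != idx
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        area = accessible.sum() / n_points * 4.0 * math.pi * r * r
        per_residue[atom.residue_index] = per_residue.get(atom.residue_index, 0.0) + area
    return per_residue


def classify_exposure(asa: float) -> str:
    """Classify a residue ASA as ``"buried"`` (< 20 A^2) or ``"exposed"``."""
    if asa < 0:
        raise ValueError("ASA cannot be negative")
    return "buried" if asa < EXPOSURE_THRESHOLD else "exposed"


def delta_asa_max(
    ensemble_asa: Mapping[str, Mapping[int, float]], position: int
) -> float:
    """Max minus min ASA at ``position`` over conformers resolving it."""
    values = [
        per_res[position]
        for per_res in ensemble_asa.values()
        if position in per_res
    ]
    if len(values) < 2:
        raise ValueError(
            f"position {position} resolved in {len(values)} conformer(s); "
            "ΔASA undefined"
        )
    return max(values) - min(values)


def compute_ensemble_geometry(
    ensemble: ConformerEnsemble,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> EnsembleGeometry:
    """RMSD matrix and per-conformer ASA for one ensemble."""
    if len(ensemble.conformers) >= 2:
        matrix, _ = ensemble_rmsd(ensemble)
    else:
        matrix = np.zeros((1, 1))
    asa = {
        c.conformer_id: shrake_rupley_asa(c, probe_radius, n_points)
        for c in ensemble.conformers
    }
    return EnsembleGeometry(
        protein_id=ensemble.protein_id,
        conformer_ids=ensemble.conformer_ids,
        rmsd_matrix=matrix,
        asa=asa,
    )
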