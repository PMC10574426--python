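"""Docking-output post-processing: best poses, affinity classes, summaries.

AutoDock-Vina-style runs produce several poses per receptor-ligand pair,
each with a binding affinity in kcal/mol (more negative = stronger
predicted binding). This module reduces pose tables to a
ligand x receptor matrix of best (lowest) affinities, classifies
affinities into none / moderate / strong, and extracts the best complex
per receptor plus the global best pair.

Classification thresholds follow the common docking convention: values
above -5 kcal/mol mean no predicted binding, values down to -7 mean
moderate binding and values below -7 mean strong binding. The boundary
values -5 and -7 are assigned to the stronger class.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import ranksums

NO_BINDING_MAX = -5.0  # affinities above this: no predicted binding
STRONG_MAX = -7.0      # affinities at/below this: strong predicted binding


@dataclass(frozen=True)
class DockingPose:
    """One docked conformation of a ligand against a receptor."""

    ligand: str
    receptor: str
    pose_index: int
    affinity: float  # kcal/mol

    def __post_init__(self) -> None:
        if not math.isfinite(self.affinity):
            raise ValueError(
                f"non-finite affinity for {self.ligand!r}/{self.receptor!r}"
            )


class BestComplex(NamedTuple):
    receptor: str
    ligand: str
    affinity: float


def best_pose(poses: Iterable[DockingPose]) -> pd.DataFrame:
    """Ligand x receptor matrix of the minimum affinity over each pair's poses.

    Cells for pairs that were never docked are NaN.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("no docking poses provided")
    df = pd.DataFrame(
        {
            "ligand": [p.ligand for p in poses],
            "receptor": [p.receptor for p in poses],
            "affinity": [p.affinity for p in poses],
        }
    )
    matrix = df.pivot_table(
        index="ligand", columns="receptor", values="affinity", aggfunc="min"
    )
    return matrix.sort_index(axis=0).sort_index(axis=1)


def classify_affinity(affinity: float) -> str:
    """Map an affinity (kcal/mol) to ``none`` / ``moderate`` / ``strong``.

    Monotone in strength: lower (more negative) affinity never yields a
    weaker class. Boundaries: exactly -5 is moderate, exactly -7 strong.
    """
    if not math.isfinite(affinity):
        raise ValueError(f"affinity must be finite, got {affinity!r}")
    if affinity <= STRONG_MAX:
        return "strong"
    if affinity <= NO_BINDING_MAX:
        return "moderate"
    return "none"


def best_complex_table(matrix: pd.DataFrame) -> tuple[list[BestComplex], BestComplex]:
    """Best (lowest-affinity) ligand per receptor, plus the global best cell.

    Ties are broken by lexicographically smaller ligand id. Returns
    ``(per_receptor, global_best)``.
    """
    if matrix.size == 0 or matrix.isna().all().all():
        raise ValueError("affinity matrix is empty")
    per_receptor: list[BestComplex] = []
    for receptor in matrix.columns:
        col = matrix[receptor].dropna()
        if col.empty:
            continue
        best_aff = col.min()
        ligand = min(col.index[col == best_aff])
        per_receptor.append(BestComplex(str(receptor), str(ligand), float(best_aff)))
    global_best = min(per_receptor, key=lambda c: (c.affinity, c.ligand, c.receptor))
    return per_receptor, global_best


def receptor_affinity_test(
    matrix: pd.DataFrame, receptors: Iterable[str]
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of a receptor group's affinities vs the rest.

    One possible reading of a "group X binds significantly better"
    claim: pool the best affinities of the named receptors across
    ligands and compare them against the pooled affinities of all other
    receptors with a two-sided rank-sum test. Returns ``(statistic,
    p_value)``.
    """
    receptors = set(receptors)
    in_group = matrix[[c for c in matrix.columns if c in receptors]].to_numpy().ravel()
    out_group = matrix[[c for c in matrix.columns if c not in receptors]].to_numpy().ravel()
    in_group = in_group[~np.isnan(in_group)]
    out_group = out_group[~np.isnan(out_group)]
    if in_group.size == 0 or out_group.size == 0:
        raise ValueError("both receptor groups must be nonempty")
    stat, p = ranksums(in_group, out_group)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# parsing

_VINA_RESULT_RE = re.compile(r"^REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)")
_VINA_TABLE_RE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+[\d.]+\s+[\d.]+\s*$")


def parse_vina_output(
    text: str, ligand: str, receptor: str
) -> list[DockingPose]:
    """Parse poses from AutoDock Vina output.

    Accepts either a Vina log (the ``mode | affinity | rmsd`` table) or a
    docked PDBQT (``REMARK VINA RESULT:`` lines); the dialect is
    auto-detected from the content.
    """
    poses: list[DockingPose] = []
    if "REMARK VINA RESULT" in text:
        idx = 0
        for line in text.splitlines():
            m = _VINA_RESULT_RE.match(line.strip())
            if m:
                idx += 1
                poses.append(DockingPose(ligand, receptor, idx, float(m.group(1))))
    else:
        for line in text.splitlines():
            m = _VINA_TABLE_RE.match(line)
            if m:
                poses.append(
                    DockingPose(ligand, receptor, int(m.group(1)), float(m.group(2)))
                )
    if not poses:
        raise ValueError(
            f"no Vina poses found for {ligand!r}/{receptor!r}; "
            "expected a log table or REMARK VINA RESULT lines"
        )
    return poses


def read_pose_table(path: Union[str, Path]) -> list[DockingPose]:
    """Read a generic pose TSV with columns ligand, receptor, pose, affinity."""
    df = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor", "affinity"}
    if not required <= set(df.columns):
        raise ValueError(
            f"pose table {path} must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    if "pose" not in df.columns:
        df["pose"] = 1
    return [
        DockingPose(str(r.ligand), str(r.receptor), int(r.pose), float(r.affinity))
        for r in df.itertuples(index=False)
    ]
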