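"""Molecular-dynamics post-processing: trajectory statistics and MM/PBSA sums.

This module consumes the tabular outputs of an MD + MM/PBSA workflow —
RMSD and SASA time series (two-column XVG files) and per-complex energy
component tables — and computes:

* plateau summary statistics (mean +/- sample standard deviation after a
  chosen equilibration time);
* a sliding-window stability call: a trajectory is stable once every
  window of a given length (default 5 ns) to the end of the run has a
  value range (max - min) below a threshold (default 0.2 nm for RMSD);
* MM/PBSA bookkeeping: MM = VDW + COU, dH = MM + PB + SA and
  dG = dH + (-T dS), with a validation mode that checks supplied totals
  against the recomputed sums to a rounding tolerance;
* per-residue decomposition fractions, unit-aware (kJ/mol inputs are
  converted to kcal/mol with the factor 4.184).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np

KJ_PER_KCAL = 4.184

STABILITY_THRESHOLD_NM = 0.2
STABILITY_WINDOW_NS = 5.0
#: tolerance (kcal/mol) for validating pre-rounded printed totals
ROUNDING_TOL = 0.011


@dataclass
class TrajectorySeries:
    """A time series from an MD run (RMSD in nm, SASA in nm^2, ...)."""

    times: np.ndarray  # ns, strictly increasing
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("negative time values")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("series values must be nonnegative")


class StabilityCall(NamedTuple):
    stable: bool
    equilibration_time: Optional[float]  # ns


def summarize_series(s: TrajectorySeries, from_time: float = 0.0) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of values at time >= from_time."""
    mask = s.times >= from_time
    vals = s.values[mask]
    if vals.size < 2:
        raise ValueError(
            f"need at least 2 samples at/after t={from_time} ns, found {vals.size}"
        )
    return float(vals.mean()), float(vals.std(ddof=1))


def stability_assess(
    s: TrajectorySeries,
    threshold: float = STABILITY_THRESHOLD_NM,
    window: float = STABILITY_WINDOW_NS,
) -> StabilityCall:
    """Sliding-window stability call on a trajectory series.

    The equilibration time is the earliest sample time ``t`` such that
    every window ``[tau, tau + window]`` with ``tau >= t`` fully inside
    the series has value range (max - min) strictly below ``threshold``,
    and at least one full window fits after ``t``. The series is stable
    when such a ``t`` exists.
    """
    if threshold <= 0 or window <= 0:
        raise ValueError("threshold and window must be positive")
    t, v = s.times, s.values
    span = t[-1] - t[0] if t.size else 0.0
    if span < window:
        raise ValueError(
            f"series spans {span:g} ns, shorter than the {window:g} ns window"
        )
    n = t.size
    # window starting at each sample i, covering samples with time <= t[i]+window
    ends = np.searchsorted(t, t + window, side="right")
    last_start = int(np.searchsorted(t, t[-1] - window, side="right")) - 1
    # a start index is "good" when its window's range is below threshold
    good = np.ones(last_start + 1, dtype=bool)
    for i in range(last_start + 1):
        w = v[i : ends[i]]
        good[i] = (w.max() - w.min()) < threshold
    bad = np.flatnonzero(~good)
    first_ok = 0 if bad.size == 0 else int(bad[-1]) + 1
    if first_ok > last_start:
        return StabilityCall(stable=False, equilibration_time=None)
    return StabilityCall(stable=True, equilibration_time=float(t[first_ok]))


def read_xvg(
    path: Union[str, Path], label: str = "", time_unit: str = "ns"
) -> TrajectorySeries:
    """Read a two-column XVG-dialect file, skipping ``#`` and ``@`` header lines.

    ``time_unit`` may be ``ns`` or ``ps``; ps times are converted to ns.
    """
    if time_unit not in ("ns", "ps"):
        raise ValueError(f"time_unit must be 'ns' or 'ps', got {time_unit!r}")
    data = np.loadtxt(path, comments=("#", "@"))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    times = data[:, 0] / (1000.0 if time_unit == "ps" else 1.0)
    return TrajectorySeries(times=times, values=data[:, 1], label=label or str(path))


def write_xvg(path: Union[str, Path], s: TrajectorySeries, comment: str = "") -> None:
    """Write a series in the two-column XVG dialect read by :func:`read_xvg`."""
    with open(path, "w") as fh:
        fh.write(f"# {comment or s.label}\n")
        fh.write('@    xaxis  label "Time (ns)"\n')
        for t, v in zip(s.times, s.values):
            fh.write(f"{t:.6f}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# MM/PBSA bookkeeping


@dataclass
class EnergyComponents:
    """MM/PBSA energy components for one complex, in kcal/mol.

    Base components: van der Waals (``vdw``), Coulomb (``cou``), polar
    solvation (``pb``), nonpolar solvation (``sa``) and the entropy term
    ``minus_t_delta_s`` (-T dS). Derived totals: ``mm = vdw + cou``,
    ``delta_h = mm + pb + sa``, ``delta_g = delta_h + minus_t_delta_s``.
    """

    complex_id: str
    vdw: Optional[float] = None
    cou: Optional[float] = None
    pb: Optional[float] = None
    sa: Optional[float] = None
    minus_t_delta_s: Optional[float] = None
    mm: Optional[float] = None
    delta_h: Optional[float] = None
    delta_g: Optional[float] = None

    BASE_FIELDS = ("vdw", "cou", "pb", "sa", "minus_t_delta_s")


def mmpbsa_totals(
    components: Iterable[EnergyComponents],
    validate: bool = False,
    tol: float = ROUNDING_TOL,
) -> list[EnergyComponents]:
    """Fill MM, dH and dG for each row from its five base components.

    With ``validate=True``, totals already present on a row are checked
    against the recomputed sums; a discrepancy beyond ``tol`` kcal/mol
    per summation step raises. (Printed tables are usually rounded to
    two decimals, so each sum may be off by one unit in the last place.)
    """
    out = []
    for row in components:
        missing = [f for f in EnergyComponents.BASE_FIELDS if getattr(row, f) is None]
        if missing:
            raise ValueError(
                f"complex {row.complex_id!r} is missing component(s): {', '.join(missing)}"
            )
        mm = row.vdw + row.cou
        delta_h = mm + row.pb + row.sa
        delta_g = delta_h + row.minus_t_delta_s
        if validate:
            for name, recomputed, supplied in (
                ("MM", mm, row.mm),
                ("dH", delta_h, row.delta_h),
                ("dG", delta_g, row.delta_g),
            ):
                if supplied is not None and abs(supplied - recomputed) > tol:
                    raise ValueError(
                        f"complex {row.complex_id!r}: supplied {name}={supplied} "
                        f"disagrees with recomputed {recomputed:.4f}"
                    )
        out.append(
            EnergyComponents(
                complex_id=row.complex_id,
                vdw=row.vdw,
                cou=row.cou,
                pb=row.pb,
                sa=row.sa,
                minus_t_delta_s=row.minus_t_delta_s,
                mm=mm,
                delta_h=delta_h,
                delta_g=delta_g,
            )
        )
    return out


@dataclass
class ResidueDecomposition:
    """Per-residue dH contributions for one complex, unit-tagged."""

    complex_id: str
    contributions: dict[int, float]
    unit: str = "kcal/mol"  # or "kJ/mol"

    def __post_init__(self) -> None:
        if self.unit not in ("kcal/mol", "kJ/mol"):
            raise ValueError(f"unknown unit {self.unit!r}")
        for res, val in self.contributions.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite contribution for residue {res}")

    def in_kcal(self) -> dict[int, float]:
        if self.unit == "kcal/mol":
            return dict(self.contributions)
        return {r: v / KJ_PER_KCAL for r, v in self.contributions.items()}


def residue_fraction(
    d: ResidueDecomposition,
    residues: Iterable[int],
    total_delta_h: float,
) -> float:
    """Percentage of the total dH contributed by the given residues.

    ``total_delta_h`` is in kcal/mol; kJ/mol decompositions are converted
    before the ratio, so the result is unit-invariant.
    """
    if total_delta_h == 0:
        raise ValueError("total dH is zero; fraction undefined")
    contrib = d.in_kcal()
    residues = set(residues)
    unknown = residues - set(contrib)
    if unknown:
        raise ValueError(f"unknown residue(s): {sorted(unknown)}")
    return 100.0 * sum(contrib[r] for r in residues) / total_delta_h
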