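"""ADME-based compound screening and compound-table bookkeeping.

Candidate herbal compounds arrive from several sources (TCMSP-style
property tables, SwissADME-style predictions, literature curation) and are
filtered on absorption/drug-likeness criteria before target prediction:

* the TCMSP route keeps compounds with oral bioavailability (OB) >= 30 %,
  drug-likeness (DL) >= 0.18 and Caco-2 permeability >= -0.4;
* the SwissADME route keeps compounds with a "High" gastrointestinal
  absorption call and at least two drug-likeness rules satisfied
  (Lipinski / Ghose / Veber / Egan / Muegge).

Surviving lists are merged and deduplicated, preferring the PubChem CID as
the identity key and falling back to a normalized compound name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

logger = logging.getLogger(__name__)

#: Default ADME thresholds for the TCMSP-style screen.
OB_MIN = 30.0
DL_MIN = 0.18
CACO2_MIN = -0.4
#: Minimum number of satisfied drug-likeness rules for the SwissADME screen.
DL_FLAGS_MIN = 2

MissingPolicy = Literal["error", "drop-missing"]


class MissingPropertyError(ValueError):
    """A record lacks a property required by the active screen."""


@dataclass
class CompoundRecord:
    """One candidate compound with its ADME properties and provenance.

    ``ob`` is a percentage in [0, 100]; ``dl`` and ``caco2`` are the
    unitless TCMSP scores; ``gi_absorption`` is SwissADME's categorical
    call; ``druglikeness_flags`` holds one boolean per drug-likeness rule.
    """

    name: str
    pubchem_cid: Optional[int] = None
    smiles: Optional[str] = None
    molecular_formula: Optional[str] = None
    molecular_weight: Optional[float] = None
    source: str = "TCMSP"
    ob: Optional[float] = None
    dl: Optional[float] = None
    caco2: Optional[float] = None
    gi_absorption: str = "unknown"
    druglikeness_flags: Sequence[bool] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ValueError(
                f"molecular_weight must be positive, got {self.molecular_weight!r} "
                f"for {self.name!r}"
            )
        if self.ob is not None and not (0.0 <= self.ob <= 100.0):
            raise ValueError(f"ob must be in [0, 100], got {self.ob!r} for {self.name!r}")
        self.druglikeness_flags = tuple(bool(f) for f in self.druglikeness_flags)

    def same_compound(self, other: "CompoundRecord") -> bool:
        """Identity rule for deduplication.

        When both records carry a PubChem CID the CID decides; otherwise
        the case-/whitespace-normalized names are compared.
        """
        if self.pubchem_cid is not None and other.pubchem_cid is not None:
            return self.pubchem_cid == other.pubchem_cid
        return normalize_name(self.name) == normalize_name(other.name)


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed compound-name key."""
    return " ".join(name.strip().lower().split())


def _require(record: CompoundRecord, fields: Sequence[str], policy: MissingPolicy) -> bool:
    """Return True if all ``fields`` are present; raise or drop per policy."""
    missing = [f for f in fields if getattr(record, f) is None]
    if "gi_absorption" in fields and record.gi_absorption == "unknown":
        missing.append("gi_absorption")
    if "druglikeness_flags" in fields and len(record.druglikeness_flags) == 0:
        missing.append("druglikeness_flags")
    if not missing:
        return True
    if policy == "drop-missing":
        logger.warning("dropping %r: missing %s", record.name, ", ".join(missing))
        return False
    raise MissingPropertyError(
        f"record {record.name!r} is missing required propert"
        f"{'ies' if len(missing) > 1 else 'y'}: {', '.join(missing)}"
    )


def screen_tcmsp(
    records: Iterable[CompoundRecord],
    *,
    ob_min: float = OB_MIN,
    dl_min: float = DL_MIN,
    caco2_min: float = CACO2_MIN,
    missing: MissingPolicy = "error",
) -> list[CompoundRecord]:
    """Keep records with OB >= ob_min, DL >= dl_min and Caco-2 >= caco2_min.

    All three thresholds are inclusive. Input order is preserved.
    """
    kept = []
    for rec in records:
        if not _require(rec, ("ob", "dl", "caco2"), missing):
            continue
        if rec.ob >= ob_min and rec.dl >= dl_min and rec.caco2 >= caco2_min:
            kept.append(rec)
    return kept


def screen_swissadme(
    records: Iterable[CompoundRecord],
    *,
    flags_min: int = DL_FLAGS_MIN,
    missing: MissingPolicy = "error",
) -> list[CompoundRecord]:
    """Keep records with GI absorption "High" and >= flags_min drug-likeness rules met."""
    kept = []
    for rec in records:
        if not _require(rec, ("gi_absorption", "druglikeness_flags"), missing):
            continue
        if rec.gi_absorption == "High" and sum(rec.druglikeness_flags) >= flags_min:
            kept.append(rec)
    return kept


def merge_dedup(*lists: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Merge compound lists into one record per compound identity.

    Two records are the same compound when their PubChem CIDs match (both
    present) or, lacking a CID on either side, their case-/whitespace-
    normalized names match. The first occurrence wins; duplicates whose
    molecular weights disagree by more than 1 % (relative) trigger a
    logged warning. Output is sorted by name.
    """
    kept: list[CompoundRecord] = []
    for lst in lists:
        for rec in lst:
            first = next((k for k in kept if k.same_compound(rec)), None)
            if first is None:
                kept.append(rec)
                continue
            if (
                first.molecular_weight is not None
                and rec.molecular_weight is not None
                and abs(rec.molecular_weight - first.molecular_weight)
                > 0.01 * abs(first.molecular_weight)
            ):
                logger.warning(
                    "duplicate compound %r with conflicting molecular weights "
                    "(%.2f vs %.2f); keeping the first",
                    rec.name, first.molecular_weight, rec.molecular_weight,
                )
    return sorted(kept, key=lambda r: normalize_name(r.name))
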