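"""Assembly of compound-target and disease-target universes.

Compound targets come from database annotation (kept unconditionally) and
from ligand-based prediction (kept only with probability strictly greater
than zero). Disease targets come from several curated sources with
per-source score filters: DisGeNet score >= 0.3 (inclusive), GeneCards
relevance > 10 (strict), OMIM and TTD unfiltered. Gene symbols are
compared case-insensitively after uppercasing and trimming; no alias or
ortholog resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

DISGENET_SCORE_MIN = 0.3
GENECARDS_RELEVANCE_MIN = 10.0


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class TargetHit:
    """A predicted or curated compound->gene association."""

    compound: str
    gene_symbol: str
    source: str = "TCMSP"  # or "SwissTargetPrediction"
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol or not self.gene_symbol.strip():
            raise ValueError(f"empty gene symbol in hit for compound {self.compound!r}")
        if self.source == "SwissTargetPrediction" and self.probability is None:
            raise ValueError(
                f"SwissTargetPrediction hit for {self.compound!r} lacks a probability"
            )
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability must be in [0, 1], got {self.probability!r}")


@dataclass
class DiseaseTargetRecord:
    """A disease->gene association from one source database."""

    gene_symbol: str
    source: str  # DisGeNet | GeneCards | OMIM | TTD
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol or not self.gene_symbol.strip():
            raise ValueError("empty gene symbol in disease-target record")
        if self.source in ("DisGeNet", "GeneCards") and self.score is None:
            raise ValueError(
                f"{self.source} record for {self.gene_symbol!r} requires a score"
            )


@dataclass
class TargetSet:
    """A deduplicated set of gene symbols with per-gene source provenance."""

    members: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {normalize_symbol(m) for m in self.members}
        self.provenance = {
            normalize_symbol(k): set(v) for k, v in self.provenance.items()
        }
        stray = set(self.provenance) - self.members
        if stray:
            raise ValueError(f"provenance keys not in members: {sorted(stray)}")

    def add(self, symbol: str, source: str) -> None:
        symbol = normalize_symbol(symbol)
        self.members.add(symbol)
        self.provenance.setdefault(symbol, set()).add(source)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def issubset(self, other: "TargetSet") -> bool:
        return self.members <= other.members

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], source: str = "unspecified") -> "TargetSet":
        ts = cls()
        for s in symbols:
            ts.add(s, source)
        return ts


class VennCounts(NamedTuple):
    """Two-set Venn breakdown: exclusive-to-a, common, exclusive-to-b."""

    a_only: int
    common: int
    b_only: int


def collect_compound_targets(hits: Iterable[TargetHit]) -> TargetSet:
    """Union of compound-target hits, deduplicated by gene symbol.

    Prediction hits (SwissTargetPrediction) are kept only when their
    probability is strictly greater than zero; curated (TCMSP) hits are
    kept unconditionally. Provenance records the contributing compounds.
    """
    ts = TargetSet()
    for hit in hits:
        if hit.source == "SwissTargetPrediction" and not hit.probability > 0.0:
            continue
        ts.add(hit.gene_symbol, hit.compound)
    return ts


def collect_disease_targets(records: Iterable[DiseaseTargetRecord]) -> TargetSet:
    """Union of disease-target records after per-source score filters."""
    ts = TargetSet()
    for rec in records:
        if rec.source == "DisGeNet" and rec.score < DISGENET_SCORE_MIN:
            continue
        if rec.source == "GeneCards" and not rec.score > GENECARDS_RELEVANCE_MIN:
            continue
        ts.add(rec.gene_symbol, rec.source)
    return ts


def intersect(a: TargetSet, b: TargetSet) -> tuple[TargetSet, VennCounts]:
    """Intersection of two target sets plus the Venn counts.

    The common set's provenance is the union of both sides' provenance.
    """
    common_symbols = a.members & b.members
    common = TargetSet()
    for s in sorted(common_symbols):
        for src in a.provenance.get(s, set()) | b.provenance.get(s, set()):
            common.add(s, src)
        common.members.add(s)
    counts = VennCounts(
        a_only=len(a.members - common_symbols),
        common=len(common_symbols),
        b_only=len(b.members - common_symbols),
    )
    return common, counts
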