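"""Over-representation analysis (ORA) with Benjamini-Hochberg adjustment.

A study gene set (e.g. the key targets from the PPI stage) is tested
against a collection of annotated gene sets (GO biological process /
cellular component / molecular function, KEGG pathways) with the
upper-tail hypergeometric test. Terms with zero overlap are excluded
before adjustment; the Benjamini-Hochberg step-up is applied within each
category separately, results with adjusted p below the significance
cutoff are kept, sorted by adjusted p (ascending), then count
(descending), then term id, and truncated to the top-k per category.

The background universe defaults to all genes appearing in the
annotation collection; callers may override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .targets import TargetSet

CATEGORIES = ("BP", "CC", "MF", "KEGG")


@dataclass
class GeneSetTerm:
    """One annotated gene set (a GO term or KEGG pathway)."""

    term_id: str
    term_name: str
    category: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for term {self.term_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        self.members = frozenset(self.members)


@dataclass
class GeneSetCollection:
    """A list of gene-set terms with unique ids."""

    terms: list[GeneSetTerm]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate term ids: {dupes}")

    def all_genes(self) -> frozenset:
        out: set = set()
        for t in self.terms:
            out |= t.members
        return frozenset(out)

    def by_category(self, category: str) -> list[GeneSetTerm]:
        return [t for t in self.terms if t.category == category]


@dataclass
class EnrichmentResult:
    """One term's ORA outcome: Count, GeneRatio, p-value, adjusted p, hits."""

    term_id: str
    term_name: str
    category: str
    count: int
    gene_ratio: Fraction
    p_value: float
    p_adjust: float
    hit_genes: frozenset


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` is the background size, ``K`` the term size within the
    background, ``n`` the study size within the background and ``k`` the
    observed overlap. X ~ Hypergeometric(N, K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``p_adj(i) = min_{j >= i} (m * p_(j) / j)`` on the ascending-sorted
    p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def run_ora(
    study: TargetSet,
    collection: GeneSetCollection,
    background: Optional[TargetSet] = None,
    alpha: float = 0.05,
    top_k: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Per-category ORA of ``study`` against ``collection``.

    Parameters
    ----------
    study
        The gene set to test (e.g. key targets).
    collection
        Annotated gene sets, each tagged BP / CC / MF / KEGG.
    background
        The gene universe. Defaults to all genes in the collection. The
        effective study set is ``study ∩ background``.
    alpha
        Keep results with adjusted p strictly below this (1.0 keeps all).
    top_k
        Truncate to this many results per category (None = no limit).

    Returns results for all categories concatenated, each category sorted
    by (p_adjust asc, count desc, term_id asc).
    """
    bg = frozenset(background.members) if background is not None else collection.all_genes()
    study_bg = study.members & bg
    if not study_bg:
        raise ValueError("study set does not overlap the background universe")
    N, n = len(bg), len(study_bg)

    out: list[EnrichmentResult] = []
    for category in CATEGORIES:
        terms = collection.by_category(category)
        rows = []
        for t in terms:
            members_bg = t.members & bg
            hits = members_bg & study_bg
            if not hits:  # zero-overlap terms are not tested
                continue
            p = hypergeom_upper(N, len(members_bg), n, len(hits))
            rows.append((t, hits, p))
        if not rows:
            continue
        adj = bh_adjust([p for _, _, p in rows])
        results = [
            EnrichmentResult(
                term_id=t.term_id,
                term_name=t.term_name,
                category=category,
                count=len(hits),
                gene_ratio=Fraction(len(hits), n),
                p_value=p,
                p_adjust=q,
                hit_genes=frozenset(hits),
            )
            for (t, hits, p), q in zip(rows, adj)
        ]
        results = [r for r in results if r.p_adjust < alpha]
        results.sort(key=lambda r: (r.p_adjust, -r.count, r.term_id))
        if top_k is not None:
            results = results[:top_k]
        out.extend(results)
    return out
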