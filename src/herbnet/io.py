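"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain text: TSV tables for compounds, target hits, disease
targets, edges and energies; GMT for gene-set collections. Column layouts
are documented on each function and shared with the synthetic-data
generators, so generated files round-trip through these readers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .enrichment import EnrichmentResult, GeneSetCollection, GeneSetTerm
from .md import EnergyComponents
from .screen import CompoundRecord
from .targets import DiseaseTargetRecord, TargetHit

PathLike = Union[str, Path]

_COMPOUND_COLUMNS = [
    "name", "pubchem_cid", "smiles", "formula", "mw", "source",
    "ob", "dl", "caco2", "gi",
]


def _opt(value, cast):
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return cast(value)


def write_compounds(path: PathLike, records: Sequence[CompoundRecord]) -> None:
    """Write a compound TSV: fixed columns plus one dl_flag_i column per rule."""
    n_flags = max((len(r.druglikeness_flags) for r in records), default=0)
    flag_cols = [f"dl_flag_{i + 1}" for i in range(n_flags)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COMPOUND_COLUMNS + flag_cols)
        for r in records:
            flags = list(r.druglikeness_flags) + [None] * (
                n_flags - len(r.druglikeness_flags)
            )
            w.writerow(
                [
                    r.name,
                    "" if r.pubchem_cid is None else r.pubchem_cid,
                    r.smiles or "",
                    r.molecular_formula or "",
                    "" if r.molecular_weight is None else f"{r.molecular_weight:g}",
                    r.source,
                    "" if r.ob is None else f"{r.ob:g}",
                    "" if r.dl is None else f"{r.dl:g}",
                    "" if r.caco2 is None else f"{r.caco2:g}",
                    r.gi_absorption,
                ]
                + ["" if f is None else int(f) for f in flags]
            )


def read_compounds(path: PathLike) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    flag_cols = [c for c in df.columns if c.startswith("dl_flag_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        flags = tuple(bool(int(d[c])) for c in flag_cols if d[c] != "")
        records.append(
            CompoundRecord(
                name=d["name"],
                pubchem_cid=_opt(d["pubchem_cid"], int),
                smiles=d["smiles"] or None,
                molecular_formula=d["formula"] or None,
                molecular_weight=_opt(d["mw"], float),
                source=d["source"],
                ob=_opt(d["ob"], float),
                dl=_opt(d["dl"], float),
                caco2=_opt(d["caco2"], float),
                gi_absorption=d["gi"] or "unknown",
                druglikeness_flags=flags,
            )
        )
    return records


def write_target_hits(path: PathLike, hits: Sequence[TargetHit]) -> None:
    """Columns: compound, gene_symbol, source, probability (blank when absent)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound", "gene_symbol", "source", "probability"])
        for h in hits:
            w.writerow(
                [h.compound, h.gene_symbol, h.source,
                 "" if h.probability is None else f"{h.probability:g}"]
            )


def read_target_hits(path: PathLike) -> list[TargetHit]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        TargetHit(
            compound=r.compound,
            gene_symbol=r.gene_symbol,
            source=r.source,
            probability=_opt(r.probability, float),
        )
        for r in df.itertuples(index=False)
    ]


def write_disease_targets(path: PathLike, records: Sequence[DiseaseTargetRecord]) -> None:
    """Columns: gene_symbol, source, score (blank for OMIM/TTD)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_symbol", "source", "score"])
        for r in records:
            w.writerow(
                [r.gene_symbol, r.source, "" if r.score is None else f"{r.score:g}"]
            )


def read_disease_targets(path: PathLike) -> list[DiseaseTargetRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        DiseaseTargetRecord(
            gene_symbol=r.gene_symbol, source=r.source, score=_opt(r.score, float)
        )
        for r in df.itertuples(index=False)
    ]


def write_edge_list(path: PathLike, graph, score_key: str = "score") -> None:
    """STRING-style edge TSV: node1, node2, combined_score (0-1 scale)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node1", "node2", "combined_score"])
        for a, b, data in sorted(
            graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
        ):
            a, b = sorted((str(a), str(b)))
            w.writerow([a, b, f"{data.get(score_key, 1.0):.6f}"])


def write_gmt(path: PathLike, collection: GeneSetCollection) -> None:
    """GMT lines: term_id <TAB> term_name <TAB> member...; category kept in the name.

    The plain GMT format has no category column, so the term name is
    written as ``name|category`` and split again by :func:`read_gmt`.
    """
    with open(path, "w") as fh:
        for t in collection.terms:
            name = f"{t.term_name}|{t.category}"
            fh.write("\t".join([t.term_id, name] + sorted(t.members)) + "\n")


def read_gmt(path: PathLike, category: str | None = None) -> GeneSetCollection:
    """Read a GMT file.

    ``category`` forces one category for every term; without it, a
    ``name|category`` suffix written by :func:`write_gmt` is honored
    (defaulting to KEGG when absent).
    """
    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no members")
            term_id, name, members = parts[0], parts[1], parts[2:]
            cat = category
            if cat is None and "|" in name:
                name, cat = name.rsplit("|", 1)
            terms.append(
                GeneSetTerm(
                    term_id=term_id,
                    term_name=name,
                    category=cat or "KEGG",
                    members=frozenset(members),
                )
            )
    return GeneSetCollection(terms=terms)


def write_enrichment_results(path: PathLike, results: Sequence[EnrichmentResult]) -> None:
    """Columns: term_id, name, category, Count, GeneRatio, pvalue, p.adjust, genes."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["term_id", "name", "category", "Count", "GeneRatio", "pvalue",
             "p.adjust", "genes"]
        )
        for r in results:
            w.writerow(
                [
                    r.term_id, r.term_name, r.category, r.count,
                    f"{r.gene_ratio.numerator}/{r.gene_ratio.denominator}",
                    f"{r.p_value:.6g}", f"{r.p_adjust:.6g}",
                    "/".join(sorted(r.hit_genes)),
                ]
            )


def write_energy_components(path: PathLike, rows: Sequence[EnergyComponents]) -> None:
    """Columns: complex, vdw, cou, pb, sa, minus_t_delta_s[, mm, delta_h, delta_g]."""
    have_totals = any(r.delta_g is not None for r in rows)
    cols = ["complex", "vdw", "cou", "pb", "sa", "minus_t_delta_s"]
    if have_totals:
        cols += ["mm", "delta_h", "delta_g"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            vals = [r.complex_id] + [
                "" if getattr(r, f) is None else f"{getattr(r, f):.2f}"
                for f in cols[1:]
            ]
            w.writerow(vals)


def read_energy_components(path: PathLike) -> list[EnergyComponents]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        rows.append(
            EnergyComponents(
                complex_id=d["complex"],
                vdw=_opt(d.get("vdw"), float),
                cou=_opt(d.get("cou"), float),
                pb=_opt(d.get("pb"), float),
                sa=_opt(d.get("sa"), float),
                minus_t_delta_s=_opt(d.get("minus_t_delta_s"), float),
                mm=_opt(d.get("mm"), float),
                delta_h=_opt(d.get("delta_h"), float),
                delta_g=_opt(d.get("delta_g"), float),
            )
        )
    return rows
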