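"""Synthetic inputs with known ground truth for every pipeline stage.

Real network-pharmacology runs consume exports from compound, target,
disease and interaction databases plus docking and MD outputs. None of
those can be redistributed or regenerated deterministically, so this
module emulates their *statistical shape* with planted ground truth:

* compound tables where a configurable fraction passes each ADME screen
  and a known number of exact duplicates is planted;
* compound/disease target sets with an exactly planted intersection;
* PPI graphs from standard random-graph models (or a fixed edge list)
  with confidence scores above the filtering cutoff;
* gene-set collections with planted over-represented terms;
* RMSD-like trajectories that ramp to a plateau at a known
  equilibration time;
* MM/PBSA component tables whose totals are recoverable by summation.

All generators are driven by one master seed; each draws from its own
derived substream, so adding a generator never perturbs the output of
another. Gene symbols are synthetic tokens (``G000001`` ...), compound
names ``CMP-001`` ... — no attempt is made to mimic real vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .enrichment import GeneSetCollection, GeneSetTerm
from .md import EnergyComponents, TrajectorySeries
from .screen import CompoundRecord
from .targets import TargetSet

#: fixed substream ids — append only, never renumber (test stability)
_STREAMS = {
    "compounds": 1,
    "targets": 2,
    "graph": 3,
    "annotations": 4,
    "trajectory": 5,
    "energy": 6,
    "relations": 7,
    "docking": 8,
}


class SyntheticSpecError(ValueError):
    """A synthetic-data parameter is invalid; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class TrajectoryParams:
    """Shape of a synthetic RMSD-like series.

    A linear ramp from 0 reaches ``plateau_level`` (nm) at
    ``equilibration_time`` (ns); afterwards the series fluctuates about
    the plateau with i.i.d. Gaussian noise of sd ``noise_sd`` (nm).
    Sampling runs to ``total_time`` every ``dt`` ns.
    """

    equilibration_time: float = 13.0
    plateau_level: float = 0.35
    noise_sd: float = 0.03
    total_time: float = 50.0
    dt: float = 0.1


@dataclass
class EnergyParams:
    """Uniform ranges (kcal/mol) for the five MM/PBSA base components."""

    n_complexes: int = 5
    vdw_range: Tuple[float, float] = (-46.0, -33.0)
    cou_range: Tuple[float, float] = (-10.5, -3.0)
    pb_range: Tuple[float, float] = (14.0, 36.0)
    sa_range: Tuple[float, float] = (-5.8, -4.5)
    minus_t_delta_s_range: Tuple[float, float] = (1.5, 5.5)


@dataclass
class PlantedTerm:
    """A gene-set term whose study overlap is forced.

    ``effect`` is the enrichment strength: the fraction of the term's
    capacity ``min(size, |study|)`` filled with study genes. Effect 1.0
    with size >= |study| makes the term contain every study gene.
    """

    term_id: str
    effect: float
    size: int = 40
    category: str = "KEGG"


@dataclass
class SyntheticSpec:
    """All knobs of the synthetic-data generators, driven by one seed."""

    seed: int = 0
    # compound table
    n_compounds: int = 30
    n_duplicates: int = 3
    tcmsp_pass_fraction: float = 0.6
    swissadme_pass_fraction: float = 0.6
    # target sets (sized after the study shape: 665 / 593 / 119)
    n_compound_targets: int = 665
    n_disease_targets: int = 593
    planted_overlap: int = 119
    # PPI graph
    graph_model: str = "erdos_renyi"
    graph_params: dict = field(default_factory=lambda: {"n": 119, "p": 0.08})
    # annotations
    n_terms: int = 40
    term_size_range: Tuple[int, int] = (20, 80)
    planted_terms: Sequence[PlantedTerm] = ()
    # trajectories / energies
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)
    energy_params: EnergyParams = field(default_factory=EnergyParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_compounds": self.n_compounds,
            "n_duplicates": self.n_duplicates,
            "n_compound_targets": self.n_compound_targets,
            "n_disease_targets": self.n_disease_targets,
            "planted_overlap": self.planted_overlap,
            "n_terms": self.n_terms,
        }
        for name, value in counts.items():
            if value < 0:
                raise SyntheticSpecError(name, f"must be >= 0, got {value}")
        if self.n_duplicates > self.n_compounds:
            raise SyntheticSpecError(
                "n_duplicates", f"exceeds n_compounds ({self.n_compounds})"
            )
        if self.planted_overlap > min(self.n_compound_targets, self.n_disease_targets):
            raise SyntheticSpecError(
                "planted_overlap",
                f"{self.planted_overlap} exceeds the smaller target set "
                f"({min(self.n_compound_targets, self.n_disease_targets)})",
            )
        for name in ("tcmsp_pass_fraction", "swissadme_pass_fraction"):
            frac = getattr(self, name)
            if not (0.0 <= frac <= 1.0):
                raise SyntheticSpecError(name, f"must be in [0, 1], got {frac}")
        tp = self.trajectory_params
        if tp.noise_sd < 0:
            raise SyntheticSpecError("trajectory_params.noise_sd", "must be >= 0")
        if tp.equilibration_time < 0 or tp.total_time <= 0 or tp.dt <= 0:
            raise SyntheticSpecError("trajectory_params", "times must be nonnegative")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            raise SyntheticSpecError("term_size_range", "must be a nonempty range >= 1")
        for p in self.planted_terms:
            if not (0.0 <= p.effect <= 1.0):
                raise SyntheticSpecError(
                    "planted_terms", f"effect must be in [0, 1], got {p.effect}"
                )
        ep = self.energy_params
        if ep.n_complexes < 0:
            raise SyntheticSpecError("energy_params.n_complexes", "must be >= 0")
        for name in ("vdw_range", "cou_range", "pb_range", "sa_range",
                     "minus_t_delta_s_range"):
            lo, hi = getattr(ep, name)
            if lo > hi:
                raise SyntheticSpecError(f"energy_params.{name}", "range inverted")

    def rng(self, stream: str) -> np.random.Generator:
        """Seeded substream generator; independent per generator name."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


def _gene_symbol(i: int) -> str:
    return f"G{i:06d}"


def gen_compound_table(spec: SyntheticSpec) -> list[CompoundRecord]:
    """Synthetic compound table with planted screen outcomes and duplicates.

    ``tcmsp_pass_fraction`` of the unique records satisfy all three
    TCMSP-style thresholds (OB >= 30, DL >= 0.18, Caco-2 >= -0.4);
    ``swissadme_pass_fraction`` satisfy the SwissADME-style screen
    (GI High, >= 2 drug-likeness rules). ``n_duplicates`` exact copies
    of randomly chosen records are interleaved, so deduplication must
    recover ``n_compounds - n_duplicates`` unique compounds.
    """
    rng = spec.rng("compounds")
    n_unique = spec.n_compounds - spec.n_duplicates
    tcmsp_pass = np.zeros(n_unique, dtype=bool)
    tcmsp_pass[: round(spec.tcmsp_pass_fraction * n_unique)] = True
    rng.shuffle(tcmsp_pass)
    swiss_pass = np.zeros(n_unique, dtype=bool)
    swiss_pass[: round(spec.swissadme_pass_fraction * n_unique)] = True
    rng.shuffle(swiss_pass)

    records: list[CompoundRecord] = []
    for i in range(n_unique):
        if tcmsp_pass[i]:
            ob = rng.uniform(30.0, 95.0)
            dl = rng.uniform(0.18, 1.0)
            caco2 = rng.uniform(-0.4, 1.5)
        else:
            ob, dl, caco2 = (
                rng.uniform(30.0, 95.0),
                rng.uniform(0.18, 1.0),
                rng.uniform(-0.4, 1.5),
            )
            # violate one randomly chosen criterion, strictly
            which = rng.integers(0, 3)
            if which == 0:
                ob = rng.uniform(0.0, 29.9)
            elif which == 1:
                dl = rng.uniform(0.0, 0.17)
            else:
                caco2 = rng.uniform(-3.0, -0.41)
        if swiss_pass[i]:
            gi = "High"
            n_true = int(rng.integers(2, 6))
        else:
            gi = "Low" if rng.random() < 0.5 else "High"
            n_true = int(rng.integers(0, 2)) if gi == "High" else int(rng.integers(0, 6))
        flags = np.zeros(5, dtype=bool)
        flags[:n_true] = True
        rng.shuffle(flags)
        records.append(
            CompoundRecord(
                name=f"CMP-{i + 1:03d}",
                pubchem_cid=int(100000 + i),
                molecular_weight=float(np.round(rng.uniform(150.0, 550.0), 2)),
                source="TCMSP" if tcmsp_pass[i] or rng.random() < 0.5 else "SymMap",
                ob=float(np.round(ob, 2)),
                dl=float(np.round(dl, 3)),
                caco2=float(np.round(caco2, 3)),
                gi_absorption=gi,
                druglikeness_flags=tuple(flags),
            )
        )
    if spec.n_duplicates:
        dup_idx = rng.choice(n_unique, size=spec.n_duplicates, replace=False)
        for i in sorted(int(j) for j in dup_idx):
            records.append(records[i])
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def gen_target_sets(spec: SyntheticSpec) -> tuple[TargetSet, TargetSet]:
    """Compound and disease target sets with an exactly planted overlap.

    ``|compound ∩ disease| == spec.planted_overlap`` by construction.
    """
    rng = spec.rng("targets")
    nc, nd, k = spec.n_compound_targets, spec.n_disease_targets, spec.planted_overlap
    total = nc + nd - k
    # random, non-contiguous token assignment over a roomy universe
    universe = rng.choice(max(2 * total, 1000), size=total, replace=False)
    symbols = [_gene_symbol(int(i) + 1) for i in universe]
    compound = TargetSet.from_symbols(symbols[:nc], source="compound-prediction")
    disease_symbols = symbols[nc - k : nc - k + nd]
    disease = TargetSet()
    for s in disease_symbols:
        disease.add(s, str(rng.choice(["DisGeNet", "GeneCards", "OMIM", "TTD"])))
    return compound, disease


def gen_ppi(
    spec: SyntheticSpec, nodes: Optional[Sequence[str]] = None
) -> nx.Graph:
    """Synthetic PPI graph: simple, undirected, no self-loops, seeded.

    ``graph_model`` selects ``erdos_renyi`` (params ``n``, ``p``),
    ``barabasi_albert`` (params ``n``, ``m``) or ``fixed_edge_list``
    (param ``edges``). Each edge gets a confidence score drawn from
    ``graph_params['score_range']`` (default (0.905, 1.0), i.e. above
    the conventional 0.9 cutoff). ``nodes`` relabels the integer nodes
    with given identifiers (e.g. gene symbols).
    """
    rng = spec.rng("graph")
    params = dict(spec.graph_params)
    score_lo, score_hi = params.pop("score_range", (0.905, 1.0))
    model = spec.graph_model
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(params["n"], params["p"], seed=int(rng.integers(2**31)))
    elif model == "barabasi_albert":
        g = nx.barabasi_albert_graph(
            params["n"], params["m"], seed=int(rng.integers(2**31))
        )
    elif model == "fixed_edge_list":
        g = nx.Graph()
        g.add_edges_from(params["edges"])
    else:
        raise SyntheticSpecError("graph_model", f"unknown model {model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    if nodes is not None:
        if len(nodes) < g.number_of_nodes():
            raise SyntheticSpecError(
                "graph_params", f"{g.number_of_nodes()} nodes but only "
                f"{len(nodes)} labels supplied"
            )
        mapping = dict(zip(sorted(g.nodes), nodes))
        g = nx.relabel_nodes(g, mapping)
    for a, b in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
        g.edges[a, b]["score"] = float(rng.uniform(score_lo, score_hi))
    return g


def gen_annotations(
    spec: SyntheticSpec, study: TargetSet, background: TargetSet
) -> GeneSetCollection:
    """Gene-set collection with planted over-represented terms.

    Planted terms draw ``round(effect * min(size, |study|))`` members
    from the study set and fill the rest uniformly from the non-study
    background; non-planted terms draw uniformly from the whole
    background. Requires ``study ⊆ background``.
    """
    if not study.issubset(background):
        raise ValueError("study set must be a subset of the background")
    rng = spec.rng("annotations")
    bg = sorted(background.members)
    study_genes = sorted(study.members)
    non_study = sorted(background.members - study.members)

    planted = {p.term_id: p for p in spec.planted_terms}
    categories = ("KEGG", "BP", "CC", "MF")
    terms: list[GeneSetTerm] = []
    for i in range(spec.n_terms):
        term_id = f"T{i + 1:04d}"
        if term_id in planted:
            p = planted[term_id]
            n_from_study = round(p.effect * min(p.size, len(study_genes)))
            n_from_study = min(n_from_study, p.size)
            members = list(
                rng.choice(study_genes, size=n_from_study, replace=False)
            )
            n_fill = p.size - n_from_study
            if n_fill > len(non_study):
                raise SyntheticSpecError(
                    "planted_terms", f"{term_id} needs {n_fill} non-study genes "
                    f"but only {len(non_study)} exist"
                )
            members += list(rng.choice(non_study, size=n_fill, replace=False))
            category = p.category
        else:
            size = int(rng.integers(spec.term_size_range[0], spec.term_size_range[1] + 1))
            size = min(size, len(bg))
            members = list(rng.choice(bg, size=size, replace=False))
            category = categories[i % len(categories)]
        terms.append(
            GeneSetTerm(
                term_id=term_id,
                term_name=f"synthetic term {i + 1}",
                category=category,
                members=frozenset(str(m) for m in members),
            )
        )
    return GeneSetCollection(terms=terms)


def gen_trajectory(spec: SyntheticSpec, label: str = "synthetic") -> TrajectorySeries:
    """RMSD-like series: linear ramp to a plateau, then Gaussian noise.

    With ``noise_sd == 0`` every post-equilibration sample equals
    ``plateau_level`` exactly. Values are clipped at 0 (an RMSD cannot
    be negative).
    """
    tp = spec.trajectory_params
    rng = spec.rng("trajectory")
    n = int(round(tp.total_time / tp.dt)) + 1
    times = np.arange(n) * tp.dt
    if tp.equilibration_time > 0:
        ramp = np.minimum(times / tp.equilibration_time, 1.0) * tp.plateau_level
    else:
        ramp = np.full(n, tp.plateau_level)
    values = ramp.copy()
    post = times >= tp.equilibration_time
    if tp.noise_sd > 0:
        values[post] += rng.normal(0.0, tp.noise_sd, size=int(post.sum()))
    return TrajectorySeries(times=times, values=np.clip(values, 0.0, None), label=label)


def gen_compound_target_pairs(
    spec: SyntheticSpec,
    compounds: Sequence[str],
    targets: Sequence[str],
    mean_degree: float = 5.0,
) -> list[tuple[str, str]]:
    """Random bipartite compound-target pairs for network assembly.

    Each compound hits a Poisson(``mean_degree``) number of distinct
    targets (at least one), drawn uniformly. Deterministic per seed.
    """
    rng = spec.rng("relations")
    targets = list(targets)
    pairs = []
    for c in compounds:
        k = min(max(1, int(rng.poisson(mean_degree))), len(targets))
        for t in rng.choice(targets, size=k, replace=False):
            pairs.append((str(c), str(t)))
    return pairs


def gen_docking_poses(
    spec: SyntheticSpec,
    ligands: Sequence[str],
    receptors: Sequence[str],
    n_poses: int = 10,
    affinity_range: Tuple[float, float] = (-10.5, -4.0),
):
    """Synthetic Vina-style pose table: n_poses per ligand x receptor pair.

    Pose 1 gets the pair's base affinity drawn from ``affinity_range``;
    later poses are progressively weaker (as Vina orders its models).
    """
    from .docking import DockingPose  # local import to avoid a cycle

    rng = spec.rng("docking")
    lo, hi = affinity_range
    poses = []
    for lig in ligands:
        for rec in receptors:
            base = rng.uniform(lo, hi)
            offsets = np.sort(rng.uniform(0.0, 2.5, size=n_poses - 1)) if n_poses > 1 else []
            affs = [base] + [base + o for o in offsets]
            for i, a in enumerate(affs, start=1):
                poses.append(
                    DockingPose(
                        ligand=str(lig), receptor=str(rec),
                        pose_index=i, affinity=float(np.round(a, 3)),
                    )
                )
    return poses


def gen_energy_table(spec: SyntheticSpec) -> list[EnergyComponents]:
    """MM/PBSA component rows (base components only; totals left unset)."""
    ep = spec.energy_params
    rng = spec.rng("energy")
    rows = []
    for i in range(ep.n_complexes):
        rows.append(
            EnergyComponents(
                complex_id=f"complex_{i + 1}",
                vdw=float(np.round(rng.uniform(*ep.vdw_range), 2)),
                cou=float(np.round(rng.uniform(*ep.cou_range), 2)),
                pb=float(np.round(rng.uniform(*ep.pb_range), 2)),
                sa=float(np.round(rng.uniform(*ep.sa_range), 2)),
                minus_t_delta_s=float(np.round(rng.uniform(*ep.minus_t_delta_s_range), 2)),
            )
        )
    return rows
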