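"""Config-driven orchestration of the full synthetic-input pipeline.

``run_pipeline`` executes the stages in dependency order — compound
screening, target-set assembly, PPI centrality, enrichment,
heterogeneous-network ranking, docking post-processing and MD
post-processing — on synthetic inputs generated from one master seed,
writing per-stage text outputs plus a JSON manifest with the parameters
and a SHA-256 hash of every output file. Stage outputs are pure
functions of (config, seed): two runs with the same config produce
byte-identical outputs and therefore identical manifests.

Default thresholds encode the conventional screening values: OB >= 30,
DL >= 0.18, Caco-2 >= -0.4, >= 2 drug-likeness rules, DisGeNet >= 0.3,
GeneCards > 10, STRING > 0.9, adjusted p < 0.05 with top 20 pathways and
top 10 GO terms, docking classes at -5 / -7 kcal/mol, and the
0.2 nm / 5 ns trajectory-stability rule.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

from . import io as hio
from . import __version__
from .docking import best_complex_table, best_pose, classify_affinity
from .enrichment import run_ora
from .md import mmpbsa_totals, stability_assess, summarize_series, write_xvg
from .network import RelationTable, build_network, rank_by_degree, to_sif
from .ppi import compute_centralities, load_string_edges, select_key_targets
from .screen import merge_dedup, screen_swissadme, screen_tcmsp
from .synthetic import (
    PlantedTerm,
    SyntheticSpec,
    gen_annotations,
    gen_compound_table,
    gen_compound_target_pairs,
    gen_docking_poses,
    gen_energy_table,
    gen_ppi,
    gen_target_sets,
    gen_trajectory,
)
from .targets import TargetSet, intersect

STAGE_ORDER = ("screen", "targets", "ppi", "enrich", "network", "dock", "md")

#: stage -> stages whose outputs it consumes
STAGE_DEPS = {
    "screen": (),
    "targets": (),
    "ppi": ("targets",),
    "enrich": ("ppi",),
    "network": ("screen", "targets", "ppi", "enrich"),
    "dock": ("network",),
    "md": (),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {s: True for s in STAGE_ORDER},
    "synthetic": {
        "planted_terms": [
            {"term_id": "T0001", "effect": 0.9, "size": 40, "category": "KEGG"},
            {"term_id": "T0002", "effect": 0.8, "size": 30, "category": "BP"},
            {"term_id": "T0003", "effect": 0.8, "size": 25, "category": "CC"},
            {"term_id": "T0004", "effect": 0.8, "size": 25, "category": "MF"},
        ],
    },
    "thresholds": {
        "ob": 30.0,
        "dl": 0.18,
        "caco2": -0.4,
        "dl_flags_min": 2,
        "string_min": 0.9,
        "alpha": 0.05,
        "top_k_pathways": 20,
        "top_k_go": 10,
        "core_k": 10,
        "stability_threshold": 0.2,
        "stability_window": 5.0,
    },
}


class PipelineError(RuntimeError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def make_config(overrides: Optional[dict] = None, seed: Optional[int] = None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, overrides or {})
    if seed is not None:
        cfg["seed"] = seed
    return cfg


def _build_spec(cfg: dict) -> SyntheticSpec:
    syn = dict(cfg.get("synthetic", {}))
    planted = [PlantedTerm(**p) for p in syn.pop("planted_terms", [])]
    return SyntheticSpec(seed=cfg["seed"], planted_terms=planted, **syn)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Optional[dict] = None, outdir: Union[str, Path] = ".") -> dict:
    """Run the enabled stages on synthetic inputs; return the run manifest.

    The manifest records the seed, the effective configuration, stage
    summaries and a SHA-256 hash of every file written. It is also
    saved as ``manifest.json`` in ``outdir``.
    """
    cfg = make_config(config)
    stages = cfg["stages"]
    for stage in STAGE_ORDER:
        if not stages.get(stage, False):
            continue
        missing = [d for d in STAGE_DEPS[stage] if not stages.get(d, False)]
        if missing:
            raise PipelineError(
                f"stage {stage!r} requires disabled stage(s): {', '.join(missing)}"
            )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _build_spec(cfg)
    thr = cfg["thresholds"]
    manifest: dict = {
        "seed": cfg["seed"],
        "version": __version__,
        "config": cfg,
        "stages": {},
    }

    def record(stage: str, files: list[Path], **summary) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **summary,
        }

    state: dict = {}

    if stages.get("screen"):
        raw = gen_compound_table(spec)
        kept = merge_dedup(
            screen_tcmsp(raw, ob_min=thr["ob"], dl_min=thr["dl"], caco2_min=thr["caco2"]),
            screen_swissadme(raw, flags_min=thr["dl_flags_min"]),
        )
        f = outdir / "compounds.tsv"
        hio.write_compounds(f, kept)
        state["compounds"] = kept
        record("screen", [f], n_input=len(raw), n_kept=len(kept))

    if stages.get("targets"):
        compound_ts, disease_ts = gen_target_sets(spec)
        common, venn = intersect(compound_ts, disease_ts)
        f_common = outdir / "intersection_targets.txt"
        f_common.write_text("".join(f"{s}\n" for s in sorted(common.members)))
        f_venn = outdir / "venn_counts.json"
        f_venn.write_text(json.dumps(venn._asdict(), indent=2) + "\n")
        state.update(compound_targets=compound_ts, disease_targets=disease_ts,
                     intersection=common)
        record("targets", [f_common, f_venn],
               n_compound=len(compound_ts), n_disease=len(disease_ts),
               n_common=venn.common)

    if stages.get("ppi"):
        symbols = sorted(state["intersection"].members)
        g_full = gen_ppi(spec, nodes=symbols)
        f_edges = outdir / "ppi_edges.tsv"
        hio.write_edge_list(f_edges, g_full)
        g = load_string_edges(f_edges, min_score=thr["string_min"])
        table = compute_centralities(g)
        key = select_key_targets(table)
        f_cent = outdir / "centralities.tsv"
        table.to_csv(f_cent, sep="\t")
        f_key = outdir / "key_targets.txt"
        f_key.write_text("".join(f"{s}\n" for s in sorted(key)))
        state["key_targets"] = key
        record("ppi", [f_edges, f_cent, f_key],
               n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
               n_key_targets=len(key))

    if stages.get("enrich"):
        study = TargetSet.from_symbols(state["key_targets"], source="ppi")
        background = state["intersection"]
        collection = gen_annotations(spec, study=study, background=background)
        f_gmt = outdir / "annotations.gmt"
        hio.write_gmt(f_gmt, collection)
        results = []
        for category, top_k in (
            ("KEGG", thr["top_k_pathways"]),
            ("BP", thr["top_k_go"]),
            ("CC", thr["top_k_go"]),
            ("MF", thr["top_k_go"]),
        ):
            sub = [r for r in run_ora(study, collection, alpha=thr["alpha"],
                                      top_k=top_k)
                   if r.category == category]
            results.extend(sub)
        f_enr = outdir / "enrichment.tsv"
        hio.write_enrichment_results(f_enr, results)
        state["enrichment"] = results
        record("enrich", [f_gmt, f_enr], n_terms=len(collection.terms),
               n_significant=len(results))

    if stages.get("network"):
        compounds = [c.name for c in state["compounds"]]
        key = sorted(state["key_targets"])
        relations = [
            RelationTable("drug", "compound", [("HERB", c) for c in compounds]),
            RelationTable(
                "compound", "target",
                gen_compound_target_pairs(spec, compounds, key),
            ),
            RelationTable("disease", "target", [("DISEASE", t) for t in key]),
        ]
        pathway_pairs, function_pairs = [], []
        for r in state["enrichment"]:
            pairs = [(r.term_id, g) for g in sorted(r.hit_genes) if g in set(key)]
            if r.category == "KEGG":
                pathway_pairs.extend(pairs)
            else:
                function_pairs.append((f"function_{r.category}", pairs))
        if pathway_pairs:
            relations.append(RelationTable("pathway", "target", pathway_pairs))
        for ftype, pairs in function_pairs:
            if pairs:
                relations.append(RelationTable(ftype, "target", pairs))
        net = build_network(relations)
        f_sif = outdir / "network.sif"
        f_sif.write_text(to_sif(net))
        core_compounds = rank_by_degree(net, "compound", thr["core_k"])
        core_targets = rank_by_degree(net, "target", thr["core_k"])
        f_rank = outdir / "core_ranking.tsv"
        with open(f_rank, "w") as fh:
            fh.write("node\tnode_type\tdegree\n")
            for e in core_compounds + core_targets:
                fh.write(f"{e.node}\t{e.node_type}\t{e.degree}\n")
        state["core_compounds"] = [e.node for e in core_compounds]
        state["core_targets"] = [e.node for e in core_targets]
        record("network", [f_sif, f_rank],
               n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges())

    if stages.get("dock"):
        poses = gen_docking_poses(spec, state["core_compounds"], state["core_targets"])
        matrix = best_pose(poses)
        f_matrix = outdir / "affinity_matrix.tsv"
        matrix.to_csv(f_matrix, sep="\t")
        per_receptor, global_best = best_complex_table(matrix)
        f_best = outdir / "best_complexes.tsv"
        with open(f_best, "w") as fh:
            fh.write("receptor\tligand\taffinity\tclass\n")
            for c in per_receptor:
                fh.write(
                    f"{c.receptor}\t{c.ligand}\t{c.affinity:.3f}\t"
                    f"{classify_affinity(c.affinity)}\n"
                )
        record("dock", [f_matrix, f_best],
               n_poses=len(poses),
               global_best={"receptor": global_best.receptor,
                            "ligand": global_best.ligand,
                            "affinity": global_best.affinity})

    if stages.get("md"):
        traj = gen_trajectory(spec, label="complex_1_rmsd")
        f_xvg = outdir / "rmsd_complex_1.xvg"
        write_xvg(f_xvg, traj)
        call = stability_assess(traj, threshold=thr["stability_threshold"],
                                window=thr["stability_window"])
        summary: dict = {"stable": call.stable,
                         "equilibration_time_ns": call.equilibration_time}
        if call.stable:
            mean, sd = summarize_series(traj, from_time=call.equilibration_time)
            summary["rmsd_mean_nm"] = round(mean, 4)
            summary["rmsd_sd_nm"] = round(sd, 4)
        energies = mmpbsa_totals(gen_energy_table(spec))
        f_energy = outdir / "mmpbsa.tsv"
        hio.write_energy_components(f_energy, energies)
        f_md = outdir / "md_summary.json"
        f_md.write_text(json.dumps(summary, indent=2) + "\n")
        record("md", [f_xvg, f_energy, f_md], **summary)

    f_manifest = outdir / "manifest.json"
    f_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
    return manifest
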