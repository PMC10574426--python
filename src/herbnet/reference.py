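"""Bundled reference tables for the docking and MM/PBSA post-processing stages.

Two small published summary tables from a network-pharmacology study of
herbal flavonoids against rheumatoid-arthritis targets ship with the
package as worked-example inputs:

* ``reference_docking.tsv`` — the best AutoDock-Vina affinity
  (kcal/mol) per receptor, with the winning ligand and PDB structure;
* ``reference_mmpbsa.tsv`` — MM/PBSA energy components for five
  protein-ligand complexes (XT = Xuelianlactone-TNF,
  AT = Acacetin-TNF, IM = Involucratin-MAPK1, LM = Luteolin-MAPK1,
  FM = Flazin-MAPK8), including the printed totals so the bookkeeping
  can be validated against them.

They exercise :mod:`herbnet.docking` and :mod:`herbnet.md` end to end
without needing a docking engine or an MD trajectory.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .docking import DockingPose
from .md import EnergyComponents


def _data_path(name: str):
    return resources.files("herbnet.data").joinpath(name)


def load_reference_docking() -> pd.DataFrame:
    """Best-complex docking table: receptor, structure, chain, ligand, affinity."""
    with resources.as_file(_data_path("reference_docking.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reference_docking_poses() -> list[DockingPose]:
    """The reference affinities as single-pose records, one per receptor."""
    df = load_reference_docking()
    return [
        DockingPose(
            ligand=str(r.ligand),
            receptor=str(r.receptor),
            pose_index=1,
            affinity=float(r.affinity),
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_mmpbsa(with_totals: bool = False) -> list[EnergyComponents]:
    """MM/PBSA component rows for the five reference complexes.

    By default only the five base components are populated, leaving the
    totals for :func:`herbnet.md.mmpbsa_totals` to reconstruct; pass
    ``with_totals=True`` to also load the printed MM / dH / dG columns
    (e.g. for validation-mode checks).
    """
    with resources.as_file(_data_path("reference_mmpbsa.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            EnergyComponents(
                complex_id=str(r.complex),
                vdw=float(r.vdw),
                cou=float(r.cou),
                pb=float(r.pb),
                sa=float(r.sa),
                minus_t_delta_s=float(r.minus_t_delta_s),
                mm=float(r.mm) if with_totals else None,
                delta_h=float(r.delta_h) if with_totals else None,
                delta_g=float(r.delta_g) if with_totals else None,
            )
        )
    return rows
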