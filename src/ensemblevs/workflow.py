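"""End-to-end pipelines with configuration, logging and provenance.

Two suites compose the stage modules:

* the **trajectory suite** — metrics (RMSD/RMSF/convergence), conformational
  clustering, elastic-network modes, the weighted dynamic network with
  communities / critical nodes / optimal switch paths, and the
  protein-ligand contact profile;
* the **screening suite** — the reference-anchored filter cascade,
  selectivity deltas and (when structures are available) scaffold
  clustering.

Every run writes a ``manifest.json`` recording inputs, parameters, seeds,
package version and per-stage outputs, so reruns with identical
configuration are reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .core import LIGAND_NODE, InputError, Trajectory
from .ensemble import cluster_trajectory, elastic_network_modes, pairwise_rmsd_matrix
from .interactions import InteractionCriteria, interaction_fractions
from .io import write_ground_truth, write_multimodel_pdb, write_pdb
from .metrics import assess_convergence, rmsd_series, rmsf
from .network import (
    NetworkConfig,
    SwitchDefinition,
    build_network,
    contact_map,
    correlation_matrix,
    critical_nodes,
    detect_communities,
    optimal_path,
)
from .screening import (
    DrugLikenessRules,
    ReferenceCompound,
    apply_filter_cascade,
    scaffold_clusters,
    selectivity_deltas,
    survivors,
)
from .synthetic import (
    PlantedStructure,
    ToyReceptorSpec,
    generate_reference_structure,
    generate_trajectory,
    make_substates,
    two_block_partition,
)

log = logging.getLogger("ensemblevs")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage toggles and parameters; defaults are the study values
    (4.5 A / 75% contacts, 2 A merge cutoff, 2% abundance floor, 30%
    contact threshold, reference cutoffs -8.6 / -90.2 kcal/mol, <=1 star)."""

    seed: int = 0
    outdir: str = "ensemblevs_out"
    # synthetic inputs (used when no trajectory is supplied)
    n_residues: int = 24
    n_frames: int = 200
    occupancies: tuple = (0.75, 0.25)
    substate_separation: float = 5.0
    block_coupling: float = 0.9
    noise_sd: float = 0.1
    include_waters: bool = True
    # stage toggles
    run_metrics: bool = True
    run_cluster: bool = True
    run_modes: bool = True
    run_network: bool = True
    run_contacts: bool = True
    # stage parameters
    segment_fraction: float = 0.5       # last fraction of frames to cluster
    merge_cutoff: float = 2.0
    abundance_floor: float = 0.02
    spring_cutoff: float = 15.0
    n_modes: int = 10
    contact_cutoff: float = 4.5
    persistence: float = 0.75
    report_threshold: float = 0.30
    drift_tol: float = 0.3
    toggle_switch: int | None = None        # default: last protein residue
    transmission_switch: int | None = None  # default: 3/4 along the chain
    # screening parameters
    docking_reference: float = -8.6
    mmgbsa_reference: float = -90.2
    max_stars: int = 1
    similarity_cutoff: float = 0.7

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["occupancies"] = list(self.occupancies)
        return d


def _write_manifest(outdir: Path, config: PipelineConfig, stages: dict) -> None:
    manifest = {
        "package": "ensemblevs",
        "version": __version__,
        "config": config.to_dict(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def synthesize_inputs(config: PipelineConfig) -> Trajectory:
    """Default synthetic system: two-substate, two-block toy receptor."""
    spec = ToyReceptorSpec(
        n_residues=config.n_residues, include_waters=config.include_waters
    )
    structure = generate_reference_structure(spec, seed=config.seed)
    substates = make_substates(
        structure, list(config.occupancies),
        separation=config.substate_separation, seed=config.seed,
    )
    planted = PlantedStructure(
        substates=substates,
        correlation_blocks=two_block_partition(structure),
        block_coupling=config.block_coupling,
        noise_sd=config.noise_sd,
        ligand_block=1,
    )
    return generate_trajectory(structure, planted, config.n_frames, seed=config.seed + 1)


def run_trajectory_suite(config: PipelineConfig, traj: Trajectory | None = None) -> dict:
    """Run the post-simulation analyses; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if traj is None:
        traj = synthesize_inputs(config)
        write_pdb(traj.frame(0), outdir / "reference.pdb")
        write_multimodel_pdb(traj, outdir / "trajectory.pdb")
        write_ground_truth(traj, outdir / "ground_truth.json")
    stages: dict = {}

    def stage(name, enabled, fn):
        if not enabled:
            stages[name] = {"status": "skipped"}
            log.info("stage %s skipped", name)
            return None
        log.info("stage %s running", name)
        try:
            outputs = fn()
        except Exception as exc:  # halt, keep partial outputs
            stages[name] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, config, stages)
            raise StageError(name, exc) from exc
        stages[name] = {"status": "ok", "outputs": outputs}
        return outputs

    def _metrics():
        prot = rmsd_series(traj, reference=0, selection="protein_ca")
        lig = rmsd_series(traj, reference=0, selection="ligand_heavy",
                          fit_selection="protein_ca")
        pd.DataFrame({"frame": np.arange(traj.n_frames),
                      "protein_rmsd": prot.values,
                      "ligand_rmsd": lig.values}).to_csv(outdir / "rmsd.csv", index=False)
        rmsf(traj).rename("rmsf").to_csv(outdir / "rmsf.csv")
        rep = assess_convergence(prot, drift_tol=config.drift_tol)
        (outdir / "convergence.json").write_text(json.dumps(dataclasses.asdict(rep)))
        return ["rmsd.csv", "rmsf.csv", "convergence.json"]

    def _cluster():
        start = int(traj.n_frames * (1 - config.segment_fraction))
        segment = Trajectory(traj.topology, traj.coords[start:])
        mat = pairwise_rmsd_matrix(segment)
        cs = cluster_trajectory(mat, merge_cutoff=config.merge_cutoff,
                                abundance_floor=config.abundance_floor)
        rows = [dict(cluster=c, abundance=cs.abundances[c],
                     centroid_frame=start + cs.centroids[c]) for c in cs.reported]
        pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)
        outputs = ["clusters.csv"]
        for c in cs.reported:
            name = f"representative_{c}.pdb"
            write_pdb(traj.frame(start + cs.centroids[c]), outdir / name)
            outputs.append(name)
        return outputs

    def _modes():
        ms = elastic_network_modes(traj.frame(0), spring_cutoff=config.spring_cutoff,
                                   n_modes=config.n_modes)
        res = traj.frame(0).residue_ids()
        rows = []
        for m, (lam, vec) in enumerate(zip(ms.eigenvalues, ms.mode_vectors), start=1):
            for rid, v in zip(res, vec):
                rows.append(dict(mode=m, eigenvalue=lam, res_id=int(rid),
                                 dx=v[0], dy=v[1], dz=v[2]))
        pd.DataFrame(rows).to_csv(outdir / "modes.csv", index=False)
        return ["modes.csv"]

    def _network():
        cfg = NetworkConfig(contact_cutoff=config.contact_cutoff,
                            persistence=config.persistence)
        adjacency = contact_map(traj, cfg)
        order, c = correlation_matrix(traj, cfg)
        net = build_network(adjacency, order, c)
        rows = [dict(node_i=str(u), node_j=str(v), corr=d["corr"], weight=d["weight"])
                for u, v, d in net.edges(data=True)]
        pd.DataFrame(rows).to_csv(outdir / "network_edges.csv", index=False)
        nx.write_graphml(nx.relabel_nodes(net, {n: str(n) for n in net}),
                         outdir / "network.graphml")
        part = detect_communities(net)
        pd.DataFrame(
            [dict(node=str(n), community=cid) for n, cid in sorted(
                part.community.items(), key=lambda kv: str(kv[0]))]
        ).to_csv(outdir / "communities.csv", index=False)
        pd.DataFrame({"critical_node": [str(n) for n in part.critical_nodes]}).to_csv(
            outdir / "critical_nodes.csv", index=False)
        res = traj.topology.residue_ids()
        switches = SwitchDefinition(
            toggle_switch=config.toggle_switch or int(res[-1]),
            transmission_switch=config.transmission_switch or int(res[3 * len(res) // 4]),
        )
        paths = {}
        for label, target in (("toggle_switch", switches.toggle_switch),
                              ("transmission_switch", switches.transmission_switch)):
            p = optimal_path(net, LIGAND_NODE, target)
            paths[label] = dict(target=target, found=p.found,
                                nodes=[str(n) for n in p.nodes],
                                total_weight=p.total_weight if p.found else None)
        (outdir / "paths.json").write_text(json.dumps(paths, indent=1))
        return ["network_edges.csv", "network.graphml", "communities.csv",
                "critical_nodes.csv", "paths.json"]

    def _contacts():
        criteria = InteractionCriteria(report_threshold=config.report_threshold)
        profile = interaction_fractions(traj, criteria)
        profile.fractions.to_csv(outdir / "contacts.csv", index=False)
        profile.flagged_residues().to_csv(outdir / "contacts_summary.csv", index=False)
        return ["contacts.csv", "contacts_summary.csv"]

    stage("metrics", config.run_metrics, _metrics)
    stage("cluster", config.run_cluster, _cluster)
    stage("modes", config.run_modes, _modes)
    stage("network", config.run_network, _network)
    stage("contacts", config.run_contacts, _contacts)
    _write_manifest(outdir, config, stages)
    return {"outdir": str(outdir), "stages": stages}


def run_screening_suite(config: PipelineConfig, table: pd.DataFrame | None = None,
                        selectivity: pd.DataFrame | None = None) -> dict:
    """Run the triage cascade (and selectivity/scaffolds when inputs allow)."""
    from . import datasets

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    if table is None:
        table = datasets.load_top8_screening()
        table = table[table["compound_id"] != datasets.REFERENCE_ID].reset_index(drop=True)
    reference = ReferenceCompound("reference", config.docking_reference,
                                  config.mmgbsa_reference)
    rules = DrugLikenessRules(max_stars=config.max_stars)

    required = ["compound_id", "docking_score", "mmgbsa_total", "gi_absorption",
                "bbb_permeant", "pains_alerts", "brenk_alerts"]
    errors = []
    ok_mask = []
    for i, row in table.iterrows():
        bad = [c for c in required if c not in table.columns or pd.isna(row.get(c))]
        ok_mask.append(not bad)
        if bad:
            errors.append(dict(row=int(i), compound_id=str(row.get("compound_id")),
                               missing=bad))
    clean = table[np.array(ok_mask, dtype=bool)].reset_index(drop=True)
    if errors:
        (outdir / "row_errors.json").write_text(json.dumps(errors, indent=1))
        log.warning("%d malformed row(s) set aside", len(errors))
    if len(clean) == 0 and len(table) > 0:
        raise InputError("all rows malformed")

    cascade = apply_filter_cascade(clean, reference, rules)
    cascade.to_csv(outdir / "cascade.csv", index=False)
    survivors(cascade).to_csv(outdir / "survivors.csv", index=False)
    stages["cascade"] = {"status": "ok",
                         "outputs": ["cascade.csv", "survivors.csv"],
                         "n_survivors": int(cascade["survives"].sum())}

    if selectivity is None:
        selectivity = datasets.load_selectivity_scores()
    sel = selectivity_deltas(selectivity)
    sel.per_compound.to_csv(outdir / "selectivity.csv", index=False)
    (outdir / "selectivity_averages.json").write_text(json.dumps(
        dict(original=sel.original_average, scores=sel.score_averages,
             deltas=sel.delta_averages), indent=1))
    stages["selectivity"] = {"status": "ok",
                             "outputs": ["selectivity.csv", "selectivity_averages.json"]}

    if "smiles" in table.columns:
        ids = scaffold_clusters(table["smiles"].tolist(), config.similarity_cutoff)
        pd.DataFrame({"compound_id": table["compound_id"],
                      "scaffold_cluster": ids}).to_csv(outdir / "scaffolds.csv", index=False)
        stages["scaffolds"] = {"status": "ok", "outputs": ["scaffolds.csv"]}
    else:
        stages["scaffolds"] = {"status": "skipped"}
    _write_manifest(outdir, config, stages)
    return {"outdir": str(outdir), "stages": stages}
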