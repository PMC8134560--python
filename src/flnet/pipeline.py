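"""End-to-end pipeline: simulate → activation → networks → common → k-shell → SSE.

``analyze_subject`` is the reusable per-scan unit; ``run_synthetic_study``
orchestrates a whole multi-group synthetic study, writing each stage's
output before the next starts and finishing with a manifest that suffices
to reproduce every output bit-identically (given the same code version).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import __version__
from . import io as fio
from .activation import ActivationMap, SubjectScan, cluster_threshold, hrf_regressor
from .config import AnalysisConfig, SyntheticConfig, ValidationError
from .group import CommonNetwork, build_common_network, detect_structures, rank_links
from .kshell import (
    ShellAssignment,
    kshell_decomposition,
    pooled_group_histograms,
    sse_between_groups,
)
from .networks import LabelMap, VoxelNetwork, build_voxel_network, label_frois, region_network, voxel_correlations
from .simulate import GroupData, simulate_group

__all__ = ["SubjectResult", "GroupResult", "StudyResult", "analyze_subject", "analyze_group", "run_synthetic_study"]

log = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    subject_id: str
    activation: ActivationMap
    voxel_net: VoxelNetwork | None
    region_net: nx.Graph | None
    shells: ShellAssignment | None

    @property
    def modules(self) -> dict[int, str]:
        if self.voxel_net is None:
            return {}
        return {n: d["region"] for n, d in self.voxel_net.graph.nodes(data=True)}


@dataclass
class GroupResult:
    group: str
    subjects: list[SubjectResult]
    common: CommonNetwork
    structures: object
    hierarchy: list

    @property
    def region_nets(self) -> list[nx.Graph]:
        return [s.region_net for s in self.subjects if s.region_net is not None]


@dataclass
class StudyResult:
    groups: dict[str, GroupResult]
    histograms: dict
    sse: dict
    manifest: dict = field(default_factory=dict)


def analyze_subject(
    scan: SubjectScan, label_map: LabelMap, cfg: AnalysisConfig
) -> SubjectResult:
    """Activation map → fROI labeling → voxel network → region network → shells.

    Subjects whose activation map is empty (or has a single voxel) yield
    ``None`` networks; the group stage treats them as contributing no links.
    """
    regressor = hrf_regressor(scan.paradigm, cfg)
    amap = cluster_threshold(scan, regressor, cfg)
    nodes = label_frois(amap.active, label_map, cfg.connectivity)
    if nodes.n_nodes < 2:
        log.warning("subject %s: %d active nodes; no network built", scan.subject_id, nodes.n_nodes)
        return SubjectResult(scan.subject_id, amap, None, None, None)
    C = voxel_correlations(scan, nodes.coords)
    vnet = build_voxel_network(C, nodes, cfg.corr_threshold)
    rnet = region_network(vnet)
    shells = kshell_decomposition(vnet.graph) if vnet.graph.number_of_edges() else None
    return SubjectResult(scan.subject_id, amap, vnet, rnet, shells)


def analyze_group(
    subjects: Sequence[SubjectResult],
    cfg: AnalysisConfig,
    roles: Mapping[str, str],
    group: str = "",
) -> GroupResult:
    nets = [s.region_net if s.region_net is not None else nx.Graph() for s in subjects]
    common = build_common_network(nets, cfg.common_retention, group)
    structures = detect_structures(nets, roles, group)
    hierarchy = rank_links(common, roles)
    return GroupResult(group, list(subjects), common, structures, hierarchy)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_synthetic_study(
    synthetic: SyntheticConfig,
    analysis: AnalysisConfig,
    groups: Mapping[str, Mapping],
    roles: Mapping[str, str],
    outdir: str | Path | None = None,
    save_scans: bool = False,
) -> StudyResult:
    """Run the full pipeline on simulated groups; optionally write all stages.

    ``groups`` maps group name to ``{"n_subjects": int, "group_seed": int,
    "dropout": {subject_index: (region, ...)}}``.  When ``outdir`` is given,
    every stage's tables are written as they complete, then a manifest.
    Output tables carry the joint config hash so outputs from different
    configurations cannot be silently mixed.
    """
    synthetic.validate()
    analysis.validate()
    outdir = Path(outdir) if outdir is not None else None
    cfg_hash = hashlib.sha256(
        (synthetic.to_json() + analysis.to_json()).encode()
    ).hexdigest()[:16]

    written: dict[str, str] = {}
    group_results: dict[str, GroupResult] = {}
    per_group_assignments: dict[str, list] = {}
    group_data: dict[str, GroupData] = {}

    for name, spec in groups.items():
        gd = simulate_group(
            synthetic,
            int(spec["n_subjects"]),
            int(spec["group_seed"]),
            dict(spec.get("dropout", {})),
            group=name,
        )
        group_data[name] = gd
        subj_results: list[SubjectResult] = []
        assignments = []
        for sd in gd.subjects:
            res = analyze_subject(sd.scan, sd.label_map, analysis)
            subj_results.append(res)
            if res.shells is not None:
                assignments.append((res.shells, res.modules))
            if outdir is not None:
                sdir = outdir / name / res.subject_id
                sdir.mkdir(parents=True, exist_ok=True)
                if save_scans:
                    p = fio.write_scan(sd.scan, sdir / "bold.nii.gz")
                    written[str(p)] = _sha256(p)
                    p = fio.write_label_map(sd.label_map, sdir / "labels.nii.gz", sd.scan.voxel_size_mm)
                    written[str(p)] = _sha256(p)
                for p in fio.write_activation_map(res.activation, sdir, sd.scan.voxel_size_mm, cfg_hash).values():
                    written[str(p)] = _sha256(p)
                if res.voxel_net is not None:
                    for p in fio.write_voxel_network(res.voxel_net, sdir, cfg_hash).values():
                        written[str(p)] = _sha256(p)
                    p = fio.write_region_network(res.region_net, sdir / "region_network.tsv", cfg_hash)
                    written[str(p)] = _sha256(p)
        gres = analyze_group(subj_results, analysis, roles, name)
        group_results[name] = gres
        per_group_assignments[name] = assignments
        if outdir is not None:
            gdir = outdir / name
            gdir.mkdir(parents=True, exist_ok=True)
            p = fio.write_region_network(gres.common.graph, gdir / "common_network.tsv", cfg_hash)
            written[str(p)] = _sha256(p)
            report = {
                "structures": gres.structures.to_dict(),
                "hierarchy": [
                    {
                        "label": r.label,
                        "regions": list(r.regions),
                        "W_common": r.weight,
                        "present": r.present,
                        "tied_with": list(r.tied_with),
                    }
                    for r in gres.hierarchy
                ],
            }
            p = fio.write_json(report, gdir / "structure_report.json")
            written[str(p)] = _sha256(p)

    hists = pooled_group_histograms(per_group_assignments, analysis.n_bins)
    sse = sse_between_groups(hists)

    if outdir is not None:
        hist_obj = {
            g: {
                m: {"counts": h.counts, "masses": h.masses, "n_bins": h.n_bins}
                for m, h in mods.items()
            }
            for g, mods in hists.items()
        }
        p = fio.write_json(hist_obj, outdir / "occupancy_histograms.json")
        written[str(p)] = _sha256(p)
        sse_obj = [
            {"module": m, "group_1": g1, "group_2": g2, "sse": v}
            for (m, (g1, g2)), v in sorted(sse.items())
        ]
        p = fio.write_json(
            {"normalized": True, "pairs": sse_obj}, outdir / "sse_report.json"
        )
        written[str(p)] = _sha256(p)

    manifest = {
        "flnet_version": __version__,
        "config_hash": cfg_hash,
        "analysis_config": analysis.to_json(),
        "synthetic_config": synthetic.to_json(),
        "roles": dict(roles),
        "groups": {
            name: {
                "n_subjects": int(spec["n_subjects"]),
                "group_seed": int(spec["group_seed"]),
                "dropout": {str(k): list(v) for k, v in dict(spec.get("dropout", {})).items()},
                "subject_seeds": group_data[name].subject_seeds,
            }
            for name, spec in groups.items()
        },
        "outputs": dict(sorted(written.items())),
    }
    if outdir is not None:
        fio.write_json(manifest, outdir / "manifest.json")
    return StudyResult(group_results, hists, sse, manifest)


def rerun_from_manifest(manifest: Mapping, outdir: str | Path) -> StudyResult:
    """Re-execute a study from its manifest (determinism check / reproduction)."""
    synthetic = SyntheticConfig.from_json(manifest["synthetic_config"])
    analysis = AnalysisConfig.from_json(manifest["analysis_config"])
    groups = {
        name: {
            "n_subjects": g["n_subjects"],
            "group_seed": g["group_seed"],
            "dropout": {int(k): tuple(v) for k, v in g.get("dropout", {}).items()},
        }
        for name, g in manifest["groups"].items()
    }
    return run_synthetic_study(synthetic, analysis, groups, manifest["roles"], outdir)
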