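"""File-format round-tripping: NIfTI volumes, TSV tables, JSON, GraphML.

Voxel coordinates are 0-based grid indices throughout; physical-space
coordinates appear only in the NIfTI affine (a diagonal scaling by the
voxel size).  Floating-point table output uses a fixed ``%.10g`` format so
reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .activation import ActivationMap, SubjectScan
from .config import TaskParadigm, ValidationError
from .networks import LabelMap, VoxelNetwork

__all__ = [
    "read_scan",
    "write_scan",
    "read_label_map",
    "write_label_map",
    "write_volume",
    "write_activation_map",
    "write_voxel_network",
    "write_region_network",
    "write_json",
]

FLOAT_FMT = "%.10g"


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def _check_orientation(img: nib.Nifti1Image) -> float:
    affine = img.affine
    scales = np.diag(affine)[:3]
    off_diag = affine[:3, :3] - np.diag(scales)
    if np.any(np.abs(off_diag) > 1e-6) or np.any(scales <= 0):
        raise ValidationError(
            "unsupported NIfTI orientation: only axis-aligned positive-scale volumes are handled"
        )
    if not np.allclose(scales, scales[0], rtol=1e-6):
        raise ValidationError("anisotropic voxels are not supported")
    return float(scales[0])


def write_volume(volume: np.ndarray, path: str | Path, voxel_size_mm: float = 1.0) -> Path:
    """Write a 3D or 4D array as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume), _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if volume.ndim == 4 else ()))
    nib.save(img, path)
    return path


def write_scan(scan: SubjectScan, path: str | Path) -> Path:
    return write_volume(scan.data, path, scan.voxel_size_mm)


def read_scan(path: str | Path, paradigm: TaskParadigm, subject_id: str = "", group_id: str = "") -> SubjectScan:
    """Read a 4D NIfTI scan; the time axis must match the paradigm."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4D scan, got {data.ndim}D")
    voxel = _check_orientation(img)
    return SubjectScan(data, voxel, paradigm, subject_id, group_id)


def write_label_map(label_map: LabelMap, path: str | Path, voxel_size_mm: float = 1.0) -> Path:
    """Write the label volume as NIfTI plus a sidecar JSON name table."""
    path = Path(path)
    write_volume(label_map.labels.astype(np.int32), path, voxel_size_mm)
    sidecar = {
        "names": {str(k): v for k, v in sorted(label_map.names.items())},
        "excluded": sorted(label_map.excluded),
    }
    path.with_suffix("").with_suffix(".labels.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1)
    )
    return path


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    sidecar_path = path.with_suffix("").with_suffix(".labels.json")
    if not sidecar_path.exists():
        raise ValidationError(f"label name table {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    return LabelMap(
        data.astype(np.int32),
        {int(k): v for k, v in sidecar["names"].items()},
        frozenset(int(v) for v in sidecar["excluded"]),
    )


def _to_tsv(df: pd.DataFrame, path: Path, config_hash: str | None) -> Path:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def tsv_config_hash(path: str | Path) -> str | None:
    """Config hash recorded in a table header, if any."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        return first.split("=", 1)[1].strip()
    return None


def write_activation_map(
    amap: ActivationMap, outdir: str | Path, voxel_size_mm: float, config_hash: str | None = None
) -> dict[str, Path]:
    """Export r/p/mask volumes plus the cluster table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "r": write_volume(amap.r, outdir / "stat_r.nii.gz", voxel_size_mm),
        "p": write_volume(amap.p, outdir / "stat_p.nii.gz", voxel_size_mm),
        "active": write_volume(amap.active.astype(np.uint8), outdir / "active_mask.nii.gz", voxel_size_mm),
        "clusters": _to_tsv(amap.cluster_table(), outdir / "clusters.tsv", config_hash),
    }
    return paths


def write_voxel_network(net: VoxelNetwork, outdir: str | Path, config_hash: str | None = None) -> dict[str, Path]:
    """Edge list + node table TSVs and a GraphML export."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = net.nodes
    node_df = pd.DataFrame(
        {
            "node": np.arange(nodes.n_nodes),
            "x": nodes.coords[:, 0],
            "y": nodes.coords[:, 1],
            "z": nodes.coords[:, 2],
            "froi": nodes.froi_id,
            "region": [nodes.region_of(i) for i in range(nodes.n_nodes)],
        }
    )
    edges = sorted((min(u, v), max(u, v), d["C"]) for u, v, d in net.graph.edges(data=True))
    edge_df = pd.DataFrame(edges, columns=["node_a", "node_b", "C"])
    paths = {
        "nodes": _to_tsv(node_df, outdir / "voxel_nodes.tsv", config_hash),
        "edges": _to_tsv(edge_df, outdir / "voxel_edges.tsv", config_hash),
    }
    gml = outdir / "voxel_network.graphml"
    export = net.graph.copy()
    for _, d in export.nodes(data=True):
        d["coord"] = ",".join(str(v) for v in d["coord"])  # GraphML has no tuples
    nx.write_graphml(export, gml, named_key_ids=True)
    paths["graphml"] = gml
    return paths


def write_region_network(graph: nx.Graph, path: str | Path, config_hash: str | None = None) -> Path:
    """Region-scale (or common) weighted network as a TSV edge table.

    Emits whichever edge attributes the graph carries (``W`` and
    ``cross_edges`` for subject networks; ``W_common``, ``f`` and
    ``retained`` for common networks).
    """
    attr_keys = sorted({k for _, _, d in graph.edges(data=True) for k in d})
    rows = sorted(
        [min(u, v), max(u, v)] + [d.get(k, "") for k in attr_keys]
        for u, v, d in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["region_i", "region_j"] + attr_keys)
    return _to_tsv(df, Path(path), config_hash)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)}")
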