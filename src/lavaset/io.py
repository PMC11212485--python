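"""Text-based readers/writers: feature tables, distances, coordinates,
neighbourhood maps, importance tables, and JSON model persistence.

All matrix I/O is UTF-8 CSV/TSV with '.' decimal.  Model files are a single
versioned JSON document holding the fit config, the neighbourhood map, every
tree (nested nodes with their full split records), the merged ledger and the
class ordering — enough to reproduce predictions and the importance report
exactly, and byte-stable for a given fitted forest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import LavasetForest
from .importance import TreeLedger
from .latent_tree import FitConfig, LatentSplitRecord, TreeNode
from .neighborhoods import NeighborhoodMap

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_distance_csv",
    "read_coords_csv",
    "write_coords_csv",
    "write_neighborhood_map",
    "read_neighborhood_map",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def read_feature_table(
    path, labels_col: str | None = None, delimiter: str | None = None
):
    """Read a samples x features table.

    Returns ``(X, y, feature_ids, sample_ids)``; ``y`` is None when no label
    column is given.  The first column is used as the sample identifier.
    Raises on non-numeric cells (naming the offending row/column) and on
    duplicate feature identifiers.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    import csv

    with open(path, encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter=delimiter))
    body_cols = [c for c in header[1:] if c != labels_col]
    if len(set(body_cols)) != len(body_cols):
        dupes = sorted({c for c in body_cols if body_cols.count(c) > 1})
        raise ValueError(f"duplicate feature ids in {path}: {dupes[:5]}")
    df = pd.read_csv(path, sep=delimiter, index_col=0,
                     float_precision="round_trip")
    y = None
    if labels_col is not None:
        if labels_col not in df.columns:
            raise ValueError(f"label column {labels_col!r} not found in {path}")
        y = df[labels_col].to_numpy()
        df = df.drop(columns=[labels_col])
    feature_ids = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    X = numeric.to_numpy(dtype=float)
    sample_ids = [str(i) for i in df.index]
    return X, y, feature_ids, sample_ids


def write_feature_table(path, X, y=None, feature_ids=None, sample_ids=None,
                        labels_col: str = "label", delimiter: str | None = None):
    """Write a samples x features table readable by :func:`read_feature_table`."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    X = np.asarray(X)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"),
                      columns=feature_ids)
    if y is not None:
        df.insert(0, labels_col, np.asarray(y))
    df.to_csv(path, sep=delimiter)


def read_distance_csv(path, delimiter: str = ",") -> tuple[np.ndarray, list[str]]:
    """Read a square feature x feature distance matrix with id header row/col."""
    df = pd.read_csv(path, sep=delimiter, index_col=0,
                     float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError("distance matrix row and column identifiers differ")
    return df.to_numpy(dtype=float), ids


def read_coords_csv(path, delimiter: str = ",") -> np.ndarray:
    """Read per-sample 3D coordinates (columns sample_id, point_id, x, y, z).

    Returns an array of shape (n_samples, n_points, 3); every sample block
    must share the same point count.
    """
    df = pd.read_csv(path, sep=delimiter)
    required = {"sample_id", "point_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates file must have columns {sorted(required)}")
    blocks = []
    point_counts = set()
    for _, block in df.groupby("sample_id", sort=True):
        block = block.sort_values("point_id")
        blocks.append(block[["x", "y", "z"]].to_numpy(dtype=float))
        point_counts.add(len(block))
    if len(point_counts) != 1:
        raise ValueError(f"coordinate blocks have mismatched point counts: {sorted(point_counts)}")
    return np.stack(blocks)


def write_coords_csv(path, coords: np.ndarray, delimiter: str = ",") -> None:
    coords = np.asarray(coords)
    n_samples, n_points, _ = coords.shape
    rows = {
        "sample_id": np.repeat(np.arange(n_samples), n_points),
        "point_id": np.tile(np.arange(n_points), n_samples),
        "x": coords[:, :, 0].ravel(),
        "y": coords[:, :, 1].ravel(),
        "z": coords[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_neighborhood_map(path, nmap: NeighborhoodMap, feature_ids=None) -> None:
    """One line per feature: feature_id then member ids, tab-separated."""
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(len(nmap))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#source={nmap.source}\tk={nmap.k}\n")
        for f in range(len(nmap)):
            ids = "\t".join(str(int(m)) for m in nmap[f])
            fh.write(f"{feature_ids[f]}\t{ids}\n")


def read_neighborhood_map(path) -> NeighborhoodMap:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#source="):
            raise ValueError("missing neighbourhood-map header line")
        fields = dict(part.split("=", 1) for part in header[1:].split("\t"))
        members = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            members.append(np.asarray([int(v) for v in parts[1:]], dtype=np.intp))
    nmap = NeighborhoodMap(tuple(members), k=int(fields["k"]), source=fields["source"])
    nmap.validate()
    return nmap


def _split_to_dict(s: LatentSplitRecord) -> dict:
    return {
        "foi": s.foi,
        "members": [int(v) for v in s.members],
        "center": [float(v) for v in s.center],
        "scale": [float(v) for v in s.scale],
        "projection": [float(v) for v in s.projection],
        "loadings": [float(v) for v in s.loadings],
        "threshold": s.threshold,
        "gain": s.gain,
        "constant_members": [bool(v) for v in s.constant_members],
    }


def _split_from_dict(d: dict) -> LatentSplitRecord:
    return LatentSplitRecord(
        foi=int(d["foi"]),
        members=np.asarray(d["members"], dtype=np.intp),
        center=np.asarray(d["center"], dtype=float),
        scale=np.asarray(d["scale"], dtype=float),
        projection=np.asarray(d["projection"], dtype=float),
        loadings=np.asarray(d["loadings"], dtype=float),
        threshold=float(d["threshold"]),
        gain=float(d["gain"]),
        constant_members=np.asarray(d["constant_members"], dtype=bool),
    )


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"leaf": True, "label": int(node.label),
                "counts": [int(v) for v in node.counts]}
    return {
        "leaf": False,
        "split": _split_to_dict(node.split),
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if d["leaf"]:
        return TreeNode(label=int(d["label"]), counts=np.asarray(d["counts"], dtype=np.int64))
    return TreeNode(
        split=_split_from_dict(d["split"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def save_model(path, forest: LavasetForest) -> None:
    """Serialize a fitted forest to a versioned JSON document."""
    cfg = forest.cfg
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "n_trees": cfg.n_trees,
            "k_neighbors": cfg.k_neighbors,
            "max_features": cfg.max_features,
            "bootstrap": cfg.bootstrap,
            "rng_seed": cfg.rng_seed,
            "min_samples_split": cfg.min_samples_split,
            "max_depth": cfg.max_depth,
        },
        "n_features": forest.n_features,
        "class_labels": [_json_label(c) for c in forest.class_labels.tolist()],
        "tree_seeds": [int(s) for s in forest.tree_seeds],
        "neighborhood_map": {
            "source": forest.nmap.source,
            "k": forest.nmap.k,
            "members": [[int(m) for m in mem] for mem in forest.nmap.members],
        },
        "ledger": {
            "evaluated": [int(v) for v in forest.ledger.evaluated],
            "selected": [int(v) for v in forest.ledger.selected],
            "gini": [float(v) for v in forest.ledger.gini],
        },
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def _json_label(c):
    if isinstance(c, (np.integer,)):
        return int(c)
    if isinstance(c, (np.floating,)):
        return float(c)
    return c


def load_model(path) -> LavasetForest:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    c = doc["config"]
    cfg = FitConfig(
        n_trees=c["n_trees"],
        k_neighbors=c["k_neighbors"],
        max_features=c["max_features"],
        bootstrap=c["bootstrap"],
        rng_seed=c["rng_seed"],
        min_samples_split=c["min_samples_split"],
        max_depth=c["max_depth"],
    )
    nm = doc["neighborhood_map"]
    nmap = NeighborhoodMap(
        tuple(np.asarray(m, dtype=np.intp) for m in nm["members"]),
        k=int(nm["k"]),
        source=nm["source"],
    )
    ledger = TreeLedger(doc["n_features"])
    ledger.evaluated[:] = doc["ledger"]["evaluated"]
    ledger.selected[:] = doc["ledger"]["selected"]
    ledger.gini[:] = doc["ledger"]["gini"]
    return LavasetForest(
        trees=[_node_from_dict(t) for t in doc["trees"]],
        cfg=cfg,
        nmap=nmap,
        ledger=ledger,
        class_labels=np.asarray(doc["class_labels"]),
        tree_seeds=[int(s) for s in doc["tree_seeds"]],
        n_features=int(doc["n_features"]),
    )
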