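"""CSV schemas, graph/model serialization and run manifests.

Two cell-table schemas are supported:

- simulated: ``id,q,CentroidX,CentroidY[,CentroidZ],fate`` (2D or 3D is
  inferred from the presence of CentroidZ); multi-tissue files carry an
  extra ``tissue_id`` column;
- experimental: ``organoid_id,stage,batch,CentroidX,CentroidY,CentroidZ,
  NANOG,GATA6`` with an optional ground-truth ``class`` column.

All files are UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fatepattern.cellgraph import CellGraph
from fatepattern.tissue_sim import Tissue

__all__ = [
    "read_cells",
    "write_cells",
    "tissues_to_frame",
    "frame_to_tissues",
    "save_graph",
    "load_graph",
    "save_recognizer",
    "load_recognizer",
    "write_manifest",
]

_SIM_REQUIRED = ["id", "q", "CentroidX", "CentroidY", "fate"]
_EXP_REQUIRED = ["organoid_id", "stage", "batch", "CentroidX", "CentroidY",
                 "CentroidZ", "NANOG", "GATA6"]


def read_cells(path, kind: str = "simulated") -> pd.DataFrame:
    """Read and validate a cell table of the given schema.

    Raises ``ValueError`` naming any missing column, non-numeric
    coordinates or duplicated cell ids.
    """
    if kind not in ("simulated", "experimental"):
        raise ValueError(f"kind must be 'simulated' or 'experimental', got {kind!r}")
    df = pd.read_csv(path)
    required = list(_SIM_REQUIRED if kind == "simulated" else _EXP_REQUIRED)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    coord_cols = [c for c in ("CentroidX", "CentroidY", "CentroidZ") if c in df.columns]
    for c in coord_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric values in column {c!r}")
        df[c] = vals
    if kind == "simulated":
        group = ["tissue_id"] if "tissue_id" in df.columns else []
        dup = df.duplicated(subset=group + ["id"]) if group else df["id"].duplicated()
        if bool(np.asarray(dup).any()):
            raise ValueError(f"{path}: duplicate cell ids")
    return df


def write_cells(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(df).to_csv(path, index=False)


def tissues_to_frame(tissues: list[Tissue]) -> pd.DataFrame:
    """Flatten simulated tissues into one simulated-schema table with a
    ``tissue_id`` column."""
    frames = []
    for t in tissues:
        if t.fates is None:
            raise ValueError("tissue has no fates; run the fate dynamics first")
        rec = {
            "tissue_id": t.tissue_id,
            "id": np.arange(t.n_cells),
            "q": t.q,
            "CentroidX": t.pos[:, 0],
            "CentroidY": t.pos[:, 1],
        }
        if t.dim == 3:
            rec["CentroidZ"] = t.pos[:, 2]
        rec["fate"] = t.fates
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def frame_to_tissues(df: pd.DataFrame) -> list[Tissue]:
    """Rebuild Tissue objects from a simulated-schema table."""
    dim = 3 if "CentroidZ" in df.columns else 2
    cols = ["CentroidX", "CentroidY"] + (["CentroidZ"] if dim == 3 else [])
    out = []
    groups = df.groupby("tissue_id") if "tissue_id" in df.columns else [(0, df)]
    for tid, sub in groups:
        out.append(Tissue(
            pos=sub[cols].to_numpy(float),
            radii=np.ones(len(sub)),
            dim=dim,
            fates=sub["fate"].to_numpy(int),
            q=float(sub["q"].iloc[0]) if "q" in sub.columns else None,
            tissue_id=int(tid),
        ))
    return out


# -- graph serialization ----------------------------------------------------

def save_graph(graph: CellGraph, prefix) -> None:
    """Write a graph as ``<prefix>_edges.csv`` (src,dst,weight),
    ``<prefix>_nodes.csv`` (id,fate) and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "src": graph.edges[:, 0], "dst": graph.edges[:, 1],
        "weight": graph.edge_weights,
    }).to_csv(f"{prefix}_edges.csv", index=False)
    pd.DataFrame({
        "id": graph.node_ids, "fate": graph.node_features[:, 0],
    }).to_csv(f"{prefix}_nodes.csv", index=False)
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump({"n": graph.n, "label_q": graph.label, "kind": graph.kind,
                   "threshold": graph.threshold}, fh, indent=2)


def load_graph(prefix) -> CellGraph:
    edges = pd.read_csv(f"{prefix}_edges.csv")
    nodes = pd.read_csv(f"{prefix}_nodes.csv")
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    return CellGraph(
        node_ids=nodes["id"].to_numpy(),
        node_features=nodes["fate"].to_numpy(float)[:, None],
        edges=edges[["src", "dst"]].to_numpy(int),
        edge_weights=edges["weight"].to_numpy(float),
        label=meta["label_q"], kind=meta["kind"], threshold=meta["threshold"],
    )


# -- model serialization ----------------------------------------------------

def save_recognizer(model, report, out_dir) -> None:
    """Model directory: one CSV per weight tensor, architecture/config JSON
    and the per-epoch training log."""
    from fatepattern.recognition import RecognizerModel

    assert isinstance(model, RecognizerModel)
    out = Path(out_dir)
    (out / "weights").mkdir(parents=True, exist_ok=True)
    for name, arr in model.params.items():
        np.savetxt(out / "weights" / f"{name}.csv", np.atleast_2d(arr), delimiter=",")
    cfg = model.cfg.__dict__.copy()
    with open(out / "architecture.json", "w") as fh:
        json.dump({k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()},
                  fh, indent=2)
    if report is not None:
        pd.DataFrame(report.history).to_csv(out / "training_log.csv", index=False)


def load_recognizer(out_dir):
    from fatepattern.recognition import RecognizerModel, RecogTrainConfig

    out = Path(out_dir)
    with open(out / "architecture.json") as fh:
        raw = json.load(fh)
    for key in ("channels", "activations", "dense_head", "split"):
        raw[key] = tuple(raw[key])
    cfg = RecogTrainConfig(**raw)
    model = RecognizerModel(cfg)
    for name in model.params:
        arr = np.loadtxt(out / "weights" / f"{name}.csv", delimiter=",", ndmin=2)
        model.params[name] = arr.reshape(model.params[name].shape).astype(np.float32)
    model.trained = True
    return model


def save_imputer(model, out_dir, k: int, n_classes: int) -> None:
    """Imputer model directory: per-tensor CSVs plus a config JSON recording
    the neighbour count and output width."""
    out = Path(out_dir)
    (out / "weights").mkdir(parents=True, exist_ok=True)
    for name, arr in model.params.items():
        np.savetxt(out / "weights" / f"{name}.csv", np.atleast_2d(arr), delimiter=",")
    hidden = [model.params[f"W{i}"].shape[1] for i in range(model.n_layers - 1)]
    with open(out / "config.json", "w") as fh:
        json.dump({"in_dim": int(model.params["W0"].shape[0]),
                   "hidden": hidden, "n_classes": model.n_classes,
                   "k": k, "lr": model.opt.lr}, fh, indent=2)
    if model.history:
        pd.DataFrame(model.history).to_csv(out / "training_log.csv", index=False)


def load_imputer(out_dir):
    """Returns (model, k)."""
    from fatepattern.nn import SoftmaxMLP

    out = Path(out_dir)
    with open(out / "config.json") as fh:
        cfg = json.load(fh)
    model = SoftmaxMLP(cfg["in_dim"], cfg["n_classes"], hidden=tuple(cfg["hidden"]),
                       lr=cfg["lr"])
    for name in model.params:
        arr = np.loadtxt(out / "weights" / f"{name}.csv", delimiter=",", ndmin=2)
        model.params[name] = arr.reshape(model.params[name].shape).astype(np.float32)
    return model, int(cfg["k"])


def write_manifest(path, command: str, seed: int, config: dict) -> None:
    """JSON run manifest: what ran, with which seed and resolved config."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"command": command, "seed": seed, "config": config}, fh,
                  indent=2, default=str)
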