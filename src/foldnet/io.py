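"""Plain-text persistence for pipeline artifacts (TSV/CSV/JSON).

Every artifact round-trips through an output directory so the CLI
stages can be run independently and real surface-mapped data can
replace the simulator at the decompose step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sparse_coding import Dictionary, SignalMatrix, SparseCodes
from .synthetic_cortex import SurfaceMesh

__all__ = [
    "save_mesh", "load_mesh", "save_templates", "load_templates",
    "save_raw_signals", "load_raw_signals", "save_signals", "load_signals",
    "save_dictionary", "load_dictionary", "save_codes", "load_codes",
    "save_fa", "load_fa", "save_accuracy", "load_accuracy",
]


def save_mesh(mesh: SurfaceMesh, out_dir) -> None:
    out_dir = Path(out_dir)
    pd.DataFrame({
        "x": mesh.vertex_coords[:, 0], "y": mesh.vertex_coords[:, 1],
        "z": mesh.vertex_coords[:, 2], "pcurv": mesh.pcurv,
    }).to_csv(out_dir / "mesh_vertices.tsv", sep="\t", index_label="vertex")
    pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(
        out_dir / "mesh_faces.tsv", sep="\t", index=False)


def load_mesh(out_dir) -> SurfaceMesh:
    out_dir = Path(out_dir)
    verts = pd.read_csv(out_dir / "mesh_vertices.tsv", sep="\t", index_col="vertex")
    faces = pd.read_csv(out_dir / "mesh_faces.tsv", sep="\t")
    return SurfaceMesh(
        vertex_coords=verts[["x", "y", "z"]].to_numpy(),
        faces=faces.to_numpy(dtype=np.intp),
        pcurv=verts["pcurv"].to_numpy(),
    )


def save_templates(rois, out_dir) -> None:
    with open(Path(out_dir) / "templates.json", "w") as fh:
        json.dump({"networks": [[sorted(int(v) for v in r) for r in net]
                                for net in rois]}, fh)


def load_templates(out_dir):
    """Returns (rois nested list of sets, template union sets)."""
    with open(Path(out_dir) / "templates.json") as fh:
        blob = json.load(fh)
    rois = [[set(r) for r in net] for net in blob["networks"]]
    return rois, [set().union(*net) for net in rois]


def save_raw_signals(X: np.ndarray, out_dir) -> None:
    pd.DataFrame(X, columns=np.arange(X.shape[1])).to_csv(
        Path(out_dir) / "signals_raw.tsv", sep="\t", index=False,
        float_format="%.8g")


def load_raw_signals(out_dir) -> np.ndarray:
    return pd.read_csv(Path(out_dir) / "signals_raw.tsv", sep="\t").to_numpy()


def save_signals(signals: SignalMatrix, out_dir) -> None:
    out_dir = Path(out_dir)
    pd.DataFrame(signals.X, columns=signals.vertex_ids).to_csv(
        out_dir / "signals.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out_dir / "signals_meta.json", "w") as fh:
        json.dump({"excluded_ids": [int(i) for i in signals.excluded_ids]}, fh)


def load_signals(out_dir) -> SignalMatrix:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "signals.tsv", sep="\t")
    meta_path = out_dir / "signals_meta.json"
    excluded = np.array([], dtype=np.intp)
    if meta_path.exists():
        with open(meta_path) as fh:
            excluded = np.asarray(json.load(fh)["excluded_ids"], dtype=np.intp)
    return SignalMatrix(
        X=df.to_numpy(),
        vertex_ids=np.asarray([int(c) for c in df.columns], dtype=np.intp),
        excluded_ids=excluded,
    )


def save_dictionary(dic: Dictionary, out_dir) -> None:
    out_dir = Path(out_dir)
    pd.DataFrame(dic.D).to_csv(out_dir / "dictionary.tsv", sep="\t",
                               index=False, float_format="%.12g")
    with open(out_dir / "dictionary_meta.json", "w") as fh:
        json.dump(dic.learn_params, fh)


def load_dictionary(out_dir) -> Dictionary:
    out_dir = Path(out_dir)
    D = pd.read_csv(out_dir / "dictionary.tsv", sep="\t").to_numpy()
    params = {}
    meta = out_dir / "dictionary_meta.json"
    if meta.exists():
        with open(meta) as fh:
            params = json.load(fh)
    return Dictionary(D=D, learn_params=params)


def save_codes(codes: SparseCodes, vertex_ids, out_dir) -> None:
    out_dir = Path(out_dir)
    pd.DataFrame(codes.alpha, columns=vertex_ids).to_csv(
        out_dir / "codes.tsv", sep="\t", index=False, float_format="%.12g")
    with open(out_dir / "codes_meta.json", "w") as fh:
        json.dump({"lam": codes.lam}, fh)


def load_codes(out_dir) -> SparseCodes:
    out_dir = Path(out_dir)
    alpha = pd.read_csv(out_dir / "codes.tsv", sep="\t").to_numpy()
    lam = 0.0
    meta = out_dir / "codes_meta.json"
    if meta.exists():
        with open(meta) as fh:
            lam = json.load(fh)["lam"]
    return SparseCodes(alpha=alpha, lam=lam)


def save_fa(fa: np.ndarray, out_dir) -> None:
    np.savetxt(Path(out_dir) / "fa.tsv", fa, delimiter="\t")


def load_fa(out_dir) -> np.ndarray:
    return np.loadtxt(Path(out_dir) / "fa.tsv")


def save_accuracy(acc, out_dir) -> None:
    pd.DataFrame({"vertex_id": acc.vertex_ids, "P": acc.P}).to_csv(
        Path(out_dir) / "accuracy.csv", index=False, float_format="%.10g")


def load_accuracy(out_dir):
    from .folding_accuracy import AccuracyMap
    df = pd.read_csv(Path(out_dir) / "accuracy.csv")
    return AccuracyMap(P=df["P"].to_numpy(),
                       vertex_ids=df["vertex_id"].to_numpy(dtype=np.intp))
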