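"""Plain-text serialization: TSV matrices, GMT gene sets, model directories."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FactorModel
from .cube import DataCube, WeightTensor, compute_weights


def read_matrix_tsv(path) -> pd.DataFrame:
    """Genes-in-rows matrix: first column gene ID, header row sample IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def save_cube(cube: DataCube, outdir, weights: WeightTensor | None = None,
              log: dict | None = None) -> None:
    """One TSV per layer plus a JSON sidecar with axis ids and weights."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    safe_names = []
    for i, name in enumerate(cube.layer_names):
        safe = name.replace("(", "_pos").replace(")", "").replace("(-", "_neg") \
                   .replace("+", "p").replace("-", "m").replace("/", "_")
        safe = f"layer{i}_{safe}"
        safe_names.append(safe)
        df = pd.DataFrame(cube.values[:, :, i], index=cube.gene_ids,
                          columns=cube.sample_ids)
        write_matrix_tsv(df, out / f"{safe}.tsv")
    if weights is None:
        weights = compute_weights(cube)
    sidecar = {
        "layer_names": cube.layer_names,
        "layer_files": [f"{s}.tsv" for s in safe_names],
        "gene_ids": cube.gene_ids,
        "sample_ids": cube.sample_ids,
        "layer_weights": [float(x) for x in weights.layer_weights],
        "log": log or {},
    }
    (out / "cube.json").write_text(json.dumps(sidecar, indent=1))


def load_cube(indir) -> DataCube:
    out = Path(indir)
    meta = json.loads((out / "cube.json").read_text())
    slabs = []
    for f in meta["layer_files"]:
        df = read_matrix_tsv(out / f)
        slabs.append(df.loc[meta["gene_ids"], [str(s) for s in meta["sample_ids"]]]
                     .to_numpy(dtype=float))
    return DataCube(values=np.stack(slabs, axis=2), gene_ids=meta["gene_ids"],
                    sample_ids=meta["sample_ids"], layer_names=meta["layer_names"])


def save_model(model: FactorModel, outdir) -> None:
    """Three factor TSVs (identifiers preserved) + JSON metadata."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"factor{j}" for j in range(model.k)]
    gid = model.gene_ids or list(range(model.G.shape[0]))
    sid = model.sample_ids or list(range(model.C.shape[0]))
    lid = model.layer_names or list(range(model.D.shape[0]))
    write_matrix_tsv(pd.DataFrame(model.G, index=gid, columns=cols), out / "gene_factors.tsv")
    write_matrix_tsv(pd.DataFrame(model.C, index=sid, columns=cols), out / "sample_factors.tsv")
    write_matrix_tsv(pd.DataFrame(model.D, index=lid, columns=cols), out / "datatype_factors.tsv")
    meta = {
        "k": model.k,
        "w": model.w,
        "seed": model.seed,
        "converged": bool(model.converged),
        "scales": [float(x) for x in (model.scales if model.scales is not None
                                      else np.ones(model.k))],
        "objective_trace": [float(x) for x in model.objective_trace],
        "zero_factors": list(model.zero_factors),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(indir) -> FactorModel:
    out = Path(indir)
    meta = json.loads((out / "model.json").read_text())
    G = read_matrix_tsv(out / "gene_factors.tsv")
    C = read_matrix_tsv(out / "sample_factors.tsv")
    D = read_matrix_tsv(out / "datatype_factors.tsv")
    return FactorModel(
        G=G.to_numpy(dtype=float), C=C.to_numpy(dtype=float),
        D=D.to_numpy(dtype=float), k=int(meta["k"]), w=float(meta["w"]),
        scales=np.asarray(meta["scales"], dtype=float),
        objective_trace=list(meta["objective_trace"]),
        converged=bool(meta["converged"]), seed=meta["seed"],
        gene_ids=list(G.index), sample_ids=list(C.index),
        layer_names=list(D.index), zero_factors=list(meta["zero_factors"]),
    )
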