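"""Readers and writers for the on-disk formats, plus model persistence.

Expression matrices travel as Matrix Market coordinate files with plain-text
gene/cell sidecars (10x-style triplets, either orientation) or as dense TSV
(header row = genes, first column = cell id).  Pathways are tab-delimited
edge files (``source<TAB>target``, or SIF ``source<TAB>relation<TAB>target``
with the relation ignored); circuits export to GMT.  The canonical in-memory
orientation is cells x genes; readers auto-detect and transpose.

A fitted annotator persists as a directory: a JSON manifest (config, class
order, gene order, circuit order, threshold, fences) plus an ``arrays.npz``
with network parameters, mask, scaler statistics and the LOF reference
encodings.  Loading refits the LOF on the stored reference, which is
deterministic, so a round-trip reproduces predictions bitwise on the same
platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .annotator import AnnotatorModel
from .network import InformedNetwork, NetworkConfig
from .novelty import NoveltyModel, fit_lof
from .pathways import EffectorCircuit, IndicatorMatrix, PathwayGraph
from .preprocessing import ExpressionMatrix, GeneScaler

MANIFEST_SCHEMA = "scsignet-model/1"


# ---------------------------------------------------------------- expression

def _read_id_file(path: Path) -> list:
    # first tab-delimited field per line (10x genes.tsv has id<TAB>symbol)
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression(path, layer_tag: str = "counts") -> ExpressionMatrix:
    """Read a Matrix Market triplet (with ``.genes.txt``/``.cells.txt``
    sidecars next to it) or a dense TSV into cells x genes orientation."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes_file = path.with_suffix("").with_suffix(".genes.txt")
        cells_file = path.with_suffix("").with_suffix(".cells.txt")
        for f in (genes_file, cells_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar {f} for {path}")
        genes = _read_id_file(genes_file)
        cells = _read_id_file(cells_file)
        values = np.asarray(scipy.io.mmread(path).todense(), dtype=np.float64)
        if values.shape == (len(cells), len(genes)):
            pass
        elif values.shape == (len(genes), len(cells)):
            values = values.T  # 10x orientation (genes x cells)
        else:
            raise ValueError(
                f"matrix shape {values.shape} matches neither sidecar orientation "
                f"({len(cells)} cells, {len(genes)} genes)"
            )
        return ExpressionMatrix(cells, genes, values, layer_tag=layer_tag)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        [str(c) for c in frame.index],
        [str(g) for g in frame.columns],
        frame.to_numpy(dtype=np.float64),
        layer_tag=layer_tag,
    )


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write ``.mtx`` (+ gene/cell sidecars, cells x genes) or dense ``.tsv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        values = m.values
        integral = np.allclose(values, np.round(values))
        sparse = scipy.sparse.coo_matrix(values.astype(np.int64) if integral else values)
        scipy.io.mmwrite(path, sparse)
        path.with_suffix("").with_suffix(".genes.txt").write_text("".join(f"{g}\n" for g in m.gene_ids))
        path.with_suffix("").with_suffix(".cells.txt").write_text("".join(f"{c}\n" for c in m.cell_ids))
        return
    m.to_frame().to_csv(path, sep="\t", index_label="cell_id")


def read_labels(path) -> pd.Series:
    """Two-column TSV (cell_id, label) with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (cell_id, label)")
    return pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0], name="label")


def write_labels(labels: pd.Series, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": labels.index, "label": labels.to_numpy()}).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ pathways

def read_pathway_file(path, pathway_id: str | None = None) -> PathwayGraph:
    """Parse one tab-delimited edge file ('#' comments allowed)."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                edges.append((fields[0], fields[1]))
            elif len(fields) == 3:  # SIF: source relation target
                edges.append((fields[0], fields[2]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-delimited fields, got {len(fields)}")
    return PathwayGraph.from_edges(pathway_id or path.stem, edges)


def read_pathways(directory) -> list:
    """All ``*.tsv``/``*.txt``/``*.sif`` edge files in a directory, sorted by name."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in (".tsv", ".txt", ".sif"))
    if not files:
        raise ValueError(f"no pathway edge files (*.tsv, *.txt, *.sif) in {directory}")
    return [read_pathway_file(p) for p in files]


def write_pathways(graphs, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g in graphs:
        lines = [f"{u}\t{v}" for u, v in sorted(g.edges)]
        (directory / f"{g.pathway_id}.tsv").write_text("".join(f"{l}\n" for l in lines))


def write_gmt(circuits, path) -> None:
    """GMT export: circuit_id, description (= pathway id), member genes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for c in circuits:
            members = "\t".join(sorted(c.members))
            fh.write(f"{c.circuit_id}\t{c.pathway_id}\t{members}\n")


def read_gmt(path) -> list:
    """Read a circuit GMT back into EffectorCircuit records.

    The effector is recovered from the ``pathway:effector`` circuit id.
    """
    circuits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 tab-delimited fields")
            circuit_id, pathway_id, members = fields[0], fields[1], fields[2:]
            effector = circuit_id.split(":", 1)[1] if ":" in circuit_id else members[0]
            circuits.append(
                EffectorCircuit(
                    circuit_id=circuit_id,
                    pathway_id=pathway_id,
                    effector=effector,
                    members=frozenset(members),
                )
            )
    return circuits


def write_indicator(ind: IndicatorMatrix, prefix) -> None:
    """Matrix Market coordinate file plus gene-list and circuit-list sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(prefix.with_suffix(".mtx"), scipy.sparse.coo_matrix(ind.values))
    prefix.with_suffix(".genes.txt").write_text("".join(f"{g}\n" for g in ind.genes))
    prefix.with_suffix(".circuits.txt").write_text("".join(f"{c}\n" for c in ind.circuits))


def read_indicator(prefix) -> IndicatorMatrix:
    prefix = Path(prefix)
    genes = _read_id_file(prefix.with_suffix(".genes.txt"))
    circuits = _read_id_file(prefix.with_suffix(".circuits.txt"))
    values = np.asarray(scipy.io.mmread(prefix.with_suffix(".mtx")).todense())
    return IndicatorMatrix(genes=genes, circuits=circuits, values=values)


# --------------------------------------------------------------- model store

def save_model(model: AnnotatorModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema": MANIFEST_SCHEMA,
        "config": asdict(model.config),
        "class_labels": model.class_labels,
        "gene_universe": model.gene_universe,
        "circuit_ids": model.network.circuit_ids,
        "seed": model.seed,
        "norm_mode": model.norm_mode,
        "size_factor": model.size_factor,
        "min_overlap": model.min_overlap,
        "valid_fraction": model.valid_fraction,
        "lof_k": model.lof_k,
        "threshold": model.novelty.threshold,
        "fences": model.novelty.fences,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {f"param_{k}": v for k, v in model.network.params.items()}
    arrays["mask"] = model.network.mask
    arrays["scaler_mins"] = model.scaler.mins
    arrays["scaler_maxs"] = model.scaler.maxs
    arrays["lof_reference"] = model.novelty.reference
    np.savez(directory / "arrays.npz", **arrays)


def load_model(directory) -> AnnotatorModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no model manifest in {directory}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValueError(f"unsupported model schema {manifest.get('schema')!r}")
    with np.load(directory / "arrays.npz") as arrays:
        params = {k[len("param_"):]: arrays[k] for k in arrays.files if k.startswith("param_")}
        mask = arrays["mask"]
        mins = arrays["scaler_mins"]
        maxs = arrays["scaler_maxs"]
        reference = arrays["lof_reference"]
    cfg = NetworkConfig(**manifest["config"])
    network = InformedNetwork(
        config=cfg,
        mask=mask,
        params=params,
        class_labels=manifest["class_labels"],
        gene_ids=manifest["gene_universe"],
        circuit_ids=manifest["circuit_ids"],
    )
    novelty = fit_lof(reference, k=manifest["lof_k"])
    novelty.fences = manifest["fences"]
    novelty.threshold = manifest["threshold"]
    scaler = GeneScaler(manifest["gene_universe"], mins, maxs)
    return AnnotatorModel(
        scaler=scaler,
        gene_universe=manifest["gene_universe"],
        network=network,
        novelty=novelty,
        class_labels=manifest["class_labels"],
        config=cfg,
        seed=manifest["seed"],
        norm_mode=manifest["norm_mode"],
        size_factor=manifest["size_factor"],
        min_overlap=manifest["min_overlap"],
        valid_fraction=manifest["valid_fraction"],
        lof_k=manifest["lof_k"],
    )


def write_predictions(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_scores(scores, path) -> None:
    """TSV of similarity scores: cell_id, similarity, split, below_threshold."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(path, sep="\t", index=False)
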