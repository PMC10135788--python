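"""End-to-end fit/predict orchestration and circuit-level interpretation.

``fit`` wires the full training workflow: preprocess raw counts, split the
training cells into a *learning* and a *validation* subset stratified by
cell type, train the masked network with validation early stopping, encode
both subsets, fit the LOF novelty model on the learning encodings and
calibrate the unassigned threshold on the validation encodings.

``predict`` annotates query cells: align genes to the training universe,
normalize/scale, encode, compute the similarity score, and either reject
the cell as "unassigned" (similarity strictly below the threshold) or
assign the argmax cell type of the softmax head.  The novelty layer only
ever relabels cells to "unassigned"; it never changes which known class
the network would pick.

``interpret`` summarizes the signaling-informed layer per cell group: the
mean activation of each circuit node over the group's cells, ranked
descending — a functional profile of each (observed or predicted) type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import network as net_mod
from . import novelty as nov_mod
from .network import InformedNetwork, NetworkConfig, one_hot
from .novelty import NoveltyModel
from .pathways import IndicatorMatrix
from .preprocessing import (
    ExpressionMatrix,
    GeneScaler,
    align_genes,
    apply_scaler,
    fit_scaler,
    log_transform,
    normalize_counts,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    cell_id: str
    label: str  # a known class or "unassigned"
    similarity: float
    probabilities: np.ndarray = field(repr=False)


@dataclass
class AnnotatorModel:
    scaler: GeneScaler
    gene_universe: list
    network: InformedNetwork
    novelty: NoveltyModel
    class_labels: list
    config: NetworkConfig
    seed: int
    norm_mode: str = "umi"
    size_factor: float = 10_000.0
    min_overlap: float = 0.5
    valid_fraction: float = 0.3
    lof_k: int = 20

    @property
    def threshold(self) -> float:
        return self.novelty.threshold


def _preprocess_query(model: AnnotatorModel, counts: ExpressionMatrix) -> ExpressionMatrix:
    aligned, _ = align_genes(counts, model.gene_universe, min_overlap=model.min_overlap)
    normalized = normalize_counts(
        aligned, mode=model.norm_mode, size_factor=model.size_factor, on_zero="keep"
    )
    return apply_scaler(model.scaler, log_transform(normalized))


def fit(
    counts: ExpressionMatrix,
    labels,
    indicator: IndicatorMatrix,
    config: NetworkConfig | None = None,
    seed: int = 0,
    valid_fraction: float = 0.3,
    norm_mode: str = "umi",
    size_factor: float = 10_000.0,
    lof_k: int = 20,
    min_overlap: float = 0.5,
) -> AnnotatorModel:
    """Train the masked classifier and calibrate the novelty threshold.

    ``labels`` maps each training cell to its type (a pandas Series indexed
    by cell id, or any sequence aligned with ``counts.cell_ids``).  The
    learning/validation split is 70/30 stratified by cell type by default.
    The gene rescaler is fitted on the learning subset only and applied with
    clipping everywhere else.
    """
    if isinstance(labels, pd.Series):
        y = labels.reindex(counts.cell_ids)
        if y.isna().any():
            missing = [c for c, bad in zip(counts.cell_ids, y.isna()) if bad]
            raise ValueError(f"labels missing for cells: {missing[:5]}...")
        y = y.to_numpy()
    else:
        y = np.asarray(labels)
        if y.shape[0] != counts.n_cells:
            raise ValueError("one label per cell required")
    class_labels = sorted(set(y.tolist()))
    counts_per_class = pd.Series(y).value_counts()
    too_small = counts_per_class[counts_per_class < 2]
    if len(too_small):
        raise ValueError(f"classes with fewer than 2 cells: {sorted(too_small.index)}")

    aligned, report = align_genes(counts, indicator.genes, min_overlap=min_overlap)
    logger.info(
        "fit: %d cells, %d classes, gene overlap %d/%d",
        counts.n_cells, len(class_labels), report["shared"], len(indicator.genes),
    )
    normalized = log_transform(
        normalize_counts(aligned, mode=norm_mode, size_factor=size_factor, on_zero="error")
    )

    idx_learn, idx_valid = train_test_split(
        np.arange(counts.n_cells),
        test_size=valid_fraction,
        stratify=y,
        random_state=seed,
    )
    scaler = fit_scaler(normalized.subset_cells(idx_learn))
    Xl = apply_scaler(scaler, normalized.subset_cells(idx_learn))
    Xv = apply_scaler(scaler, normalized.subset_cells(idx_valid))
    yl, yv = y[idx_learn], y[idx_valid]

    cfg = config or NetworkConfig(
        n_genes=len(indicator.genes),
        n_circuits=len(indicator.circuits),
        n_classes=len(class_labels),
        seed=seed,
    )
    if (cfg.n_genes, cfg.n_circuits, cfg.n_classes) != (
        len(indicator.genes), len(indicator.circuits), len(class_labels)
    ):
        raise ValueError("network config dimensions do not match indicator/classes")
    network = net_mod.init_network(cfg, indicator, class_labels=class_labels, seed=seed)
    network, history = net_mod.train(
        network,
        (Xl.values, one_hot(yl, class_labels)),
        (Xv.values, one_hot(yv, class_labels)),
    )
    logger.info("training stopped after %d epochs (best %d)", len(history["learn_loss"]), history["best_epoch"])

    enc_learn = net_mod.encode(network, Xl.values)
    enc_valid = net_mod.encode(network, Xv.values)
    k = min(lof_k, enc_learn.shape[0] - 1)
    novelty = nov_mod.fit_lof(enc_learn, k=k)
    valid_scores = nov_mod.score(novelty, enc_valid)
    nov_mod.calibrate_threshold(novelty, valid_scores, yv, expected_labels=class_labels)
    logger.info("unassigned threshold %.4f (fences: %s)", novelty.threshold, novelty.fences)

    return AnnotatorModel(
        scaler=scaler,
        gene_universe=list(indicator.genes),
        network=network,
        novelty=novelty,
        class_labels=class_labels,
        config=cfg,
        seed=seed,
        norm_mode=norm_mode,
        size_factor=size_factor,
        min_overlap=min_overlap,
        valid_fraction=valid_fraction,
        lof_k=k,
    )


def predict(model: AnnotatorModel, counts: ExpressionMatrix) -> list:
    """Annotate query cells; returns one :class:`AnnotationResult` per cell.

    Ties in the softmax argmax break toward the lowest class index (stable).
    All-zero cells are processed like any other query (they stay zero after
    normalization) rather than erroring.
    """
    if counts.n_cells == 0:
        raise ValueError("empty query matrix")
    scaled = _preprocess_query(model, counts)
    _, enc, probs = net_mod.forward(model.network, scaled.values)
    sims = nov_mod.score(model.novelty, enc)
    rejected = nov_mod.is_unassigned(model.novelty, sims)
    hard = np.argmax(probs, axis=1)  # np.argmax takes the first max: lowest class index
    results = []
    for i, cell in enumerate(counts.cell_ids):
        label = UNASSIGNED if rejected[i] else model.class_labels[hard[i]]
        results.append(AnnotationResult(cell, label, float(sims[i]), probs[i].copy()))
    return results


def predictions_frame(model: AnnotatorModel, results) -> pd.DataFrame:
    """Tabular view: cell_id, predicted_label, similarity, one p_<class> per class."""
    rows = {
        "cell_id": [r.cell_id for r in results],
        "predicted_label": [r.label for r in results],
        "similarity": [r.similarity for r in results],
    }
    probs = np.vstack([r.probabilities for r in results])
    for j, c in enumerate(model.class_labels):
        rows[f"p_{c}"] = probs[:, j]
    return pd.DataFrame(rows)


def interpret(
    model: AnnotatorModel,
    counts: ExpressionMatrix,
    groups,
    top_k: int = 10,
    rank_by: str = "activation",
) -> pd.DataFrame:
    """Rank effector circuits per cell group by mean signaling-layer activation.

    ``groups`` assigns each cell a group label (observed or predicted cell
    type).  ``rank_by="activation"`` (default) ranks the group mean of each
    circuit node's ReLU activation; ``rank_by="weight"`` instead weights the
    mean activation by the L2 norm of the circuit node's input weights, an
    alternative reading of "highest-weighted nodes".  Returns the top_k rows
    per group with columns group, circuit_id, mean_activation, rank.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != counts.n_cells:
        raise ValueError("one group label per cell required")
    if rank_by not in ("activation", "weight"):
        raise ValueError("rank_by must be 'activation' or 'weight'")
    scaled = _preprocess_query(model, counts)
    act = net_mod.signaling_activity(model.network, scaled.values)
    if rank_by == "weight":
        wnorm = np.linalg.norm(model.network.masked_kernel, axis=0)
    rows = []
    for g in sorted(set(groups.tolist())):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        mean_act = act[sel].mean(axis=0)
        key = mean_act * wnorm if rank_by == "weight" else mean_act
        # descending by score, circuit id as deterministic tie-break
        order = sorted(range(len(key)), key=lambda j: (-key[j], model.network.circuit_ids[j]))
        for rank, j in enumerate(order[:top_k], start=1):
            rows.append(
                {
                    "group": g,
                    "circuit_id": model.network.circuit_ids[j],
                    "mean_activation": float(mean_act[j]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)
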