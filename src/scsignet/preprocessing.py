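"""Count normalization, log transform, [-1, 1] gene rescaling, gene alignment.

The preprocessing chain for the classifier is: per-cell count normalization
(fixed-sum 10,000 for UMI data, TPM for read counts), natural ``log1p``, and
a per-gene min-max rescale to ``[-1, 1]``.  The rescaler is fitted on the
learning split only and re-applied (with clipping) to validation and query
data, so the network's input domain is fixed by the training data and no
information leaks from held-out cells.

Matrices carry a ``layer_tag`` (``counts`` -> ``normalized`` -> ``scaled``)
so the pipeline refuses to re-transform already-transformed data instead of
silently compounding transforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYER_TAGS = ("counts", "normalized", "scaled")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with a processing-stage tag."""

    cell_ids: list
    gene_ids: list
    values: np.ndarray = field(repr=False)
    layer_tag: str = "counts"

    def __post_init__(self):
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag in ("counts", "normalized") and (self.values < 0).any():
            raise ValueError(f"negative entries not allowed in a {self.layer_tag!r} matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_cells(self, index) -> "ExpressionMatrix":
        index = np.asarray(index)
        cells = [self.cell_ids[i] for i in index]
        return ExpressionMatrix(cells, self.gene_ids, self.values[index], self.layer_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class GeneScaler:
    """Per-gene min/max of log-normalized training data, for [-1, 1] rescaling."""

    gene_ids: list
    mins: np.ndarray = field(repr=False)
    maxs: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if (self.maxs < self.mins).any():
            raise ValueError("per-gene max must be >= min")


def normalize_counts(
    m: ExpressionMatrix,
    mode: str = "umi",
    gene_lengths=None,
    size_factor: float = 10_000.0,
    on_zero: str = "error",
) -> ExpressionMatrix:
    """Per-cell count normalization.

    ``umi``: rescale each cell so its counts sum to ``size_factor`` (10,000 by
    default).  ``tpm``: divide by gene length in kilobases, then rescale each
    cell to sum 1e6; without ``gene_lengths`` this degrades to CPM with a
    warning (droplet data has no meaningful length correction).

    ``on_zero`` controls cells with zero total counts: ``"error"`` (fit-time
    contract) or ``"keep"`` (query-time: the cell stays all-zero).
    """
    if m.layer_tag != "counts":
        raise ValueError(f"normalize_counts expects counts, got {m.layer_tag!r}")
    if mode not in ("umi", "tpm"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = m.values
    if mode == "tpm":
        if gene_lengths is None:
            warnings.warn("TPM requested without gene lengths; falling back to CPM", stacklevel=2)
            logger.warning("TPM requested without gene lengths; falling back to CPM")
        else:
            lengths = np.asarray(gene_lengths, dtype=np.float64)
            if lengths.shape != (m.n_genes,) or (lengths <= 0).any():
                raise ValueError("gene_lengths must be positive, one per gene (kb)")
            values = values / lengths
        target = 1e6
    else:
        target = float(size_factor)
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        if on_zero == "error":
            bad = [m.cell_ids[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"cells with zero total counts: {bad}")
        totals = np.where(zero, 1.0, totals)
    out = values * (target / totals)[:, None]
    return ExpressionMatrix(m.cell_ids, m.gene_ids, out, layer_tag="normalized")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise natural ``log(1 + x)``."""
    if m.layer_tag != "normalized":
        raise ValueError(f"log_transform expects a normalized matrix, got {m.layer_tag!r}")
    if (m.values < 0).any():
        raise ValueError("log_transform requires nonnegative values")
    return ExpressionMatrix(m.cell_ids, m.gene_ids, np.log1p(m.values), layer_tag="normalized")


def fit_scaler(m: ExpressionMatrix) -> GeneScaler:
    """Record per-gene min/max of the (log-normalized) training matrix."""
    if m.layer_tag != "normalized":
        raise ValueError(f"fit_scaler expects a normalized matrix, got {m.layer_tag!r}")
    return GeneScaler(list(m.gene_ids), m.values.min(axis=0), m.values.max(axis=0))


def apply_scaler(scaler: GeneScaler, m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each gene to [-1, 1] using training min/max, clipping queries.

    ``x -> 2 (x - min) / (max - min) - 1``; a gene constant in training
    (max == min) maps to 0; values outside the training range clip to +-1.
    """
    if m.layer_tag != "normalized":
        raise ValueError(f"apply_scaler expects a normalized matrix, got {m.layer_tag!r}")
    if list(m.gene_ids) != list(scaler.gene_ids):
        raise ValueError("gene order of matrix does not match scaler")
    span = scaler.maxs - scaler.mins
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    scaled = 2.0 * (m.values - scaler.mins) / safe - 1.0
    scaled[:, constant] = 0.0
    np.clip(scaled, -1.0, 1.0, out=scaled)
    return ExpressionMatrix(m.cell_ids, m.gene_ids, scaled, layer_tag="scaled")


def align_genes(
    m: ExpressionMatrix, universe, min_overlap: float = 0.5
) -> tuple:
    """Reorder/subset columns to ``universe``; zero-fill genes absent from ``m``.

    Returns ``(aligned_matrix, report)`` where the report counts shared,
    dropped (present in ``m`` only) and filled (universe only) genes.  Errors
    if fewer than ``min_overlap`` of the universe genes are present.
    """
    universe = list(universe)
    have = {g: i for i, g in enumerate(m.gene_ids)}
    shared = [g for g in universe if g in have]
    if len(universe) and len(shared) / len(universe) < min_overlap:
        raise ValueError(
            f"insufficient gene overlap: {len(shared)}/{len(universe)} universe genes "
            f"present (< {min_overlap:.0%})"
        )
    values = np.zeros((m.n_cells, len(universe)), dtype=np.float64)
    for j, g in enumerate(universe):
        i = have.get(g)
        if i is not None:
            values[:, j] = m.values[:, i]
    report = {
        "shared": len(shared),
        "dropped": m.n_genes - len(shared),
        "filled": len(universe) - len(shared),
    }
    logger.info("gene alignment: %(shared)d shared, %(dropped)d dropped, %(filled)d zero-filled", report)
    return ExpressionMatrix(m.cell_ids, universe, values, layer_tag=m.layer_tag), report
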