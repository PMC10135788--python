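"""Synthetic pathway graphs and count matrices with planted circuit activity.

The generator emulates the kind of input the annotator consumes: a set of
directed signaling pathways (layered random DAGs: a receptor layer, one or
two intermediate layers, an effector layer) and a cells x genes UMI-like
count matrix in which each known cell type over-expresses the genes of a
few "active" effector circuits.  An optional *unknown* population draws its
activity exclusively from circuits that no known type uses, giving an
out-of-distribution class for open-set evaluation.

Counts follow a negative-binomial (gamma-Poisson) model with Bernoulli
dropout — the standard noise assumptions for droplet scRNA-seq.  Library
sizes, marker structure, and gene-gene correlation of real tissues are not
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pathways import PathwayGraph, EffectorCircuit, decompose_circuits

UNKNOWN_LABEL = "unknown"


@dataclass
class SimulationScenario:
    """Parameters of one synthetic study.

    ``effect`` is the fold change applied to the baseline negative-binomial
    mean for genes inside a cell type's active circuits; ``dispersion`` is
    the NB dispersion (variance = mu + dispersion * mu^2); ``dropout`` is the
    per-entry Bernoulli zeroing probability.  ``undersample=(type_index,
    ratio)`` keeps only that fraction of one known type's cells.
    """

    n_pathways: int = 10
    nodes_min: int = 8
    nodes_max: int = 20
    n_known_types: int = 3
    cells_per_type: int = 300
    n_unknown_cells: int = 150
    active_circuits_per_type: int = 3
    effect: float = 5.0
    baseline: float = 2.0
    dispersion: float = 0.5
    dropout: float = 0.3
    seed: int = 0
    undersample: tuple | None = None

    def __post_init__(self):
        if self.n_pathways < 1 or self.nodes_min < 3 or self.nodes_max < self.nodes_min:
            raise ValueError("degenerate pathway size parameters")
        if self.n_known_types < 1 or self.cells_per_type < 1 or self.n_unknown_cells < 0:
            raise ValueError("cell counts must be positive (unknown cells >= 0)")
        if self.effect <= 1:
            raise ValueError("effect size must exceed 1")
        if not (0 <= self.dropout < 1) or self.dispersion < 0 or self.baseline <= 0:
            raise ValueError("invalid noise parameters")
        if self.undersample is not None:
            t, r = self.undersample
            if not (0 <= t < self.n_known_types) or not (0 < r <= 1):
                raise ValueError("undersample must be (known type index, ratio in (0, 1])")


def scenario_presets() -> dict:
    """Named study designs.

    ``S1``: closed set — 3 known types, strong effects, no unknown cells.
    ``S2``: open set — S1 plus an unknown population whose active circuits
    are disjoint from every known type's.  ``S3_<r>``: S1 with the first
    type undersampled to ratio r in {0.2, 0.4, 0.6}.
    """
    s1 = SimulationScenario(n_unknown_cells=0)
    out = {"S1": s1, "S2": SimulationScenario()}
    for r in (0.2, 0.4, 0.6):
        out[f"S3_{r}"] = replace(s1, undersample=(0, r))
    return out


def generate_pathways(scenario: SimulationScenario) -> list:
    """Seeded layered random DAGs with globally unique gene names.

    Every pathway has >= 2 receptors and >= 2 effectors by construction;
    each non-receptor node draws 1-3 parents from the previous layer, so
    every node lies on some receptor -> effector path.
    """
    rng = np.random.default_rng(scenario.seed)
    graphs = []
    for p in range(scenario.n_pathways):
        n_nodes = int(rng.integers(scenario.nodes_min, scenario.nodes_max + 1))
        n_eff = int(rng.integers(2, 5))
        n_rec = int(rng.integers(2, 4))
        n_mid = n_nodes - n_eff - n_rec
        n_layers = 2 if (n_mid >= 4 and rng.random() < 0.5) else 1
        mid_sizes = [n_mid] if n_layers == 1 else [n_mid // 2, n_mid - n_mid // 2]
        mid_sizes = [s for s in mid_sizes if s > 0] or [0]

        names = [f"P{p:02d}G{i:02d}" for i in range(n_nodes)]
        layers, start = [], 0
        for size in [n_rec, *[s for s in mid_sizes if s], n_eff]:
            layers.append(names[start : start + size])
            start += size
        edges = set()
        for upper, lower in zip(layers, layers[1:]):
            for child in lower:
                n_par = int(rng.integers(1, min(3, len(upper)) + 1))
                for parent in rng.choice(upper, size=n_par, replace=False):
                    edges.add((str(parent), child))
            # make sure no upper-layer node dangles without a child
            used = {u for u, _ in edges}
            for parent in upper:
                if parent not in used:
                    edges.add((parent, str(rng.choice(lower))))
        graphs.append(PathwayGraph.from_edges(f"PW{p:02d}", edges))
    return graphs


def _assign_active_circuits(scenario, circuits, rng):
    need = scenario.n_known_types + (1 if scenario.n_unknown_cells else 0)
    total = need * scenario.active_circuits_per_type
    if len(circuits) < total:
        raise ValueError(
            f"{len(circuits)} circuits cannot supply {need} disjoint active sets "
            f"of {scenario.active_circuits_per_type}"
        )
    order = rng.permutation(len(circuits))
    sets, pos = [], 0
    for _ in range(need):
        sets.append([circuits[i] for i in order[pos : pos + scenario.active_circuits_per_type]])
        pos += scenario.active_circuits_per_type
    return sets


def generate_counts(scenario: SimulationScenario, circuits) -> tuple:
    """Draw a counts matrix and labels with planted per-type circuit activity.

    Gene mean = baseline x effect for genes inside the type's active circuits,
    baseline elsewhere; counts are gamma-Poisson with the scenario dispersion,
    then hit by Bernoulli dropout.  Unknown cells (label ``"unknown"``) use
    active circuits disjoint from every known type's.  Returns
    ``(ExpressionMatrix with layer_tag="counts", pandas Series of labels)``.
    """
    from .preprocessing import ExpressionMatrix

    circuits = list(circuits)
    rng = np.random.default_rng(scenario.seed + 1)
    genes = sorted(set().union(*(c.members for c in circuits)))
    gene_index = {g: i for i, g in enumerate(genes)}
    active_sets = _assign_active_circuits(scenario, circuits, rng)

    groups, labels = [], []
    for t in range(scenario.n_known_types):
        n = scenario.cells_per_type
        if scenario.undersample is not None and scenario.undersample[0] == t:
            n = max(1, int(round(n * scenario.undersample[1])))
        groups.append((f"type_{t}", n, active_sets[t]))
    if scenario.n_unknown_cells:
        groups.append((UNKNOWN_LABEL, scenario.n_unknown_cells, active_sets[-1]))

    blocks = []
    for label, n_cells, active in groups:
        mu = np.full(len(genes), scenario.baseline)
        for c in active:
            for g in c.members:
                mu[gene_index[g]] = scenario.baseline * scenario.effect
        if scenario.dispersion > 0:
            shape = 1.0 / scenario.dispersion
            lam = rng.gamma(shape, mu * scenario.dispersion, size=(n_cells, len(genes)))
        else:
            lam = np.broadcast_to(mu, (n_cells, len(genes)))
        counts = rng.poisson(lam).astype(np.float64)
        if scenario.dropout > 0:
            counts *= rng.random(counts.shape) >= scenario.dropout
        blocks.append(counts)
        labels.extend([label] * n_cells)

    values = np.vstack(blocks)
    cell_ids = [f"cell_{i:05d}" for i in range(values.shape[0])]
    m = ExpressionMatrix(cell_ids, genes, values, layer_tag="counts")
    return m, pd.Series(labels, index=cell_ids, name="label")


def generate_dataset(scenario: SimulationScenario) -> tuple:
    """Convenience: pathways -> circuits -> counts in one call.

    Returns ``(pathway graphs, circuits, counts matrix, labels)``.
    """
    graphs = generate_pathways(scenario)
    circuits = [c for g in graphs for c in decompose_circuits(g)]
    counts, labels = generate_counts(scenario, circuits)
    return graphs, circuits, counts, labels
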