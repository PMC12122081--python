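"""Synthetic cohorts of CCC graphs with known group structure.

The generator emulates what a ligand-receptor pipeline produces for a disease
cohort: every sample shares one random directed edge set over a fixed panel
of cell types (communication topology is largely conserved across patients),
while each disease group up-weights the edges incident to a group-specific
"hub" cell type — mimicking a disease-linked cell population whose incoming
and outgoing signaling strengthens. Per-sample variation is multiplicative
lognormal jitter (LR scores are positive and right-skewed) plus optional
independent edge dropout.

``downsample_signal`` emulates sequencing-depth robustness experiments by
binomially thinning each edge weight on a count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CCCGraph, Cohort
from .errors import GenerationError, ParameterError

__all__ = ["CohortSpec", "generate_cohort", "downsample_signal"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a pancreas-adenocarcinoma-sized cohort: 10 cell types
    at edge density 0.75 (~75 directed interactions per sample), two disease
    groups of 10 samples, a 5-fold weight shift on each group's hub edges,
    and 10% lognormal jitter.
    """

    n_cell_types: int = 10
    n_groups: int = 2
    samples_per_group: int = 10
    edge_density: float = 0.75
    effect_size: float = 5.0
    affected_fraction: float = 1.0
    noise_sigma: float = 0.1
    dropout: float = 0.0
    baseline_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.edge_density <= 1.0):
            raise ParameterError("edge_density must be in (0, 1]")
        if self.effect_size < 1.0:
            raise ParameterError("effect_size must be >= 1")
        if not (0.0 < self.affected_fraction <= 1.0):
            raise ParameterError("affected_fraction must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must be in [0, 1)")
        if self.noise_sigma < 0 or self.baseline_sigma < 0:
            raise ParameterError("sigmas must be >= 0")
        if self.n_groups < 1 or self.samples_per_group < 1:
            raise ParameterError("need at least one group and one sample")
        if self.n_cell_types < self.n_groups:
            raise ParameterError("need at least one cell type per group (hubs)")


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, np.ndarray]:
    """Generate a cohort plus its ground-truth group labels.

    A shared edge set is drawn Bernoulli(edge_density) over all ordered
    cell-type pairs (self-loops included). Each group g gets a hub cell type;
    the edges touching that hub and no other group's hub (subsampled to
    ``affected_fraction``) have their baseline mean multiplied by
    ``effect_size``. Sample weights are the group mean times lognormal(0,
    noise_sigma) jitter, with edges dropped independently at the dropout
    rate. Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cells = [f"CT{i + 1:02d}" for i in range(spec.n_cell_types)]
    pairs = [(a, b) for a in cells for b in cells]
    keep = rng.random(len(pairs)) < spec.edge_density
    edges = [e for e, k in zip(pairs, keep) if k]
    if not edges:
        raise GenerationError("edge_density too low: shared edge set is empty")
    base = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=len(edges))

    hubs = list(rng.choice(spec.n_cell_types, size=spec.n_groups, replace=False))
    hub_cells = [cells[h] for h in hubs]
    group_mean = np.tile(base, (spec.n_groups, 1))
    for g, hub in enumerate(hub_cells):
        others = set(hub_cells) - {hub}
        block = [i for i, (a, b) in enumerate(edges)
                 if (a == hub or b == hub) and not (a in others or b in others)]
        if spec.affected_fraction < 1.0 and block:
            m = max(1, int(round(spec.affected_fraction * len(block))))
            block = list(rng.choice(block, size=m, replace=False))
        if not block:
            raise GenerationError(
                f"group {g}: no edges incident to hub {hub!r}; "
                "increase edge_density"
            )
        group_mean[g, block] *= spec.effect_size

    graphs, labels = [], []
    for g in range(spec.n_groups):
        for s in range(spec.samples_per_group):
            jitter = rng.lognormal(0.0, spec.noise_sigma, size=len(edges))
            w = group_mean[g] * jitter
            if spec.dropout > 0:
                w = np.where(rng.random(len(edges)) < spec.dropout, 0.0, w)
            edge_map = {e: float(x) for e, x in zip(edges, w) if x > 0}
            if not edge_map:
                raise GenerationError("dropout removed every edge of a sample")
            sid = f"g{g + 1}_s{s + 1:02d}"
            graphs.append(CCCGraph(sid, tuple(cells), edge_map))
            labels.append(g + 1)
    order = np.argsort([g.sample_id for g in graphs])
    cohort = Cohort.from_graphs(
        graphs, labels={graphs[i].sample_id: str(labels[i]) for i in range(len(graphs))}
    )
    return cohort, np.asarray(labels)[order]


def downsample_signal(cohort: Cohort, keep_fraction: float, seed: int = 0,
                      scale: float = 100.0) -> Cohort:
    """Binomially thin every edge weight, emulating cell downsampling.

    Each weight w becomes Binomial(round(w * scale), keep_fraction) / scale,
    treating w as a count at resolution 1/scale; edges thinned to zero are
    dropped. Deterministic given ``seed``.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ParameterError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    graphs = []
    for g in cohort.samples:
        new_edges = {}
        for e, w in sorted(g.edges.items()):
            thinned = rng.binomial(int(round(w * scale)), keep_fraction) / scale
            if thinned > 0:
                new_edges[e] = float(thinned)
        if not new_edges:
            raise GenerationError(
                f"sample {g.sample_id!r} lost all edges at keep_fraction="
                f"{keep_fraction}"
            )
        graphs.append(CCCGraph(g.sample_id, g.nodes, new_edges))
    return Cohort.from_graphs(graphs, labels=cohort.labels)
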