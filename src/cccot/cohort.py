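"""Cohorts of per-sample directed weighted cell-cell communication graphs.

A cohort experiment yields one directed weighted graph per patient sample:
nodes are cell types, an edge ``(source, target)`` says the source cell type
signals to the target cell type, and the weight is the summed ligand-receptor
interaction score for that directed cell pair. This module reads such graphs
from delimited text, validates them, and stacks them into the samples-by-edges
signal matrix that the transport machinery consumes. It also hosts the plain
CSV writers for every artifact the pipeline produces.

All orderings (samples, cell types, edges) are canonicalized lexicographically
so that downstream distance matrices are bit-reproducible across runs and
input row orders.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CCCGraph",
    "Cohort",
    "EdgeSignalMatrix",
    "read_edge_table",
    "aggregate_lr_scores",
    "build_edge_signal_matrix",
    "write_cohort",
    "write_distance_matrix",
    "write_labels",
    "write_edge_masses",
    "write_transport_plan",
    "edge_label",
]

#: separator used when rendering a directed edge as a single string label
EDGE_SEP = "->"


def edge_label(edge: tuple[str, str]) -> str:
    """Render a directed cell-pair edge as ``"source->target"``."""
    return f"{edge[0]}{EDGE_SEP}{edge[1]}"


@dataclass(frozen=True)
class CCCGraph:
    """One sample's directed weighted cell-cell communication graph.

    Parameters
    ----------
    sample_id
        Unique sample (patient) identifier.
    nodes
        Ordered tuple of cell-type labels. Labels are opaque, case-sensitive
        strings; no harmonization is attempted.
    edges
        Mapping from directed ``(source, target)`` cell pairs to non-negative
        finite weights (summed LR scores). Self-loops are permitted.
    """

    sample_id: str
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (s, t), w in self.edges.items():
            if s not in node_set or t not in node_set:
                raise ValidationError(
                    f"sample {self.sample_id!r}: edge ({s!r}, {t!r}) has an "
                    "endpoint outside the node set"
                )
            if not np.isfinite(w) or w < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: edge ({s!r}, {t!r}) has "
                    f"invalid weight {w!r} (must be finite and >= 0)"
                )

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of CCC graphs sharing one cell-type universe."""

    samples: tuple[CCCGraph, ...]
    node_universe: tuple[str, ...]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [g.sample_id for g in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_ids in cohort")
        union = sorted(set().union(*(set(g.nodes) for g in self.samples))) if self.samples else []
        if list(self.node_universe) != union:
            raise ValidationError(
                "node_universe must equal the sorted union of all samples' nodes"
            )

    @classmethod
    def from_graphs(
        cls, graphs: list[CCCGraph], labels: dict[str, str] | None = None
    ) -> "Cohort":
        """Assemble a cohort, sorting samples by id and warning on rare nodes."""
        graphs = sorted(graphs, key=lambda g: g.sample_id)
        universe = sorted(set().union(*(set(g.nodes) for g in graphs))) if graphs else []
        if graphs:
            counts = {v: sum(v in g.nodes for g in graphs) for v in universe}
            rare = [v for v, c in counts.items() if c < 0.5 * len(graphs)]
            if rare:
                warnings.warn(
                    f"cell types present in <50% of samples (possible label "
                    f"mismatch across samples): {rare}",
                    stacklevel=3,
                )
        return cls(tuple(graphs), tuple(universe), labels)

    @property
    def sample_ids(self) -> list[str]:
        return [g.sample_id for g in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def edge_union(self) -> list[tuple[str, str]]:
        """Sorted union of directed edges over all samples."""
        edges: set[tuple[str, str]] = set()
        for g in self.samples:
            edges.update(g.edges)
        return sorted(edges)


@dataclass(frozen=True)
class EdgeSignalMatrix:
    """Samples-by-edges weight matrix, zero-padded over the edge union.

    Row ``k`` holds sample ``k``'s edge weights over the union of all
    directed edges seen in the cohort; an edge absent from a sample
    contributes an exact 0.
    """

    edge_index: tuple[tuple[str, str], ...]
    values: np.ndarray  # (n_samples, n_edges), non-negative
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.edge_index)):
            raise ValidationError("EdgeSignalMatrix shape mismatch")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("EdgeSignalMatrix entries must be finite and >= 0")
        if self.values.size and np.any(self.values.max(axis=0) <= 0):
            raise ValidationError("every edge column must be positive in some sample")

    @property
    def edge_labels(self) -> list[str]:
        return [edge_label(e) for e in self.edge_index]


_REQUIRED = ("sample", "source", "target", "weight")
_LR_REQUIRED = ("sample", "source", "target", "ligand", "receptor", "score")


def _read_delimited(path_or_buf, delimiter: str | None) -> pd.DataFrame:
    if delimiter is not None:
        return pd.read_csv(path_or_buf, sep=delimiter, dtype=str, skipinitialspace=True)
    # auto-detect comma vs tab via the csv sniffer (python engine)
    return pd.read_csv(path_or_buf, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def _check_columns(df: pd.DataFrame, required: tuple[str, ...]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")


def _parse_weights(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # +2: header line + 1-based
        raise ValidationError(f"non-numeric {col} at file row {row}")
    neg = vals < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise ValidationError(f"negative {col} at file row {row}")
    return vals


def _cohort_from_long_table(df: pd.DataFrame, weight_col: str = "weight") -> Cohort:
    dup = df.duplicated(subset=["sample", "source", "target"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValidationError(
            f"duplicate (sample, source, target) at file row {row}; "
            "use aggregate_lr_scores for LR-level input"
        )
    # a 0-weight edge is indistinguishable from an absent edge in the model
    df = df[df[weight_col] > 0]
    graphs = []
    for sid, grp in df.groupby("sample", sort=True):
        nodes = tuple(sorted(set(grp["source"]) | set(grp["target"])))
        edges = {
            (s, t): float(w)
            for s, t, w in zip(grp["source"], grp["target"], grp[weight_col])
        }
        graphs.append(CCCGraph(str(sid), nodes, edges))
    return Cohort.from_graphs(graphs)


def read_edge_table(path_or_buf, delimiter: str | None = None) -> Cohort:
    """Read a cohort from an edge table.

    Accepts either one long delimited table with columns
    ``sample, source, target, weight``, or a directory containing one file
    per sample (file stem = sample id, columns ``source, target, weight``).
    The delimiter is auto-detected between comma and tab unless given.

    Zero-weight rows are dropped; duplicate ``(sample, source, target)``
    rows and negative or non-numeric weights are rejected.
    """
    if isinstance(path_or_buf, (str, os.PathLike)) and os.path.isdir(path_or_buf):
        frames = []
        for name in sorted(os.listdir(path_or_buf)):
            p = os.path.join(path_or_buf, name)
            if not os.path.isfile(p):
                continue
            sub = _read_delimited(p, delimiter)
            _check_columns(sub, ("source", "target", "weight"))
            sub = sub.assign(sample=os.path.splitext(name)[0])
            frames.append(sub)
        if not frames:
            raise FormatError(f"no sample files found in directory {path_or_buf!r}")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = _read_delimited(path_or_buf, delimiter)
        _check_columns(df, _REQUIRED)
    df = df.copy()
    df["weight"] = _parse_weights(df, "weight")
    return _cohort_from_long_table(df)


def aggregate_lr_scores(path_or_buf_or_df, delimiter: str | None = None) -> Cohort:
    """Aggregate a ligand-receptor-level score table into a cohort.

    Each row carries ``(sample, source, target, ligand, receptor, score)``;
    the weight of directed edge ``(source, target)`` in a sample is the sum
    of the scores of all its LR rows.
    """
    if isinstance(path_or_buf_or_df, pd.DataFrame):
        df = path_or_buf_or_df.copy()
    else:
        df = _read_delimited(path_or_buf_or_df, delimiter)
    _check_columns(df, _LR_REQUIRED)
    df["score"] = _parse_weights(df, "score")
    agg = (
        df.groupby(["sample", "source", "target"], sort=True)["score"]
        .sum()
        .reset_index()
        .rename(columns={"score": "weight"})
    )
    return _cohort_from_long_table(agg)


def build_edge_signal_matrix(cohort: Cohort) -> EdgeSignalMatrix:
    """Stack a cohort into the samples-by-edges signal matrix.

    Columns are the sorted union of directed edges across samples; entries
    for edges absent from a sample are exactly 0. Row order follows the
    cohort's sample order.
    """
    if cohort.n_samples == 0:
        raise ValidationError("cannot build a signal matrix from an empty cohort")
    edge_index = tuple(cohort.edge_union())
    if not edge_index:
        raise ValidationError("cohort contains no edges")
    col = {e: j for j, e in enumerate(edge_index)}
    values = np.zeros((cohort.n_samples, len(edge_index)))
    for i, g in enumerate(cohort.samples):
        for e, w in g.edges.items():
            values[i, col[e]] = w
    return EdgeSignalMatrix(edge_index, values, tuple(cohort.sample_ids))


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: Cohort, path_or_buf, delimiter: str = ",") -> None:
    """Write a cohort in the long edge-table dialect (round-trips with
    :func:`read_edge_table`)."""
    rows = [
        (g.sample_id, s, t, w)
        for g in cohort.samples
        for (s, t), w in sorted(g.edges.items())
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED)).to_csv(
        path_or_buf, sep=delimiter, index=False
    )


def write_distance_matrix(D: np.ndarray, sample_ids, path_or_buf) -> None:
    """Write a square distance matrix as CSV with sample ids as header/index."""
    pd.DataFrame(D, index=list(sample_ids), columns=list(sample_ids)).to_csv(
        path_or_buf
    )


def write_labels(sample_ids, labels, path_or_buf) -> None:
    """Write cluster assignments as a two-column CSV (sample_id, cluster)."""
    pd.DataFrame({"sample_id": list(sample_ids), "cluster": list(labels)}).to_csv(
        path_or_buf, index=False
    )


def write_edge_masses(edge_index, masses, path_or_buf) -> None:
    """Write a distribution over directed edges (e.g. a barycenter) as an
    edge-list CSV (source, target, mass)."""
    rows = [(s, t, m) for (s, t), m in zip(edge_index, masses)]
    pd.DataFrame(rows, columns=["source", "target", "mass"]).to_csv(
        path_or_buf, index=False
    )


def write_transport_plan(edge_index, gamma: np.ndarray, path_or_buf,
                         drop_zeros: bool = True) -> None:
    """Write a transport plan in long format (source_edge, target_edge, mass)."""
    labels = [edge_label(e) for e in edge_index]
    ii, jj = np.nonzero(gamma > 0) if drop_zeros else np.indices(gamma.shape).reshape(2, -1)
    rows = [(labels[i], labels[j], gamma[i, j]) for i, j in zip(ii, jj)]
    pd.DataFrame(rows, columns=["source_edge", "target_edge", "mass"]).to_csv(
        path_or_buf, index=False
    )


def cohort_to_graphml(cohort_or_edges, masses=None, path=None):
    """Export a single weighted graph (e.g. a barycenter) as GraphML.

    Accepts an edge index plus masses. Uses :mod:`networkx` for serialization.
    """
    import networkx as nx

    G = nx.DiGraph()
    for (s, t), m in zip(cohort_or_edges, masses):
        if m > 0:
            G.add_edge(s, t, weight=float(m))
    nx.write_graphml(G, path)
    return G
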