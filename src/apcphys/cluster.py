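"""Phenotype classification by z-scored Ward hierarchical clustering.

The workflow mirrors how intrinsic-property cohorts are classified: features
are standardised to z-scores, cells are agglomerated with Ward's minimum-
variance criterion on Euclidean distances, the dendrogram is cut at a chosen
number of groups, and clusters are named either from benchmark cells of known
class or against generator ground truth.  Sequential refinement drops defined
groups and *re-standardises* the survivors before re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment

from .features import FEATURE_NAMES, SUBTHRESHOLD_FEATURES

__all__ = [
    "FeatureMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "StagePlan",
    "BenchmarkTieError",
    "standardize",
    "ward_linkage",
    "cut",
    "count_misclassified",
    "benchmark_assign",
    "sequential_cluster",
    "records_to_frame",
]


class BenchmarkTieError(ValueError):
    """A cluster's benchmark classes tie; explicit naming is required."""


@dataclass
class FeatureMatrix:
    """Cells-by-features matrix with an optional standardisation record."""

    cell_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    standardization: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.cell_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.X)):
            bad = [
                self.feature_names[j]
                for j in np.nonzero(~np.isfinite(self.X).all(axis=0))[0]
            ]
            raise ValueError(f"non-finite values in features: {', '.join(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_names: Sequence[str] | None = None):
        names = list(feature_names) if feature_names is not None else [
            c for c in df.columns if c in FEATURE_NAMES
        ]
        return cls(
            cell_ids=[str(i) for i in df.index],
            feature_names=names,
            X=df[names].to_numpy(dtype=float),
        )

    def select(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in feature_names]
        return FeatureMatrix(
            cell_ids=list(self.cell_ids),
            feature_names=list(feature_names),
            X=self.X[:, idx],
        )


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores using the sample (n-1) standard deviation."""
    if len(matrix.cell_ids) < 2:
        raise ValueError("standardization needs at least 2 cells")
    mean = matrix.X.mean(axis=0)
    sd = matrix.X.std(axis=0, ddof=1)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        names = ", ".join(matrix.feature_names[j] for j in const)
        raise ValueError(f"cannot standardize constant feature(s): {names}")
    return FeatureMatrix(
        cell_ids=list(matrix.cell_ids),
        feature_names=list(matrix.feature_names),
        X=(matrix.X - mean) / sd,
        standardization=(mean, sd),
    )


@dataclass
class Dendrogram:
    """Agglomeration result: a scipy-format linkage plus the leaf identities."""

    linkage: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("Ward merge heights must be non-decreasing")
        if self.linkage.shape[0] != len(self.cell_ids) - 1:
            raise ValueError("linkage must contain n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick serialisation with merge heights as branch lengths."""
        n = len(self.cell_ids)
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.cell_ids[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                blen = node.dist - (0.0 if child.is_leaf() else child.dist)
                parts.append(f"{render(child)}:{blen:.6g}")
            return f"({','.join(parts)})"

        return render(tree) + ";"


def ward_linkage(matrix: FeatureMatrix) -> Dendrogram:
    """Ward's minimum-variance agglomeration on Euclidean distances.

    Expects a standardised matrix; merges minimise the within-cluster
    variance increase (Lance-Williams recurrence).  Deterministic for a given
    input order.
    """
    if len(matrix.cell_ids) < 2:
        raise ValueError("clustering needs at least 2 cells")
    Z = hierarchy.linkage(matrix.X, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, cell_ids=list(matrix.cell_ids))


@dataclass
class ClusterAssignment:
    """A flat partition of cells at one dendrogram cut."""

    labels: dict[str, int]                       # cell id -> cluster number
    k: int
    cluster_names: dict[int, str] = field(default_factory=dict)
    misclassified: list[str] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return [c for c, l in self.labels.items() if l == cluster]

    @property
    def n_misclassified(self) -> int:
        return len(self.misclassified)


def cut(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """The ``k`` clusters obtained by removing the k-1 highest merges."""
    n = len(dendrogram.cell_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels={c: int(l) for c, l in zip(dendrogram.cell_ids, flat)}, k=k
    )


def count_misclassified(
    assignment: ClusterAssignment, true_labels: Mapping[str, str]
) -> tuple[int, list[str]]:
    """Confusion-matrix off-diagonal count under the best cluster<->class map.

    Clusters are matched to true classes by maximising agreement (Hungarian
    assignment); every cell whose cluster maps to a different class — or to
    no class, when there are more clusters than classes — is misclassified.
    """
    cells = [c for c in assignment.labels if c in true_labels]
    classes = sorted({true_labels[c] for c in cells})
    clusters = sorted({assignment.labels[c] for c in cells})
    conf = np.zeros((len(clusters), len(classes)), dtype=int)
    for c in cells:
        conf[clusters.index(assignment.labels[c]), classes.index(true_labels[c])] += 1
    rows, cols = linear_sum_assignment(-conf)
    matched = conf[rows, cols].sum()
    mapping = {clusters[r]: classes[c] for r, c in zip(rows, cols)}
    mis = [
        c
        for c in cells
        if mapping.get(assignment.labels[c]) != true_labels[c]
    ]
    assert len(mis) == len(cells) - matched
    return len(mis), mis


def benchmark_assign(
    assignment: ClusterAssignment,
    benchmark_labels: Mapping[str, str],
    known_labels: Mapping[str, str] | None = None,
) -> ClusterAssignment:
    """Name clusters from benchmark cells of known class.

    Each cluster containing benchmarks takes the majority benchmark class
    (prefixed "p" for putative, e.g. ``pPV``); a tie raises
    :class:`BenchmarkTieError` rather than breaking it silently.  Cells with
    a known class (``known_labels``, default: the benchmarks themselves)
    assigned to a cluster named otherwise or unnamed are listed misclassified.
    """
    if not benchmark_labels:
        raise ValueError("at least one benchmark cell is required")
    counts: dict[int, dict[str, int]] = {}
    for c, klass in benchmark_labels.items():
        cl = assignment.labels[c]
        counts.setdefault(cl, {})[klass] = counts.get(cl, {}).get(klass, 0) + 1
    names: dict[int, str] = {}
    for cluster, cls_counts in counts.items():
        top = max(cls_counts.values())
        winners = sorted(k for k, v in cls_counts.items() if v == top)
        if len(winners) > 1:
            raise BenchmarkTieError(
                f"cluster {cluster}: benchmark classes tie ({', '.join(winners)}); "
                "name this cluster explicitly"
            )
        names[cluster] = f"p{winners[0]}"
    # a class names only the cluster holding most of its benchmarks: a stray
    # benchmark must not drag the class name onto a second cluster
    for klass in set(benchmark_labels.values()):
        claimants = {
            cl: counts[cl].get(klass, 0)
            for cl, name in names.items()
            if name == f"p{klass}"
        }
        if len(claimants) > 1:
            best = max(claimants.values())
            top_clusters = sorted(cl for cl, v in claimants.items() if v == best)
            if len(top_clusters) > 1:
                raise BenchmarkTieError(
                    f"class {klass}: clusters {top_clusters} tie for the name; "
                    "name them explicitly"
                )
            for cl in claimants:
                if cl != top_clusters[0]:
                    del names[cl]
    known = dict(benchmark_labels if known_labels is None else known_labels)
    mis = [
        c
        for c, cl in assignment.labels.items()
        if c in known and names.get(cl) != f"p{known[c]}"
    ]
    return ClusterAssignment(
        labels=dict(assignment.labels),
        k=assignment.k,
        cluster_names=names,
        misclassified=mis,
    )


@dataclass(frozen=True)
class StagePlan:
    """One stage of sequential clustering."""

    feature_names: tuple[str, ...] = FEATURE_NAMES
    exclude_groups: tuple[str, ...] = ()
    k: int = 2


def records_to_frame(records, group_key: str = "label") -> pd.DataFrame:
    """Tabulate CellRecords (with extracted features) for clustering."""
    rows = {}
    for rec in records:
        if rec.features is None:
            raise ValueError(f"cell {rec.cell_id} has no extracted features")
        rows[rec.cell_id] = rec.features.to_dict() | {
            "group": getattr(rec, group_key),
            "benchmark": rec.benchmark,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def sequential_cluster(
    table: pd.DataFrame,
    stage_plan: Sequence[StagePlan],
    group_column: str = "group",
) -> list[tuple[StagePlan, ClusterAssignment]]:
    """Run the staged classification workflow.

    At each stage the listed groups are dropped, z-scores are recomputed on
    the surviving cells, Ward clustering is re-run and the dendrogram is cut
    at the stage's ``k``.  Returns the full audit trail of (plan, assignment)
    pairs; the dendrograms can be regenerated deterministically from the
    same table.
    """
    trail: list[tuple[StagePlan, ClusterAssignment]] = []
    current = table
    for stage in stage_plan:
        if stage.exclude_groups:
            current = current[~current[group_column].isin(stage.exclude_groups)]
        if current.empty:
            raise ValueError("stage excluded all cells")
        fm = FeatureMatrix.from_frame(current, stage.feature_names)
        assignment = cut(ward_linkage(standardize(fm)), stage.k)
        trail.append((stage, assignment))
    return trail


# convenience aliases mirroring the subthreshold-only workflow
SUBTHRESHOLD_PLAN = StagePlan(feature_names=tuple(SUBTHRESHOLD_FEATURES))
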