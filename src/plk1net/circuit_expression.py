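"""Stage 5: circuit-level log2 fold-change clustering of cancer types.

Tumor-vs-normal log2 fold changes (cancer × gene) are restricted to the
genes of one circuit and the cancer types are split into two groups.
Cluster 2 is, by convention, the group with the higher mean log2FC — the
cancers in which the circuit is predominantly overexpressed — while
cluster 1 collects profiles closer to normal tissue.  The default method is
agglomerative clustering with Euclidean distance and Ward linkage cut at
k = 2 (the convention behind heatmap-with-dendrogram figures); seeded
k-means is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .model_schema import Plk1NetError

__all__ = [
    "Log2FCMatrix",
    "CircuitDefinition",
    "ClusterAssignment",
    "ClusteringError",
    "DEFAULT_CIRCUITS",
    "cluster_cancers",
    "circuit_summary",
    "cluster_concordance",
    "plot_circuit_heatmap",
]


class ClusteringError(Plk1NetError):
    pass


@dataclass
class Log2FCMatrix:
    """Cancer × gene log2 fold changes (tumor vs normal); NaN = missing."""

    cancers: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.cancers)) != len(self.cancers):
            raise Plk1NetError("duplicate cancer codes")
        if len(set(self.genes)) != len(self.genes):
            raise Plk1NetError("duplicate gene symbols")
        if self.values.shape != (len(self.cancers), len(self.genes)):
            raise Plk1NetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cancers)} cancers × {len(self.genes)} genes"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Log2FCMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.index], [str(g) for g in df.columns],
                   df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.cancers,
                     columns=self.genes).to_csv(path, sep="\t")

    def submatrix(self, genes: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        """Circuit-restricted value block; missing genes dropped with a
        warning, NaN cells imputed as 0 ("no change") for distances."""
        present = [g for g in genes if g in self.genes]
        absent = [g for g in genes if g not in self.genes]
        if absent:
            warnings.warn(f"genes absent from matrix dropped: {absent}",
                          stacklevel=2)
        if not present:
            raise ClusteringError("no circuit genes present in the matrix")
        cols = [self.genes.index(g) for g in present]
        block = self.values[:, cols].copy()
        block[np.isnan(block)] = 0.0
        return block, present


@dataclass(frozen=True)
class CircuitDefinition:
    """A named gene circuit."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise Plk1NetError(f"circuit {self.name} has no genes")


#: The three PLK1 genomic-instability circuits plus candidate novel markers.
DEFAULT_CIRCUITS: dict[str, CircuitDefinition] = {
    "CIRCUIT1_CPC": CircuitDefinition(
        "CIRCUIT1_CPC",
        ("AURKB", "INCENP", "BIRC5", "CDCA8", "FOXM1", "PLK1"),
    ),
    "CIRCUIT2_MCC": CircuitDefinition(
        "CIRCUIT2_MCC",
        ("BUB1B", "BUB3", "CDC20", "MAD2L1", "CENPE", "KIF2C", "KNL1", "ZWINT"),
    ),
    "CIRCUIT3_APCC": CircuitDefinition(
        "CIRCUIT3_APCC",
        ("ESPL1", "PTTG1", "FBXO5", "ANAPC2", "CDC20", "PDS5A", "RAD21",
         "SMC1A", "SMC3", "STAG1"),
    ),
    "NOVEL_MARKERS": CircuitDefinition(
        "NOVEL_MARKERS",
        ("ZWINT", "NCAPH", "SMC2", "SMC4", "PDS5B", "MXD1", "TP53"),
    ),
}


@dataclass
class ClusterAssignment:
    """Per-cancer labels in {1, 2} for one circuit.

    Label 2 marks the higher-mean-log2FC cluster.  ``degenerate`` flags
    inputs on which the partition is arbitrary (e.g. a constant matrix).
    """

    circuit: str
    labels: dict[str, int]
    method: str
    seed: int | None = None
    degenerate: bool = False

    def label_vector(self, cancers: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[c] for c in cancers])


def cluster_cancers(
    matrix: Log2FCMatrix,
    circuit: CircuitDefinition,
    k: int = 2,
    method: str = "ward",
    seed: int | None = 0,
) -> ClusterAssignment:
    """Partition the cancer types on the circuit-restricted submatrix.

    ``method`` is ``"ward"`` (agglomerative, Euclidean/Ward — deterministic)
    or ``"kmeans"`` (seeded).  With k = 2 the cluster with the higher mean
    log2FC is relabelled 2.  A spread-free submatrix yields an arbitrary
    split flagged as degenerate.
    """
    if k < 2:
        raise ClusteringError("k must be at least 2")
    if len(matrix.cancers) < k:
        raise ClusteringError(
            f"cannot split {len(matrix.cancers)} cancers into {k} clusters"
        )
    block, _genes = matrix.submatrix(circuit.genes)
    degenerate = bool(np.allclose(block, block[0]))
    if degenerate:
        raw = np.zeros(len(matrix.cancers), dtype=int)
        raw[: len(raw) // 2] = 1  # arbitrary but deterministic split
    elif method == "ward":
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(block)
    elif method == "kmeans":
        raw = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(block)
    else:
        raise ClusteringError(f"unknown clustering method {method!r}")

    means = [block[raw == c].mean() if np.any(raw == c) else -np.inf
             for c in range(k)]
    order = np.argsort(means)  # ascending: lowest-mean cluster gets label 1
    relabel = {int(c): rank + 1 for rank, c in enumerate(order)}
    labels = {cancer: relabel[int(raw[i])]
              for i, cancer in enumerate(matrix.cancers)}
    return ClusterAssignment(
        circuit=circuit.name, labels=labels, method=method, seed=seed,
        degenerate=degenerate,
    )


def circuit_summary(
    matrix: Log2FCMatrix,
    circuits: Sequence[CircuitDefinition],
    assignments: dict[str, ClusterAssignment],
) -> pd.DataFrame:
    """Per-(circuit, cluster) summary: mean and spread of log2FC plus
    per-gene means with an over/under/mixed direction flag.

    A gene is "over" ("under") in a cluster when its cluster mean is clearly
    positive (negative); means within ±0.1 of zero are flagged "mixed/none".
    """
    rows = []
    for circuit in circuits:
        block, genes = matrix.submatrix(circuit.genes)
        assignment = assignments[circuit.name]
        labels = assignment.label_vector(matrix.cancers)
        for cluster in sorted(set(labels.tolist())):
            mask = labels == cluster
            sub = block[mask]
            for gi, gene in enumerate(genes):
                gmean = float(sub[:, gi].mean())
                direction = (
                    "over" if gmean > 0.1
                    else "under" if gmean < -0.1
                    else "mixed/none"
                )
                rows.append({
                    "circuit": circuit.name,
                    "cluster": cluster,
                    "n_cancers": int(mask.sum()),
                    "cluster_mean": float(sub.mean()),
                    "cluster_sd": float(sub.std(ddof=0)),
                    "gene": gene,
                    "gene_mean": gmean,
                    "direction": direction,
                })
    return pd.DataFrame(rows)


def cluster_concordance(
    a: ClusterAssignment,
    b: ClusterAssignment,
) -> tuple[float, list[str]]:
    """Best-permutation agreement between two assignments over the same
    cancer universe; returns (agreement fraction, discordant cancer list)."""
    if set(a.labels) != set(b.labels):
        raise Plk1NetError("assignments cover different cancer sets")
    cancers = sorted(a.labels)
    la = np.array([a.labels[c] for c in cancers])
    lb = np.array([b.labels[c] for c in cancers])
    uniq = sorted(set(lb.tolist()))
    best_agree, best_map = -1.0, None
    for perm in permutations(uniq):
        mapping = dict(zip(uniq, perm))
        agree = float(np.mean(la == np.array([mapping[x] for x in lb])))
        if agree > best_agree:
            best_agree, best_map = agree, mapping
    mapped = np.array([best_map[x] for x in lb])
    discordant = [c for c, ok in zip(cancers, la == mapped) if not ok]
    return best_agree, discordant


def plot_circuit_heatmap(
    matrix: Log2FCMatrix,
    circuit: CircuitDefinition,
    assignment: ClusterAssignment,
    path: str | Path,
) -> None:
    """Write a cluster-ordered log2FC heatmap for one circuit (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    block, genes = matrix.submatrix(circuit.genes)
    order = np.argsort(assignment.label_vector(matrix.cancers), kind="stable")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(genes)), max(4, 0.3 * len(matrix.cancers)))
    )
    im = ax.imshow(block[order], aspect="auto", cmap="RdBu_r",
                   vmin=-np.nanmax(np.abs(block)) or -1,
                   vmax=np.nanmax(np.abs(block)) or 1)
    ax.set_xticks(range(len(genes)), genes, rotation=90)
    ax.set_yticks(range(len(matrix.cancers)),
                  [matrix.cancers[i] for i in order])
    ax.set_title(f"{circuit.name} log2FC (clusters {assignment.method})")
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
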