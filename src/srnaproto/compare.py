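"""Cross-library comparison: rank correlation, hierarchical clustering,
and mature/star ratio inversions.

Correlations are computed on RAW counts (rank correlation is invariant to
per-library scaling), clustering on glog-normalised values — the two views
answer different questions: how concordant are the libraries' abundance
rankings, and which libraries sit closest in expression space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


def spearman(x, y) -> float:
    """Spearman rank correlation (mean ranks for ties); NaN if either
    vector has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_matrix(count_matrix: pd.DataFrame, drop_all_zero: bool = True) -> pd.DataFrame:
    """Symmetric library x library Spearman matrix on raw counts.

    Species with zero counts in every library are dropped first (their
    ranks are degenerate and carry no ordering information).
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    mat = count_matrix
    if drop_all_zero:
        mat = mat.loc[(mat != 0).any(axis=1)]
    libs = list(mat.columns)
    out = pd.DataFrame(np.eye(len(libs)), index=libs, columns=libs)
    for i, a in enumerate(libs):
        for j in range(i + 1, len(libs)):
            b = libs[j]
            rho = spearman(mat[a].to_numpy(), mat[b].to_numpy())
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over library columns.

    ``merges`` lists (left leaves, right leaves, height) in merge order;
    heights are non-decreasing (complete linkage is monotone).
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(default_factory=list)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two leaf sets joined by the final (highest) merge."""
        left, right, _ = self.merges[-1]
        return frozenset(left), frozenset(right)

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Height at which each leaf pair is first joined."""
        n = len(self.labels)
        coph = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for left, right, height in self.merges:
            for a in left:
                for b in right:
                    coph.loc[a, b] = height
                    coph.loc[b, a] = height
        return coph

    def to_newick(self) -> str:
        """Ultrametric Newick string (leaf depth = half the merge height)."""
        node_of: dict[frozenset, tuple[str, float]] = {
            frozenset([lab]): (lab, 0.0) for lab in self.labels
        }
        for left, right, height in self.merges:
            lkey, rkey = frozenset(left), frozenset(right)
            (lrep, lh), (rrep, rh) = node_of.pop(lkey), node_of.pop(rkey)
            h = height / 2.0
            rep = f"({lrep}:{h - lh:.6g},{rrep}:{h - rh:.6g})"
            node_of[lkey | rkey] = (rep, h)
        (rep, _), = node_of.values()
        return rep + ";"


def hierarchical_cluster(normalized_matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration over Euclidean distances between
    library columns.

    Deterministic tie-break: among pairs at the minimal distance, merge the
    pair whose (sorted) leaf-label tuples compare lexicographically
    smallest.
    """
    labels = list(normalized_matrix.columns)
    if len(labels) < 3:
        raise ValueError("need at least three libraries to cluster")
    X = normalized_matrix.to_numpy(dtype=float)
    base = {
        (a, b): float(np.linalg.norm(X[:, i] - X[:, j]))
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def dist(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return max(
            base[(a, b)] if (a, b) in base else base[(b, a)] for a in c1 for b in c2
        )

    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best_pair, best_d = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                pair = tuple(sorted([clusters[i], clusters[j]]))
                if d < best_d or (d == best_d and pair < best_pair):
                    best_pair, best_d = pair, d
        left, right = best_pair
        merges.append((left, right, best_d))
        clusters = [c for c in clusters if c not in (left, right)]
        clusters.append(tuple(sorted(left + right)))
    return Dendrogram(labels=labels, merges=merges)


@dataclass
class StarRatioReport:
    """Per-pair, per-library mature vs star counts and inversion flags."""

    table: pd.DataFrame  # columns: pair, library, mature_count, star_count, inverted
    per_library: pd.Series  # total inversions per library
    skipped: list[str] = field(default_factory=list)


def star_ratio_report(
    count_matrix: pd.DataFrame, mirna_pairs: Mapping[str, str]
) -> StarRatioReport:
    """Flag miR/miR* pairs where the star form out-counts the mature form.

    ``mirna_pairs`` maps each star species name to its mature partner.
    Stars whose partner is missing from the matrix are skipped with a note.
    """
    rows = []
    skipped = []
    for star, mature in sorted(mirna_pairs.items()):
        if star not in count_matrix.index or mature not in count_matrix.index:
            skipped.append(star)
            continue
        for lib in count_matrix.columns:
            m = int(count_matrix.loc[mature, lib])
            s = int(count_matrix.loc[star, lib])
            rows.append(
                {
                    "pair": f"{mature}/{star}",
                    "library": lib,
                    "mature_count": m,
                    "star_count": s,
                    "inverted": s > m,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        per_library = pd.Series(0, index=count_matrix.columns, dtype=int)
    else:
        per_library = (
            table[table["inverted"]].groupby("library").size()
            .reindex(count_matrix.columns, fill_value=0)
        )
    per_library.name = "n_inversions"
    return StarRatioReport(table=table, per_library=per_library, skipped=skipped)
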