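"""Protein x motif matrices, distance-correlation distances, Ward
clustering, the heatmap filter pipeline and the C-index scan.

Proteins are clustered by their motif content: rows of a protein x motif
matrix (occurrence counts, or per-protein density enrichments against the
background) are compared with the Szekely distance correlation, and
``1 - dcor`` serves as the clustering distance because of its robustness
to outliers.  Agglomeration uses the Ward.D convention (Lance-Williams
update applied to the *unsquared* dissimilarities); Ward.D2 is available
behind a flag.  Cluster number is explored, not chosen, via the C-index
profile over k = 2..50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifStats, count_matches_per_sequence
from .seqio import SequenceSet


def distance_correlation(x, y) -> float:
    """Szekely distance correlation of two equal-length value lists, in [0, 1].

    Computed from double-centred pairwise-distance matrices.  A constant
    vector has zero distance variance and is defined to have dcor 0 — a
    motif-free protein is maximally uninformative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 1e-15 or dvar_y <= 1e-15:
        return 0.0
    dcov2 = (A * B).mean()
    r2 = dcov2 / np.sqrt(dvar_x * dvar_y)
    return float(np.sqrt(max(r2, 0.0)))


def dcor_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - dcor`` over the rows of ``X``; symmetric, zero diagonal."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - distance_correlation(X[i], X[j])
            D[i, j] = D[j, i] = d
    return D


@dataclass
class MotifMatrix:
    """Protein x motif occurrence counts and per-protein enrichments.

    The enrichment cell is (count_ij / length_i) / (bg occurrences of
    motif j / bg total residues): the protein's own motif density over the
    background density.  Cells are infinite only for motifs absent from
    the background.
    """

    protein_ids: list[str]
    motifs: list[str]
    counts: np.ndarray  # (n_proteins, n_motifs) int
    enrichment: np.ndarray  # (n_proteins, n_motifs) float

    def subset(self, row_idx: np.ndarray, col_idx: np.ndarray) -> "MotifMatrix":
        return MotifMatrix(
            protein_ids=[self.protein_ids[i] for i in row_idx],
            motifs=[self.motifs[j] for j in col_idx],
            counts=self.counts[np.ix_(row_idx, col_idx)],
            enrichment=self.enrichment[np.ix_(row_idx, col_idx)],
        )


def build_motif_matrix(
    fg: SequenceSet, stats: list[MotifStats], bg: SequenceSet
) -> MotifMatrix:
    """Enumerate every discovered motif in every foreground protein."""
    n, m = len(fg), len(stats)
    counts = np.zeros((n, m), dtype=np.int64)
    enr = np.zeros((n, m), dtype=float)
    lengths = np.array([s.length for s in fg], dtype=float)
    bg_total = bg.total_residues
    for j, st in enumerate(stats):
        counts[:, j] = count_matches_per_sequence(st.motif, fg)
        bg_density = st.bg_occurrences / bg_total
        if bg_density > 0:
            enr[:, j] = (counts[:, j] / lengths) / bg_density
        else:
            enr[:, j] = np.where(counts[:, j] > 0, np.inf, 0.0)
    return MotifMatrix(
        protein_ids=fg.ids,
        motifs=[st.motif.pattern for st in stats],
        counts=counts,
        enrichment=enr,
    )


@dataclass
class FilterProvenance:
    """Which proteins/motifs each filter dropped, in application order."""

    dropped: list[tuple[str, str, str]] = field(default_factory=list)
    # (filter name, axis "protein"|"motif", identifier)
    notes: list[str] = field(default_factory=list)

    def drop(self, filt: str, axis: str, names) -> None:
        self.dropped.extend((filt, axis, n) for n in names)


def apply_heatmap_filters(
    matrix: MotifMatrix,
    stats: list[MotifStats],
    biased_protein_ids: set[str],
    heatmap: int = 1,
    dcor_min: float = 0.65,
    top_motifs: int = 70,
    min_proteins: int = 3,
    poi_size: int | None = None,
) -> tuple[MotifMatrix, FilterProvenance]:
    """The five-filter pipeline selecting proteins and motifs for clustering.

    In order: (1) keep proteins with a compositionally biased region
    (membership supplied by the caller, typically at p < 1e-20);
    (2) remove infinitely enriched motifs; (3) remove motifs present in
    fewer than ``min_proteins`` foreground proteins, active only for
    heatmap 1 and only when the foreground holds more than 10 proteins;
    (4) keep the ``top_motifs`` most enriched motifs (ties: more foreground
    proteins, then pattern order); (5) keep proteins whose best dcor to
    another protein, on the post-filter-4 enrichment rows, exceeds
    ``dcor_min``.  Heatmap 3 shares heatmap 2's selection and merely
    displays counts.  An everything-filtered outcome returns an empty
    matrix with explanatory provenance rather than an error.
    """
    if heatmap not in (1, 2, 3):
        raise ValueError("heatmap must be 1, 2 or 3")
    prov = FilterProvenance()
    by_pattern = {st.motif.pattern: st for st in stats}
    n_poi = poi_size if poi_size is not None else len(matrix.protein_ids)

    rows = np.arange(len(matrix.protein_ids))
    keep = np.array(
        [pid in biased_protein_ids for pid in matrix.protein_ids], dtype=bool
    )
    prov.drop("1:biased-region", "protein",
              [p for p, k in zip(matrix.protein_ids, keep) if not k])
    rows = rows[keep]

    cols = np.arange(len(matrix.motifs))
    inf_mask = np.array(
        [not np.isfinite(by_pattern[m].enrichment) for m in matrix.motifs],
        dtype=bool,
    )
    prov.drop("2:infinite-enrichment", "motif",
              [m for m, bad in zip(matrix.motifs, inf_mask) if bad])
    cols = cols[~inf_mask]

    if heatmap == 1 and n_poi > 10:
        fgp = np.array([by_pattern[matrix.motifs[j]].fg_proteins for j in cols])
        bad = fgp < min_proteins
        prov.drop("3:min-proteins", "motif", [matrix.motifs[j] for j in cols[bad]])
        cols = cols[~bad]
    elif heatmap == 1:
        prov.notes.append("filter 3 inactive: foreground has <= 10 proteins")
    else:
        prov.notes.append(f"filter 3 not applied for heatmap {heatmap}")

    if len(cols) > top_motifs:
        order = sorted(
            cols,
            key=lambda j: (
                -by_pattern[matrix.motifs[j]].enrichment,
                -by_pattern[matrix.motifs[j]].fg_proteins,
                matrix.motifs[j],
            ),
        )
        kept = set(order[:top_motifs])
        prov.drop("4:top-enriched", "motif",
                  [matrix.motifs[j] for j in cols if j not in kept])
        cols = np.array(sorted(kept))

    sub = matrix.subset(rows, cols)
    if len(sub.protein_ids) >= 2 and len(sub.motifs) >= 1:
        D = dcor_distance_matrix(sub.enrichment)
        best_dcor = (1.0 - np.where(np.eye(len(D), dtype=bool), np.inf, D)).max(axis=1)
        keep5 = best_dcor > dcor_min
        prov.drop("5:dcor-to-neighbour", "protein",
                  [p for p, k in zip(sub.protein_ids, keep5) if not k])
        sub = sub.subset(np.flatnonzero(keep5), np.arange(len(sub.motifs)))
    elif len(sub.protein_ids) < 2:
        prov.notes.append("filter 5 inactive: fewer than 2 proteins remain")
    if len(sub.protein_ids) == 0 or len(sub.motifs) == 0:
        prov.notes.append("all proteins or motifs filtered out")
    return sub, prov


def ward_linkage(D: np.ndarray, method: str = "ward.D") -> np.ndarray:
    """Agglomerative Ward linkage on a distance matrix.

    ``ward.D`` applies the Lance-Williams update directly to the unsquared
    dissimilarities (the classic hclust convention); ``ward.D2`` applies it
    to squared distances and reports square-rooted heights.  Ties are
    broken lexicographically on (i, j) in the scipy-style id space, so
    merges are deterministic.  Returns an (n-1, 4) linkage array
    [id_a, id_b, height, size].
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("D must be a square distance matrix with n >= 2")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be symmetric with zero diagonal")
    work = D.copy() if method == "ward.D" else D**2
    if method not in ("ward.D", "ward.D2"):
        raise ValueError("method must be 'ward.D' or 'ward.D2'")
    active = list(range(n))
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    np.fill_diagonal(work, np.inf)
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = divmod(int(flat), len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        d_ij = work[i, j]
        height = d_ij if method == "ward.D" else np.sqrt(d_ij)
        id_i, id_j = ids[i], ids[j]
        si, sj = sizes[id_i], sizes[id_j]
        merges[step] = [min(id_i, id_j), max(id_i, id_j), height, si + sj]
        for k in active:
            if k in (i, j):
                continue
            sk = sizes[ids[k]]
            work[i, k] = work[k, i] = (
                (si + sk) * work[i, k] + (sj + sk) * work[j, k] - sk * d_ij
            ) / (si + sj + sk)
        work[j, :] = np.inf
        work[:, j] = np.inf
        active.remove(j)
        ids[i] = next_id
        sizes[next_id] = si + sj
        next_id += 1
    return merges


def labels_from_linkage(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Cut a linkage at ``k`` clusters; labels 1..k by first appearance."""
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[i] = roots[r]
    return labels


def ward_clusters(D: np.ndarray, k: int, method: str = "ward.D") -> np.ndarray:
    """Ward hierarchical clustering of a distance matrix, cut at ``k``."""
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError("k must satisfy 2 <= k <= n")
    return labels_from_linkage(ward_linkage(D, method), n, k)


def c_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C-index of a partition: (S - S_min)/(S_max - S_min).

    S sums within-cluster pairwise distances; S_min / S_max sum the same
    number of smallest / largest distances overall.  Lower is better;
    defined 0 when all distances are equal.
    """
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    dists = D[iu]
    within = labels[iu[0]] == labels[iu[1]]
    nw = int(within.sum())
    if nw == 0:
        return 0.0
    S = float(dists[within].sum())
    ordered = np.sort(dists)
    s_min = float(ordered[:nw].sum())
    s_max = float(ordered[-nw:].sum())
    if s_max == s_min:
        return 0.0
    return (S - s_min) / (s_max - s_min)


def c_index_scan(
    D: np.ndarray, k_range=None, method: str = "ward.D"
) -> list[tuple[int, float]]:
    """C-index profile over a range of cluster numbers (default 2..50).

    The choice of k from the profile remains a manual judgement; C is in
    [0, 1] for every k.
    """
    n = D.shape[0]
    if k_range is None:
        k_range = range(2, min(50, n - 1) + 1)
    merges = ward_linkage(D, method)
    return [(k, c_index(D, labels_from_linkage(merges, n, k))) for k in k_range]
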