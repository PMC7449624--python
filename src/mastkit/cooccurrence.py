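"""Strain co-occurrence scoring and Markov clustering of strains.

Two strains that always appear in the same hosts score S = 1; strains that
never share a host score 0.  S is the Sørensen–Dice coefficient of the two
strains' host sets, S = 2*b_AB / (b_A + b_B), with b_AB the number of hosts
carrying both and b_A, b_B the numbers carrying each.  The same form,
applied host-wise to strain sets, yields the bee-by-bee similarity used for
composition heatmaps.  Strain clusters are read off the S matrix with the
Markov Cluster algorithm (expansion / inflation iterations on the
column-stochastic matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .strain_caller import Strain, StrainTable, snp_distance


def cooccurrence_score(b_ab: int, b_a: int, b_b: int) -> float:
    """Dice co-occurrence: hosts with both over the mean hosts with either."""
    if b_a < 1 or b_b < 1:
        raise ValueError("each strain must occur in at least one host")
    if not 0 <= b_ab <= min(b_a, b_b):
        raise ValueError(f"inconsistent counts: b_AB={b_ab}, b_A={b_a}, b_B={b_b}")
    return 2.0 * b_ab / (b_a + b_b)


@dataclass
class CooccurrenceGraph:
    """Symmetric strain-by-strain score matrix with unit diagonal."""

    strain_ids: list[str]
    S: np.ndarray
    presence_counts: np.ndarray  # hosts per strain (b)

    def __len__(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.strain_ids, columns=self.strain_ids)


def build_cooccurrence_graph(table: StrainTable, marker: str) -> CooccurrenceGraph:
    """Pairwise S over all called strains of a marker (presence/absence based).

    Strains present in no sample are dropped; with fewer than two remaining
    strains an empty graph is returned with a warning.
    """
    pres = table.presence(marker)
    P = pres.to_numpy(dtype=bool)
    keep = P.any(axis=1)
    if (~keep).any():
        warnings.warn(
            f"{marker}: dropping {int((~keep).sum())} strain(s) absent from all samples"
        )
    P = P[keep]
    ids = [sid for sid, k in zip(pres.index, keep) if k]
    if len(ids) < 2:
        warnings.warn(f"{marker}: fewer than 2 strains, empty co-occurrence graph")
        return CooccurrenceGraph(ids, np.zeros((len(ids), len(ids))), P.sum(axis=1))
    b = P.sum(axis=1).astype(float)
    b_ab = (P.astype(float) @ P.T.astype(float))
    S = 2.0 * b_ab / (b[:, None] + b[None, :])
    np.fill_diagonal(S, 1.0)
    return CooccurrenceGraph(ids, S, b.astype(int))


def bee_similarity_matrix(table: StrainTable, marker: str) -> pd.DataFrame:
    """Host-by-host Dice similarity of called strain sets.

    1.0 means the two bees are composed of exactly the same strains, 0.0
    that they share none.  Bees with no called strain (or no data) are
    reported as missing (NaN rows/columns).
    """
    samples = table.marker_samples(marker)
    if len(samples) < 2:
        raise ValueError("need at least two samples with data")
    pres = table.presence(marker)[samples]
    P = pres.to_numpy(dtype=float)
    n = P.sum(axis=0)  # strains per bee
    both = P.T @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = 2.0 * both / (n[:, None] + n[None, :])
    sim[n == 0, :] = np.nan
    sim[:, n == 0] = np.nan
    idx = np.arange(len(samples))
    sim[idx, idx] = np.where(n > 0, 1.0, np.nan)
    return pd.DataFrame(sim, index=samples, columns=samples)


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering parameters (inflation is the granularity knob)."""

    inflation: float = 2.0
    expansion: int = 2
    prune_below: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class StrainClusterSet:
    """A partition of strains into co-occurrence clusters."""

    partition: dict[str, list[str]]  # cluster_id -> sorted member strain ids
    converged: bool = True
    n_iterations: int = 0

    @property
    def membership(self) -> dict[str, str]:
        return {sid: cid for cid, members in self.partition.items() for sid in members}

    def sizes(self) -> list[int]:
        return [len(m) for m in self.partition.values()]

    def labels(self, strain_ids: list[str]) -> list[str]:
        mem = self.membership
        return [mem[s] for s in strain_ids]


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return M / colsum


def _prune(M: np.ndarray, threshold: float) -> np.ndarray:
    """Zero small entries but always keep each column's maximum."""
    if threshold <= 0:
        return M
    keep_max = M == M.max(axis=0, keepdims=True)
    M = np.where((M < threshold) & ~keep_max, 0.0, M)
    return M


def mcl_cluster(
    graph: CooccurrenceGraph | np.ndarray,
    params: MCLParams = MCLParams(),
    strain_ids: list[str] | None = None,
) -> StrainClusterSet:
    """Markov clustering of a symmetric non-negative score matrix.

    Self-loops are added to zero-diagonal nodes (weight = column maximum,
    falling back to 1 on isolated nodes), the matrix is made column
    stochastic, and expansion (matrix power) alternates with inflation
    (entrywise power + renormalisation) and pruning until the iteration is
    stationary.  Clusters are read off attractor rows; strains attracted by
    several clusters are assigned deterministically to the largest cluster,
    ties broken by smallest member strain id.
    """
    if isinstance(graph, CooccurrenceGraph):
        ids = list(graph.strain_ids)
        S = np.asarray(graph.S, dtype=float)
    else:
        S = np.asarray(graph, dtype=float)
        ids = list(strain_ids) if strain_ids is not None else [f"n{i}" for i in range(len(S))]
    n = len(ids)
    if n == 0:
        return StrainClusterSet(partition={})
    if (S < 0).any():
        raise ValueError("scores must be non-negative")
    if not np.allclose(S, S.T):
        raise ValueError("score matrix must be symmetric")

    M = S.copy()
    diag = np.diagonal(M).copy()
    colmax = M.max(axis=0)
    loops = np.where(colmax > 0, colmax, 1.0)
    np.fill_diagonal(M, np.where(diag > 0, diag, loops))
    M = _normalize_columns(M)

    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        M_new = np.linalg.matrix_power(M, params.expansion)
        M_new = M_new ** params.inflation
        M_new = _prune(M_new, params.prune_below)
        M_new = _normalize_columns(M_new)
        diff = float(np.abs(M_new - M).max())
        M = M_new
        if diff < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iter} iterations; "
            "returning current clustering"
        )

    # Attractors are nodes that retain mass on their own row.
    attractors = np.nonzero(np.diagonal(M) > 0)[0]
    if attractors.size == 0:
        attractors = np.unique(np.argmax(M, axis=0))

    # Union attractor systems that lie in each other's clusters.
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rowsets = {int(a): set(np.nonzero(M[a] > 0)[0]) for a in attractors}
    for a in attractors:
        for b in attractors:
            if int(b) in rowsets[int(a)]:
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[rb] = ra

    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), set()).update(rowsets[int(a)])
    roots = list(systems)
    clusters = [systems[r] for r in roots]
    root_to_ci = {r: ci for ci, r in enumerate(roots)}

    # Resolve nodes claimed by several systems: largest cluster wins, ties
    # broken by smallest member strain id; unclaimed nodes follow their
    # strongest attractor.
    claimed: dict[int, list[int]] = {}
    for ci, members in enumerate(clusters):
        for node in members:
            claimed.setdefault(node, []).append(ci)
    assignment: dict[int, int] = {}
    for node in range(n):
        owners = claimed.get(node, [])
        if len(owners) == 1:
            assignment[node] = owners[0]
        elif owners:
            assignment[node] = min(
                owners, key=lambda ci: (-len(clusters[ci]), min(ids[m] for m in clusters[ci]))
            )
        else:
            a = int(attractors[np.argmax(M[attractors, node])])
            assignment[node] = root_to_ci[find(a)]
    final: dict[int, list[int]] = {}
    for node, ci in assignment.items():
        final.setdefault(ci, []).append(node)

    ordered = sorted(
        final.values(), key=lambda members: (-len(members), min(ids[m] for m in members))
    )
    width = max(3, len(str(len(ordered))))
    partition = {
        f"c{ci:0{width}d}": sorted(ids[m] for m in members)
        for ci, members in enumerate(ordered)
    }
    return StrainClusterSet(partition=partition, converged=converged, n_iterations=iterations)


@dataclass
class ClusterStats:
    sizes: list[int]
    clusters_per_bee: pd.Series  # indexed by sample id
    within_cluster_snp_means: dict[str, float]  # cluster_id -> mean pairwise SNPs


def cluster_stats(
    clusters: StrainClusterSet, table: StrainTable, marker: str
) -> ClusterStats:
    """Cluster sizes, clusters per bee, and mean within-cluster SNP distance.

    A cluster counts as present in a bee iff at least one member strain is
    present there.
    """
    pres = table.presence(marker)
    samples = table.marker_samples(marker)
    per_bee = {}
    for sample in samples:
        count = 0
        for members in clusters.partition.values():
            members_in = [m for m in members if m in pres.index]
            if members_in and pres.loc[members_in, sample].any():
                count += 1
        per_bee[sample] = count
    within: dict[str, float] = {}
    for cid, members in clusters.partition.items():
        seqs = [table.registry[m].sequence for m in members if m in table.registry]
        pairs = [
            snp_distance(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        within[cid] = float(np.mean(pairs)) if pairs else float("nan")
    return ClusterStats(
        sizes=clusters.sizes(),
        clusters_per_bee=pd.Series(per_bee, name="clusters_per_bee"),
        within_cluster_snp_means=within,
    )


@dataclass
class WithinBetweenResult:
    within: np.ndarray
    between: np.ndarray
    statistic: float
    pvalue: float
    applicable: bool = True


def within_vs_between_snps(
    clusters: StrainClusterSet, registry: dict[str, Strain]
) -> WithinBetweenResult:
    """Compare pairwise SNP distances inside vs across clusters.

    All strain pairs of the same marker are split into same-cluster and
    different-cluster sets and compared with a two-sided Wilcoxon rank-sum
    test (normal approximation, tie-corrected).  With a single cluster the
    between set is empty and the test is flagged not applicable.
    """
    membership = clusters.membership
    sids = [s for s in membership if s in registry]
    within, between = [], []
    for i in range(len(sids)):
        for j in range(i + 1, len(sids)):
            a, b = registry[sids[i]], registry[sids[j]]
            if a.marker != b.marker:
                continue
            d = snp_distance(a, b)
            (within if membership[sids[i]] == membership[sids[j]] else between).append(d)
    within_arr, between_arr = np.asarray(within), np.asarray(between)
    if len(within_arr) == 0 or len(between_arr) == 0:
        return WithinBetweenResult(within_arr, between_arr, float("nan"), float("nan"), False)
    stat, p = stats.mannwhitneyu(
        within_arr, between_arr, alternative="two-sided", method="asymptotic"
    )
    return WithinBetweenResult(within_arr, between_arr, float(stat), float(p), True)
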