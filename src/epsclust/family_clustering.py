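"""Two-level protein families by Markov clustering of the similarity graph.

Mirrors the genus-level / cross-genus family hierarchy used in pan-genome
resources: a permissive pass over the similarity graph yields *loose*
families, and a stricter pass run independently inside each loose family
yields *strict* subfamilies, so strict families nest in loose ones by
construction.  Diversity statistics per gene role (families, singletons,
proteins per family, multicopy behaviour) summarise how conserved or
variable each cluster gene is.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homology import AlignmentParams, DEFAULT_PARAMS, SimilarityEdge, all_vs_all
from .model import EpsCluster, ROLE_TO_GENE, RoleCall

MCL_PRUNE = 1e-5
MCL_TOL = 1e-8
MCL_MAX_ITER = 200

LOOSE_MIN_IDENTITY = 35.0
STRICT_MIN_IDENTITY = 50.0
MIN_COVERAGE = 50.0
LOOSE_INFLATION = 1.5
STRICT_INFLATION = 2.0


@dataclass
class FamilySet:
    """One level of the family hierarchy: protein -> family id."""

    level: str  # strict | loose
    assignment: dict[str, str]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for pid, fid in self.assignment.items():
            fams.setdefault(fid, []).append(pid)
        return {fid: sorted(members) for fid, members in fams.items()}

    def sizes(self) -> dict[str, int]:
        return {fid: len(m) for fid, m in self.families().items()}

    def __len__(self) -> int:
        return len(self.assignment)


def mcl(
    edges: list[SimilarityEdge],
    proteins: list[str],
    inflation: float = 2.0,
    prune: float = MCL_PRUNE,
    tol: float = MCL_TOL,
    max_iter: int = MCL_MAX_ITER,
) -> list[set[str]]:
    """Markov clustering of an identity-weighted similarity graph.

    Builds a column-stochastic transition matrix with self-loops (weight =
    the node's maximum incident edge weight, 1 for isolated nodes) and
    alternates expansion (matrix squaring) with inflation (elementwise
    power + renormalisation), pruning tiny entries, until the matrix stops
    changing.  Clusters are the attractor systems; overlapping systems are
    merged, so the result is a partition.  Deterministic in the input
    (nodes are processed in sorted order).
    """
    if not 1.2 <= inflation <= 6.0:
        raise ValueError("inflation expected in [1.2, 6]")
    nodes = sorted(set(proteins))
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    W = np.zeros((n, n))
    for e in edges:
        if e.protein_a not in index or e.protein_b not in index:
            raise KeyError(f"edge references unknown protein {e.protein_a}/{e.protein_b}")
        i, j = index[e.protein_a], index[e.protein_b]
        w = e.percent_identity / 100.0
        W[i, j] = max(W[i, j], w)
        W[j, i] = max(W[j, i], w)
    loop = W.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(W, loop)
    M = W / W.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = M ** inflation  # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; interpreting the current matrix")
    # attractors have mass on the diagonal; each attractor row spans one cluster
    attractors = np.where(np.diag(M) > prune)[0]
    clusters: list[set[int]] = []
    for a in attractors:
        members = set(np.where(M[a, :] > prune)[0]) | {a}
        merged = None
        for c in clusters:
            if c & members:
                c |= members
                merged = c
                break
        if merged is None:
            clusters.append(members)
    # transitive closure of overlaps
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    return sorted(
        ({nodes[i] for i in c} for c in clusters), key=lambda c: sorted(c)[0]
    )


def partition_to_familyset(partition: list[set[str]], level: str, prefix: str) -> FamilySet:
    assignment = {}
    for members in partition:
        fid = f"{prefix}.{min(members)}"
        for m in members:
            assignment[m] = fid
    return FamilySet(level=level, assignment=assignment)


def build_two_level_families(
    proteins: dict[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
    loose_min_identity: float = LOOSE_MIN_IDENTITY,
    strict_min_identity: float = STRICT_MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    loose_inflation: float = LOOSE_INFLATION,
    strict_inflation: float = STRICT_INFLATION,
    edges: list[SimilarityEdge] | None = None,
) -> tuple[FamilySet, FamilySet]:
    """Strict-in-loose family hierarchy from one all-vs-all pass.

    Edges are computed once at the loose identity threshold; the strict
    pass reuses the subset at the strict threshold within each loose
    family, which both saves alignments and enforces the nesting
    invariant structurally.
    """
    if edges is None:
        edges = all_vs_all(
            proteins, params, min_identity=loose_min_identity, min_coverage=min_coverage
        )
    ids = sorted(proteins)
    loose_partition = mcl(edges, ids, inflation=loose_inflation)
    loose = partition_to_familyset(loose_partition, "loose", "L")
    strict_edges = [e for e in edges if e.percent_identity >= strict_min_identity]
    strict_assignment: dict[str, str] = {}
    for loose_members in loose_partition:
        sub_edges = [
            e
            for e in strict_edges
            if e.protein_a in loose_members and e.protein_b in loose_members
        ]
        for members in mcl(sub_edges, sorted(loose_members), inflation=strict_inflation):
            fid = f"S.{min(members)}"
            for m in members:
                strict_assignment[m] = fid
    strict = FamilySet(level="strict", assignment=strict_assignment)
    return strict, loose


# ---------------------------------------------------------------------------
# diversity statistics (per gene role)


def ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Rounded ratio used throughout the per-role family summaries; 0 when
    the denominator is zero."""
    if denominator == 0:
        return 0.0
    return round(numerator / denominator, ndigits)


def singleton_percent(family_sizes: list[int], ndigits: int = 1) -> float:
    if not family_sizes:
        return 0.0
    singles = sum(1 for s in family_sizes if s == 1)
    return round(100.0 * singles / len(family_sizes), ndigits)


def diversity_stats(
    strict: FamilySet,
    loose: FamilySet,
    clusters: list[EpsCluster],
    roles: dict[str, RoleCall],
    missing_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene-role family diversity table.

    One row per gene symbol (epsA..wzy): protein count, strict and loose
    family counts, proteins per strict family, strict families per loose
    family, % singleton (strict) families, and — over clusters holding >= 2
    copies of the gene — the mean copy count and mean number of distinct
    strict families those copies span (near 1:1 indicates non-redundant
    copies).  Pseudogenes never enter family statistics.
    """
    member_cluster: dict[str, str] = {}
    for cl in clusters:
        for fid in cl.member_feature_ids:
            member_cluster[fid] = cl.cluster_id
    rows = []
    genes = sorted(set(ROLE_TO_GENE.values()))
    for gene in genes:
        pids = [
            fid
            for fid, call in roles.items()
            if ROLE_TO_GENE.get(call.role) == gene
            and not call.is_pseudo
            and fid in strict.assignment
            and fid in member_cluster
        ]
        strict_fams = {strict.assignment[p] for p in pids}
        loose_fams = {loose.assignment[p] for p in pids}
        sizes = {}
        for p in pids:
            sizes[strict.assignment[p]] = sizes.get(strict.assignment[p], 0) + 1
        per_cluster: dict[str, list[str]] = {}
        for p in pids:
            per_cluster.setdefault(member_cluster[p], []).append(p)
        multi = {cid: ps for cid, ps in per_cluster.items() if len(ps) >= 2}
        mean_copies = (
            round(float(np.mean([len(ps) for ps in multi.values()])), 1) if multi else 0.0
        )
        mean_fams = (
            round(
                float(
                    np.mean([len({strict.assignment[p] for p in ps}) for ps in multi.values()])
                ),
                1,
            )
            if multi
            else 0.0
        )
        rows.append(
            {
                "gene": gene,
                "n_proteins": len(pids),
                "n_strict_families": len(strict_fams),
                "n_loose_families": len(loose_fams),
                "n_clusters_missing": (missing_counts or {}).get(gene, 0),
                "proteins_per_strict_family": ratio(len(pids), len(strict_fams)),
                "strict_per_loose": ratio(len(strict_fams), len(loose_fams)),
                "singleton_percent": singleton_percent(list(sizes.values())),
                "n_clusters_with_multicopy": len(multi),
                "mean_copies_when_multicopy": mean_copies,
                "mean_families_when_multicopy": mean_fams,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def write_families_tsv(strict: FamilySet, loose: FamilySet, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstrict_family\tloose_family\n")
        for pid in sorted(strict.assignment):
            fh.write(f"{pid}\t{strict.assignment[pid]}\t{loose.assignment[pid]}\n")
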