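"""Cluster-level comparison: presence/absence matrix, hierarchical
clustering, group cutting, and habitat-sharing partitions.

Clusters are compared by which protein families they contain (binary
presence/absence), agglomerated with Jaccard distance and average linkage,
and cut into a user-chosen number of groups.  Family sharing across the
three habitat lifestyles is summarised as a 7-region Venn partition per
gene role, with singleton families tallied separately and unknown-habitat
material excluded.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .family_clustering import FamilySet
from .model import EpsCluster, HABITATS, ROLE_TO_GENE, RoleCall, UNKNOWN_HABITAT


@dataclass
class PresenceMatrix:
    """Binary families x clusters matrix."""

    data: pd.DataFrame  # index: family ids, columns: cluster ids, values 0/1
    level: str

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class HclResult:
    linkage: np.ndarray
    leaves: list[str]  # column ids in input order
    cophenetic: np.ndarray  # condensed distances
    newick: str


def build_matrix(
    families: FamilySet, clusters: list[EpsCluster], level: str | None = None
) -> PresenceMatrix:
    """Presence/absence of each family in each cluster.

    Rows are family ids, columns cluster ids, both sorted for determinism;
    a family is present where at least one member protein belongs to the
    cluster.  All-zero rows cannot occur because families are built from
    cluster proteins.
    """
    cluster_of: dict[str, str] = {}
    for cl in clusters:
        for fid in cl.member_feature_ids:
            cluster_of[fid] = cl.cluster_id
    fam_ids = sorted(set(families.assignment.values()))
    cl_ids = sorted(cl.cluster_id for cl in clusters)
    data = pd.DataFrame(0, index=fam_ids, columns=cl_ids, dtype=int)
    for pid, fam in families.assignment.items():
        cid = cluster_of.get(pid)
        if cid is not None:
            data.loc[fam, cid] = 1
    data = data.loc[data.sum(axis=1) > 0]
    return PresenceMatrix(data=data, level=level or families.level)


def _linkage_to_newick(Z: np.ndarray, leaves: list[str]) -> str:
    """Serialise a SciPy linkage over the given leaf names as Newick."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, leaves)
    return str(tree).strip()


def hcl(
    matrix: PresenceMatrix, distance: str = "jaccard", linkage: str = "average"
) -> HclResult:
    """Agglomerative clustering of cluster columns.

    Jaccard distance on the 1-entries with average linkage by default;
    columns are taken in lexicographic id order so equal-distance merges
    resolve deterministically.  Identical columns merge at height 0.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("hierarchical clustering needs at least two clusters")
    cols = sorted(matrix.clusters)
    X = matrix.data[cols].T.values.astype(bool)
    dist = pdist(X, metric=distance)
    dist = np.nan_to_num(dist, nan=0.0)  # all-zero column pairs: treat as identical
    Z = hierarchy.linkage(dist, method=linkage)
    coph = hierarchy.cophenet(Z)
    return HclResult(linkage=Z, leaves=cols, cophenetic=coph, newick=_linkage_to_newick(Z, cols))


def cut_groups(result: HclResult, k: int) -> dict[str, int]:
    """Cut the dendrogram into k groups (group ids 1..k by leaf order)."""
    n = len(result.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return {leaf: int(g) for leaf, g in zip(result.leaves, labels)}


def group_habitat_composition(
    groups: dict[str, int], habitat_of_cluster: dict[str, str]
) -> dict[int, dict[str, int]]:
    comp: dict[int, dict[str, int]] = {}
    for cid, g in groups.items():
        habitat = habitat_of_cluster.get(cid, UNKNOWN_HABITAT)
        comp.setdefault(g, {})
        comp[g][habitat] = comp[g].get(habitat, 0) + 1
    return comp


# ---------------------------------------------------------------------------
# habitat sharing (7-region Venn partition per role)


def _region_key(habitats: frozenset[str]) -> str:
    return "&".join(sorted(habitats))


ALL_REGIONS = [
    _region_key(frozenset(c))
    for c in (
        {"host-adapted"}, {"nomadic"}, {"free-living"},
        {"host-adapted", "nomadic"}, {"host-adapted", "free-living"},
        {"nomadic", "free-living"},
        {"host-adapted", "nomadic", "free-living"},
    )
]


@dataclass
class SharingPartition:
    """Per role: family counts in each of the 7 habitat Venn regions,
    multi-member and singleton families tallied separately."""

    by_role: dict[str, dict]  # gene -> {"multi": {...}, "singleton": {...}, "excluded_unknown": n}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.by_role, fh, indent=1, sort_keys=True)


def habitat_sharing(
    families: FamilySet,
    clusters: list[EpsCluster],
    roles: dict[str, RoleCall],
    habitat_of_strain: dict[str, str],
) -> SharingPartition:
    """Partition each role's families by the habitats of the contributing
    strains.

    A family's region is the set of habitats of the strains whose cluster
    proteins it contains (for that role).  Proteins from unknown-habitat
    strains are dropped first; families left with no known-habitat member
    are counted as excluded.  Families with one member (within the role)
    are tallied separately from multi-member families.
    """
    strain_of: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    for cl in clusters:
        for fid in cl.member_feature_ids:
            strain_of[fid] = cl.strain
            cluster_of[fid] = cl.cluster_id
    by_role: dict[str, dict] = {}
    genes = sorted(set(ROLE_TO_GENE.values()))
    for gene in genes:
        fam_members: dict[str, list[str]] = {}
        for pid, call in roles.items():
            if ROLE_TO_GENE.get(call.role) != gene or call.is_pseudo:
                continue
            fam = families.assignment.get(pid)
            if fam is None or pid not in strain_of:
                continue
            fam_members.setdefault(fam, []).append(pid)
        multi = {r: 0 for r in ALL_REGIONS}
        single = {r: 0 for r in ALL_REGIONS}
        excluded = 0
        for fam, pids in sorted(fam_members.items()):
            habitats = frozenset(
                h
                for h in (habitat_of_strain.get(strain_of[p], UNKNOWN_HABITAT) for p in pids)
                if h in HABITATS
            )
            if not habitats:
                excluded += 1
                continue
            region = _region_key(habitats)
            if len(pids) == 1:
                single[region] += 1
            else:
                multi[region] += 1
        by_role[gene] = {
            "multi": multi,
            "singleton": single,
            "excluded_unknown": excluded,
            "n_families": len(fam_members),
        }
    return SharingPartition(by_role=by_role)


def write_matrix(matrix: PresenceMatrix, tsv_path, mtx_path=None) -> None:
    matrix.data.to_csv(tsv_path, sep="\t")
    if mtx_path is not None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(mtx_path), csr_matrix(matrix.data.values))
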