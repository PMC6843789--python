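"""Architecture and composition calls for detected clusters.

Covers the generic/non-generic gene-order call (intact ordered epsABCDE
stretch at the 5' end), completeness against the essential-gene checklist,
multicopy accounting, per-role GC deviation from the genome background and
transposase adjacency — the evidence base for horizontal-acquisition
arguments, reported without drawing that conclusion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import compute_gc
from .model import (
    DISPENSABLE_GENES,
    ESSENTIAL_GENES,
    EpsCluster,
    GenomeRecord,
    ROLE_TO_GENE,
    RoleCall,
)


@dataclass
class ClusterClassification:
    cluster_id: str
    is_generic: bool
    missing_essential: set = field(default_factory=set)
    missing_dispensable: set = field(default_factory=set)
    multicopy: dict = field(default_factory=dict)  # gene symbol -> copy count (>= 2)
    gc_by_role: dict = field(default_factory=dict)  # gene symbol -> (gene_gc, genome_gc, delta)
    transposase_adjacent_roles: set = field(default_factory=set)
    transposase_adjacent_features: set = field(default_factory=set)


def oriented_roles(cluster: EpsCluster, roles: dict[str, RoleCall]) -> list[RoleCall]:
    """Member role calls in 5'->3' order of the cluster's majority strand.

    Clusters encoded on the minus strand are reversed so the regulatory
    end reads first, mirroring how cluster maps are conventionally drawn.
    """
    calls = [roles[fid] for fid in cluster.member_feature_ids]
    if cluster.strand == "-":
        calls = list(reversed(calls))
    return calls


def is_generic(cluster: EpsCluster, roles: dict[str, RoleCall]) -> bool:
    """True iff the first five non-transposase genes at the 5' end are
    EpsA, EpsB, EpsC, EpsD, EpsE in exactly that order.

    Mobile-element insertions are skipped: a transposase interleaved in
    the stretch is an insertion, not cluster architecture.
    """
    order = [c.role for c in oriented_roles(cluster, roles) if c.role != "Transposase"]
    return order[:5] == ["EpsA", "EpsB", "EpsC", "EpsD", "EpsE"]


def completeness(
    cluster: EpsCluster,
    roles: dict[str, RoleCall],
    count_truncated_as_missing: bool = True,
) -> tuple[set, set]:
    """Missing essential / dispensable genes.

    A gene counts as present only when carried by a non-pseudo (and, by
    default, non-truncated) CDS: a pseudogene or a likely non-functional
    truncated product does not rescue completeness.
    """
    present = set()
    for fid in cluster.member_feature_ids:
        call = roles[fid]
        gene = ROLE_TO_GENE.get(call.role)
        if gene is None:
            continue
        if call.is_pseudo:
            continue
        if count_truncated_as_missing and call.is_truncated:
            continue
        present.add(gene)
    return set(ESSENTIAL_GENES) - present, set(DISPENSABLE_GENES) - present


def multicopy_counts(cluster: EpsCluster, roles: dict[str, RoleCall]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for fid in cluster.member_feature_ids:
        gene = ROLE_TO_GENE.get(roles[fid].role)
        if gene is not None:
            counts[gene] = counts.get(gene, 0) + 1
    return {g: n for g, n in counts.items() if n >= 2}


def gc_deviation(
    cluster: EpsCluster, roles: dict[str, RoleCall], genome: GenomeRecord
) -> dict[str, tuple[float, float, float]]:
    """Per-role pooled gene GC versus whole-record GC.

    Roles absent from the cluster are omitted; delta = gene GC - genome GC,
    so the horizontally-acquired signature reads as a negative delta.
    """
    genome_gc = compute_gc(genome.sequence)
    intervals: dict[str, list[tuple[int, int]]] = {}
    feats = {f.feature_id: f for f in genome.features}
    for fid in cluster.member_feature_ids:
        gene = ROLE_TO_GENE.get(roles[fid].role)
        if gene is None:
            continue
        f = feats[fid]
        intervals.setdefault(gene, []).append((f.start, f.end))
    out = {}
    for gene, ivs in intervals.items():
        pooled = "".join(genome.sequence[lo:hi] for lo, hi in ivs)
        gene_gc = compute_gc(pooled)
        out[gene] = (gene_gc, genome_gc, gene_gc - genome_gc)
    return out


def transposase_adjacent_feature_ids(
    cluster: EpsCluster, roles: dict[str, RoleCall], genome: GenomeRecord
) -> set[str]:
    """Member features with a transposase as immediate feature-order
    neighbour, or whose genomic span nests a transposase."""
    idx = genome.feature_index()
    feats = genome.features
    transposase_positions = [
        idx[fid] for fid in cluster.member_feature_ids if roles[fid].role == "Transposase"
    ]
    flagged: set[str] = set()
    member_set = set(cluster.member_feature_ids)
    for tpos in transposase_positions:
        tfeat = feats[tpos]
        for npos in (tpos - 1, tpos + 1):
            if 0 <= npos < len(feats) and feats[npos].feature_id in member_set:
                if roles[feats[npos].feature_id].role != "Transposase":
                    flagged.add(feats[npos].feature_id)
        for fid in member_set:
            f = feats[idx[fid]]
            if f.feature_id != tfeat.feature_id and f.start <= tfeat.start and tfeat.end <= f.end:
                flagged.add(fid)
    return flagged


def transposase_adjacency(
    cluster: EpsCluster, roles: dict[str, RoleCall], genome: GenomeRecord
) -> set[str]:
    """Roles with a transposase as immediate feature-order neighbour or
    nested within the gene's genomic span."""
    flagged = {
        roles[fid].role
        for fid in transposase_adjacent_feature_ids(cluster, roles, genome)
    }
    flagged.discard("Transposase")
    return flagged


def classify_cluster(
    cluster: EpsCluster,
    roles: dict[str, RoleCall],
    genome: GenomeRecord,
    count_truncated_as_missing: bool = True,
) -> ClusterClassification:
    missing_e, missing_d = completeness(cluster, roles, count_truncated_as_missing)
    adj_features = transposase_adjacent_feature_ids(cluster, roles, genome)
    adj_roles = {roles[fid].role for fid in adj_features}
    adj_roles.discard("Transposase")
    return ClusterClassification(
        cluster_id=cluster.cluster_id,
        is_generic=is_generic(cluster, roles),
        missing_essential=missing_e,
        missing_dispensable=missing_d,
        multicopy=multicopy_counts(cluster, roles),
        gc_by_role=gc_deviation(cluster, roles, genome),
        transposase_adjacent_roles=adj_roles,
        transposase_adjacent_features=adj_features,
    )


def run_summary(
    classifications: list[ClusterClassification],
    clusters: list[EpsCluster],
    roles: dict[str, RoleCall],
) -> dict:
    """Run-level aggregation: per-gene missing counts, multicopy counts,
    mean GC deltas and transposase-adjacency proportions."""
    n_generic = sum(c.is_generic for c in classifications)
    missing: dict[str, int] = {}
    multicopy: dict[str, int] = {}
    gc_deltas: dict[str, list[float]] = {}
    for c in classifications:
        for gene in c.missing_essential | c.missing_dispensable:
            missing[gene] = missing.get(gene, 0) + 1
        for gene in c.multicopy:
            multicopy[gene] = multicopy.get(gene, 0) + 1
        for gene, (_, _, delta) in c.gc_by_role.items():
            gc_deltas.setdefault(gene, []).append(delta)
    # transposase adjacency per role: adjacent genes / all genes of the role
    role_totals: dict[str, int] = {}
    role_adjacent: dict[str, int] = {}
    adj_by_cluster = {c.cluster_id: c.transposase_adjacent_features for c in classifications}
    for cl in clusters:
        flagged = adj_by_cluster.get(cl.cluster_id, set())
        for fid in cl.member_feature_ids:
            role = roles[fid].role
            role_totals[role] = role_totals.get(role, 0) + 1
            if fid in flagged:
                role_adjacent[role] = role_adjacent.get(role, 0) + 1
    proportions = {
        role: role_adjacent.get(role, 0) / total for role, total in role_totals.items()
    }
    return {
        "n_clusters": len(classifications),
        "n_generic": n_generic,
        "n_non_generic": len(classifications) - n_generic,
        "missing_gene_counts": dict(sorted(missing.items())),
        "multicopy_cluster_counts": dict(sorted(multicopy.items())),
        "mean_gc_delta_by_gene": {
            g: sum(v) / len(v) for g, v in sorted(gc_deltas.items())
        },
        "transposase_adjacent_proportion_by_role": dict(sorted(proportions.items())),
    }


def write_classification_tsv(classifications: list[ClusterClassification], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tis_generic\tmissing_essential\tmissing_dispensable\t"
            "multicopy\ttransposase_adjacent_roles\n"
        )
        for c in sorted(classifications, key=lambda c: c.cluster_id):
            mc = ",".join(f"{g}:{n}" for g, n in sorted(c.multicopy.items()))
            fh.write(
                f"{c.cluster_id}\t{int(c.is_generic)}\t"
                f"{','.join(sorted(c.missing_essential))}\t"
                f"{','.join(sorted(c.missing_dispensable))}\t{mc}\t"
                f"{','.join(sorted(c.transposase_adjacent_roles))}\n"
            )
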