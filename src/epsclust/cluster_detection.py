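"""EPS gene-cluster discovery: seed homology plus neighborhood expansion.

Seeds are CDS matching the conserved regulatory/priming proteins
(EpsA-EpsE) of characterised clusters.  The genomic environment of each
seed is then walked gene-by-gene: a neighbour counts as EPS-related if it
aligns to any reference-library protein above the neighbour threshold or
its annotation text carries a curated biosynthesis keyword.  Extension
tolerates short runs of unrelated genes (insertions, hypotheticals) and
never crosses a replicon boundary.
"""
from __future__ import annotations

import re

from .model import EpsCluster, GenomeRecord, SeedHit
from .reference import ReferenceAligner, ReferenceLibrary, SEED_ROLES

#: Annotation keywords that mark a gene as EPS-biosynthesis related during
#: neighbourhood expansion (matched case-insensitively on product text).
EPS_KEYWORDS = (
    "glycosyltransferase",
    "polysaccharide",
    "flippase",
    "polymerase",
    "epimerase",
    "mutase",
    "dehydratase",
    "transposase",
    "acetyltransferase",
)

_KEYWORD_RE = re.compile("|".join(EPS_KEYWORDS), re.IGNORECASE)

SEED_MIN_IDENTITY = 30.0  # exclusive bound: identity must exceed this
SEED_MIN_COVERAGE = 50.0
DEFAULT_MAX_GAP = 2


def product_is_eps_related(product_text: str) -> bool:
    return bool(_KEYWORD_RE.search(product_text or ""))


def find_seeds(
    genome: GenomeRecord,
    library: ReferenceLibrary,
    aligner: ReferenceAligner | None = None,
) -> list[SeedHit]:
    """Locate CDS matching any seed-role reference (EpsA-EpsE).

    Each qualifying CDS yields exactly one SeedHit carrying its
    best-scoring role.  Pseudogenes are skipped (they cannot anchor a
    cluster but may still join one during expansion).
    """
    if not library.seed_entries():
        raise ValueError("reference library contains no seed-role proteins")
    if aligner is None:
        aligner = ReferenceAligner(
            library, min_identity=SEED_MIN_IDENTITY, min_coverage=SEED_MIN_COVERAGE
        )
    hits = []
    for feat in genome.features:
        if feat.is_pseudo or not feat.translation:
            continue
        best = aligner.best_hit(feat.feature_id, feat.translation, roles=SEED_ROLES)
        if best is None:
            continue
        entry, res = best
        hits.append(
            SeedHit(
                genome_record_id=genome.record_id,
                feature_id=feat.feature_id,
                seed_role=entry.role,
                best_identity=res.percent_identity,
                best_reference_id=entry.ref_id,
            )
        )
    return hits


class RelatednessCache:
    """Memoised 'is this gene EPS-related?' oracle for one run.

    Homology evidence uses the full reference library (all roles);
    annotation keywords are the fallback and the only evidence considered
    for pseudogenes, which stay out of the alignment stages.
    """

    def __init__(self, aligner: ReferenceAligner):
        self.aligner = aligner
        self._cache: dict[str, bool] = {}

    def is_related(self, feat) -> bool:
        if feat.feature_id in self._cache:
            return self._cache[feat.feature_id]
        related = product_is_eps_related(feat.product_text)
        if not related and not feat.is_pseudo and feat.translation:
            related = self.aligner.best_hit(feat.feature_id, feat.translation) is not None
        self._cache[feat.feature_id] = related
        return related


def expand_cluster(
    genome: GenomeRecord,
    seed: SeedHit,
    relatedness: RelatednessCache,
    max_gap: int = DEFAULT_MAX_GAP,
) -> EpsCluster:
    """Expand a seed across the record's feature order into a full cluster.

    Walks left and right; a run of more than ``max_gap`` consecutive
    unrelated genes ends the walk and trailing unrelated genes are trimmed,
    so interior insertions are spanned but flanking housekeeping genes are
    not absorbed.  Adjacency is feature order, not base-pair distance.
    """
    idx = genome.feature_index()
    if seed.feature_id not in idx:
        raise KeyError(f"seed feature {seed.feature_id} not in record {genome.record_id}")
    features = genome.features
    pos = idx[seed.feature_id]

    def walk(direction: int) -> int:
        last_related = pos
        gap = 0
        i = pos + direction
        while 0 <= i < len(features):
            if relatedness.is_related(features[i]):
                last_related = i
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
            i += direction
        return last_related

    lo = walk(-1)
    hi = walk(+1)
    members = [f.feature_id for f in features[lo : hi + 1]]
    strands = [f.strand for f in features[lo : hi + 1]]
    majority = "+" if strands.count("+") >= strands.count("-") else "-"
    return EpsCluster(
        cluster_id=f"{genome.strain}.{genome.record_id}.tmp",
        genome_record_id=genome.record_id,
        strain=genome.strain,
        member_feature_ids=members,
        start=features[lo].start,
        end=features[hi].end,
        strand=majority,
        replicon_kind=genome.replicon_kind,
        seed_feature_ids=[seed.feature_id],
    )


def merge_and_deduplicate(
    clusters: list[EpsCluster], genome: GenomeRecord
) -> list[EpsCluster]:
    """Merge clusters (from one record) sharing any member feature.

    Output is sorted by genomic span and numbered ``strain.record_id.N``;
    strain-level a/b/c display labels are assigned later across records via
    :func:`assign_labels`.
    """
    if not clusters:
        return []
    idx = genome.feature_index()
    merged: list[set[str]] = []
    seeds: list[set[str]] = []
    for cl in clusters:
        mset = set(cl.member_feature_ids)
        sset = set(cl.seed_feature_ids)
        absorbed = None
        for i, existing in enumerate(merged):
            if existing & mset:
                existing |= mset
                seeds[i] |= sset
                absorbed = i
                break
        if absorbed is None:
            merged.append(mset)
            seeds.append(sset)
        else:
            # a merge may bridge two previously disjoint sets
            changed = True
            while changed:
                changed = False
                for i in range(len(merged)):
                    for j in range(i + 1, len(merged)):
                        if merged[i] & merged[j]:
                            merged[i] |= merged.pop(j)
                            seeds[i] |= seeds.pop(j)
                            changed = True
                            break
                    if changed:
                        break
    out = []
    spans = []
    for mset, sset in zip(merged, seeds):
        positions = sorted(idx[fid] for fid in mset)
        lo, hi = positions[0], positions[-1]
        feats = genome.features[lo : hi + 1]
        strands = [f.strand for f in feats]
        spans.append(
            (
                feats[0].start,
                [f.feature_id for f in feats],
                feats[-1].end,
                "+" if strands.count("+") >= strands.count("-") else "-",
                sorted(sset),
            )
        )
    spans.sort(key=lambda t: t[0])
    for n, (start, members, end, strand, seed_ids) in enumerate(spans, start=1):
        out.append(
            EpsCluster(
                cluster_id=f"{genome.strain}.{genome.record_id}.{n}",
                genome_record_id=genome.record_id,
                strain=genome.strain,
                member_feature_ids=members,
                start=start,
                end=end,
                strand=strand,
                replicon_kind=genome.replicon_kind,
                seed_feature_ids=seed_ids,
            )
        )
    return out


def assign_labels(clusters: list[EpsCluster]) -> None:
    """Strain display labels: bare strain name for a single cluster, letter
    suffixes a/b/c... in genomic order when a strain holds several."""
    by_strain: dict[str, list[EpsCluster]] = {}
    for cl in clusters:
        by_strain.setdefault(cl.strain, []).append(cl)
    for strain, group in by_strain.items():
        group.sort(key=lambda c: (c.genome_record_id, c.start))
        if len(group) == 1:
            group[0].label = strain
        else:
            for i, cl in enumerate(group):
                cl.label = f"{strain}_{chr(ord('a') + i)}"


def detect_clusters(
    genome: GenomeRecord,
    library: ReferenceLibrary,
    aligner: ReferenceAligner | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[EpsCluster]:
    """find_seeds + expand + merge for one genome record."""
    if aligner is None:
        aligner = ReferenceAligner(
            library, min_identity=SEED_MIN_IDENTITY, min_coverage=SEED_MIN_COVERAGE
        )
    seeds = find_seeds(genome, library, aligner)
    relatedness = RelatednessCache(aligner)
    expanded = [expand_cluster(genome, s, relatedness, max_gap) for s in seeds]
    expanded = [cl for cl in expanded if len(cl.member_feature_ids) >= 2]
    return merge_and_deduplicate(expanded, genome)


def write_clusters_tsv(clusters: list[EpsCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tlabel\tstrain\trecord\tstart\tend\tstrand\tn_genes\treplicon\tmembers\n")
        for cl in sorted(clusters, key=lambda c: c.cluster_id):
            fh.write(
                f"{cl.cluster_id}\t{cl.label}\t{cl.strain}\t{cl.genome_record_id}\t"
                f"{cl.start}\t{cl.end}\t{cl.strand}\t{len(cl.member_feature_ids)}\t"
                f"{cl.replicon_kind}\t{','.join(cl.member_feature_ids)}\n"
            )
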