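"""Functional role calls for cluster genes and CAZy-style GT families.

Roles come from the best reference-library hit, with annotation keywords
as fallback; flippase (Wzx) and polymerase (Wzy) calls additionally need a
consistent transmembrane topology.  GT family labels require two
independent methods to agree — a best-hit vote and a k-mer containment
vote — otherwise the family stays ``unknown``.
"""
from __future__ import annotations

import re

from .model import GeneFeature, EpsCluster, GtFamilyCall, RoleCall, TmProfile
from .reference import ReferenceAligner, ReferenceLibrary
from . import tm_topology

MIN_WZX_WZY_HELICES = 8

_KEYWORD_ROLES = [
    # order matters: specific names before broad catch-alls
    (re.compile(r"UDP-galactopyranose mutase", re.I), "Precursor:UDP-galactopyranose mutase"),
    (re.compile(r"UDP-glucose 4-epimerase|GalE", re.I), "Precursor:UDP-glucose 4-epimerase"),
    (re.compile(r"glucose-1-phosphate thymidylyltransferase|RmlA", re.I), "Precursor:rmlA"),
    (re.compile(r"dTDP-glucose 4,6-dehydratase|RmlB", re.I), "Precursor:rmlB"),
    (re.compile(r"dTDP-4-dehydrorhamnose 3,5-epimerase|RmlC", re.I), "Precursor:rmlC"),
    (re.compile(r"dTDP-4-dehydrorhamnose reductase|RmlD", re.I), "Precursor:rmlD"),
    (
        re.compile(r"UDP-N-acetylglucosamine[ -]2-epimerase", re.I),
        "Precursor:UDP-N-acetylglucosamine 2-epimerase",
    ),
    (re.compile(r"transposase|insertion element|IS\d+", re.I), "Transposase"),
    (re.compile(r"MarR", re.I), "Regulator:MarR"),
    (re.compile(r"AraC", re.I), "Regulator:AraC"),
    (re.compile(r"adhesin", re.I), "Adhesin"),
    (re.compile(r"priming glycosyltransferase|EpsE", re.I), "EpsE"),
    (re.compile(r"tyrosine kinase modulator|EpsB", re.I), "EpsB"),
    (re.compile(r"phosphotyrosine phosphatase|EpsD", re.I), "EpsD"),
    (re.compile(r"tyrosine[- ]?(protein )?kinase|EpsC", re.I), "EpsC"),
    (re.compile(r"LytR|transcriptional regulator.*polysaccharide|polysaccharide.*transcriptional regulator|EpsA", re.I), "EpsA"),
    (re.compile(r"flippase|Wzx", re.I), "Wzx"),
    (re.compile(r"polysaccharide polymerase|Wzy", re.I), "Wzy"),
    (re.compile(r"glycosyltransferase", re.I), "GT"),
]


def keyword_role(product_text: str) -> str | None:
    for pattern, role in _KEYWORD_ROLES:
        if pattern.search(product_text or ""):
            return role
    return None


def assign_role(
    feature: GeneFeature,
    library: ReferenceLibrary,
    topology: TmProfile | None = None,
    aligner: ReferenceAligner | None = None,
) -> RoleCall:
    """Assign exactly one functional role to a cluster gene.

    Homology (best passing hit over the whole library) outranks keyword
    evidence.  Wzx/Wzy calls demand >= MIN_WZX_WZY_HELICES predicted
    helices; failing that the gene falls to Other.  Pseudogenes are scored
    through their conceptual translation and keep the pseudo flag; a
    protein shorter than half its reference family's median length is
    flagged truncated.
    """
    if aligner is None:
        aligner = ReferenceAligner(library)
    role = None
    evidence = ""
    best_identity = 0.0
    best_ref = ""
    if feature.translation and not feature.is_pseudo:
        hit = aligner.best_hit(feature.feature_id, feature.translation)
    elif feature.translation:
        # conceptual translation of a pseudogene
        hit = aligner.best_hit(feature.feature_id, feature.translation)
    else:
        hit = None
    if hit is not None:
        entry, res = hit
        role = entry.role
        evidence = "homology"
        best_identity = res.percent_identity
        best_ref = entry.ref_id
    else:
        kw = keyword_role(feature.product_text)
        if kw is not None:
            role = kw
            evidence = "keyword"
    if role is None:
        role = "Other"
        evidence = "keyword" if feature.product_text else "homology"
    if role in ("Wzx", "Wzy"):
        if topology is None:
            topology = tm_topology.profile(feature.feature_id, feature.translation)
        if topology.n_helices >= MIN_WZX_WZY_HELICES:
            evidence = "combined"
        else:
            role = "Other"
            evidence = "topology"
    is_truncated = False
    if role in library.roles():
        median = library.role_median_length(role)
        if median > 0 and len(feature.translation) < 0.5 * median:
            is_truncated = True
    return RoleCall(
        feature_id=feature.feature_id,
        role=role,
        evidence=evidence,
        best_identity=best_identity,
        best_reference_id=best_ref,
        is_truncated=is_truncated,
        is_pseudo=feature.is_pseudo,
    )


# ---------------------------------------------------------------------------
# GT family classification (two-method agreement)


def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class GtClassifier:
    """Two independent votes on the CAZy-style family of a GT.

    Method 1: family of the best-scoring reference alignment (identity
    > 30 %, query coverage >= 50 %).  Method 2: family whose concatenated
    reference 4-mer set contains the largest fraction of the query's
    4-mers (containment >= 0.2, and the top family must clear the runner-up
    by > 0.05 to count as a vote).  A family label is emitted only when
    both methods name the same family.
    """

    def __init__(self, library: ReferenceLibrary, aligner: ReferenceAligner | None = None):
        gt_entries = [e for e in library.gt_entries() if e.family]
        if not library.gt_entries():
            raise ValueError("reference library contains no GT proteins")
        self.library = library
        self.aligner = aligner or ReferenceAligner(library)
        self._family_kmers: dict[str, set[str]] = {}
        for e in gt_entries:
            self._family_kmers.setdefault(e.family, set()).update(_kmers(e.sequence))

    def _best_hit_family(self, feature_id: str, seq: str) -> str | None:
        hit = self.aligner.best_hit(feature_id, seq, roles=("GT",))
        if hit is None:
            return None
        return hit[0].family or None

    def _kmer_family(self, seq: str) -> str | None:
        q = _kmers(seq)
        if not q:
            return None
        scored = sorted(
            ((len(q & fam_kmers) / len(q), fam) for fam, fam_kmers in self._family_kmers.items()),
            key=lambda t: (-t[0], t[1]),
        )
        if not scored or scored[0][0] < 0.2:
            return None
        if len(scored) > 1 and scored[0][0] - scored[1][0] <= 0.05:
            return None  # ambiguous profile: no vote
        return scored[0][1]

    def classify(self, feature: GeneFeature) -> GtFamilyCall:
        fam1 = self._best_hit_family(feature.feature_id, feature.translation)
        fam2 = self._kmer_family(feature.translation)
        if fam1 is not None and fam1 == fam2:
            return GtFamilyCall(feature.feature_id, fam1, 2)
        # no family reaches two concurring votes -> unknown; report the
        # largest single-family vote count for diagnostics
        agreement = 1 if (fam1 is not None or fam2 is not None) else 0
        return GtFamilyCall(feature.feature_id, "unknown", agreement)


def classify_gt(
    feature: GeneFeature,
    gt_library: ReferenceLibrary,
    classifier: GtClassifier | None = None,
) -> GtFamilyCall:
    if classifier is None:
        classifier = GtClassifier(gt_library)
    return classifier.classify(feature)


# ---------------------------------------------------------------------------
# precursor inventory


def inventory_precursors(
    cluster: EpsCluster, roles: dict[str, RoleCall]
) -> tuple[dict[str, int], bool]:
    """Count precursor biosynthesis enzymes in a cluster.

    Returns (per-enzyme counts, rml_operon_complete); the dTDP-L-rhamnose
    operon is complete only when rmlA, rmlB, rmlC and rmlD are all present.
    """
    counts: dict[str, int] = {}
    for fid in cluster.member_feature_ids:
        call = roles.get(fid)
        if call is None or not call.role.startswith("Precursor:"):
            continue
        enzyme = call.role.split(":", 1)[1]
        counts[enzyme] = counts.get(enzyme, 0) + 1
    complete = all(counts.get(r, 0) >= 1 for r in ("rmlA", "rmlB", "rmlC", "rmlD"))
    return counts, complete


def write_roles_tsv(
    clusters: list[EpsCluster], roles: dict[str, RoleCall], path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tfeature_id\trole\tevidence\tidentity\tis_truncated\tis_pseudo\n")
        for cl in sorted(clusters, key=lambda c: c.cluster_id):
            for fid in cl.member_feature_ids:
                call = roles[fid]
                fh.write(
                    f"{cl.cluster_id}\t{fid}\t{call.role}\t{call.evidence}\t"
                    f"{call.best_identity:.1f}\t{int(call.is_truncated)}\t{int(call.is_pseudo)}\n"
                )
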