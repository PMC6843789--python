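"""Stage orchestration: detect -> families -> compare, with a run manifest.

The functions here are the programmatic surface the CLI wraps: each stage
consumes in-memory objects (or the files a previous stage wrote under the
run directory) and writes deterministic tab-separated / JSON / Newick
outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster_classification import (
    classify_cluster,
    run_summary,
    write_classification_tsv,
)
from .cluster_detection import (
    DEFAULT_MAX_GAP,
    SEED_MIN_COVERAGE,
    SEED_MIN_IDENTITY,
    assign_labels,
    detect_clusters,
    write_clusters_tsv,
)
from .comparative_analysis import (
    PresenceMatrix,
    build_matrix,
    cut_groups,
    group_habitat_composition,
    habitat_sharing,
    hcl,
    write_matrix,
)
from .family_clustering import (
    LOOSE_INFLATION,
    LOOSE_MIN_IDENTITY,
    MIN_COVERAGE,
    STRICT_INFLATION,
    STRICT_MIN_IDENTITY,
    build_two_level_families,
    diversity_stats,
    write_families_tsv,
)
from .genome_io import read_genbank, read_habitat_tsv, records_to_json, records_from_json
from .homology import write_edges_tsv
from .model import GenomeRecord, HabitatTable
from .reference import ReferenceAligner, ReferenceLibrary
from .role_assignment import GtClassifier, assign_role, write_roles_tsv
from .tm_topology import profile as tm_profile, write_topology_tsv


@dataclass
class RunConfig:
    """All tunables of a run; serialised verbatim into the manifest."""

    seed: int = 42
    seed_min_identity: float = SEED_MIN_IDENTITY
    seed_min_coverage: float = SEED_MIN_COVERAGE
    seed_min_score: int = 100
    max_gap: int = DEFAULT_MAX_GAP
    loose_min_identity: float = LOOSE_MIN_IDENTITY
    strict_min_identity: float = STRICT_MIN_IDENTITY
    min_coverage: float = MIN_COVERAGE
    loose_inflation: float = LOOSE_INFLATION
    strict_inflation: float = STRICT_INFLATION
    matrix_level: str = "strict"
    distance: str = "jaccard"
    linkage: str = "average"
    k_groups: int = 3
    count_truncated_as_missing: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class DetectResult:
    clusters: list
    roles: dict
    gt_calls: dict
    tm_profiles: dict
    classifications: list
    summary: dict
    records: list
    habitat_table: HabitatTable
    library: ReferenceLibrary


def run_detect(
    records: list[GenomeRecord],
    library: ReferenceLibrary,
    habitat_table: HabitatTable,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> DetectResult:
    """Detect clusters, assign roles/topology, classify architecture."""
    aligner = ReferenceAligner(
        library,
        min_identity=config.seed_min_identity,
        min_coverage=config.seed_min_coverage,
        min_score=config.seed_min_score,
    )
    clusters = []
    for rec in records:
        clusters.extend(detect_clusters(rec, library, aligner, config.max_gap))
    assign_labels(clusters)
    record_of = {rec.record_id: rec for rec in records}
    roles = {}
    tm_profiles = {}
    gt_calls = {}
    gt_classifier = GtClassifier(library, aligner) if library.gt_entries() else None
    for cl in clusters:
        rec = record_of[cl.genome_record_id]
        feats = {f.feature_id: f for f in rec.features}
        for fid in cl.member_feature_ids:
            feat = feats[fid]
            topo = tm_profile(fid, feat.translation) if feat.translation else None
            if topo is not None:
                tm_profiles[fid] = topo
            call = assign_role(feat, library, topo, aligner)
            roles[fid] = call
            if gt_classifier is not None and call.role in ("GT", "EpsE") and not call.is_pseudo:
                gt_calls[fid] = gt_classifier.classify(feat)
    classifications = [
        classify_cluster(
            cl, roles, record_of[cl.genome_record_id], config.count_truncated_as_missing
        )
        for cl in clusters
    ]
    summary = run_summary(classifications, clusters, roles)
    result = DetectResult(
        clusters=clusters,
        roles=roles,
        gt_calls=gt_calls,
        tm_profiles=tm_profiles,
        classifications=classifications,
        summary=summary,
        records=records,
        habitat_table=habitat_table,
        library=library,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_clusters_tsv(clusters, out / "clusters.tsv")
        write_roles_tsv(clusters, roles, out / "roles.tsv")
        write_classification_tsv(classifications, out / "classification.tsv")
        write_topology_tsv(
            [tm_profiles[f] for f in sorted(tm_profiles)], out / "topology.tsv"
        )
        with open(out / "gt_families.tsv", "w") as fh:
            fh.write("feature_id\tfamily\tmethod_agreement\n")
            for fid in sorted(gt_calls):
                c = gt_calls[fid]
                fh.write(f"{fid}\t{c.family}\t{c.method_agreement}\n")
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        records_to_json(records, out / "genomes.json")
    return result


@dataclass
class CompareResult:
    strict: object
    loose: object
    edges: list
    stats: object
    matrix: PresenceMatrix
    hcl_result: object
    groups: dict
    group_composition: dict
    sharing: object


def run_compare(
    detect: DetectResult, config: RunConfig, out_dir: str | Path | None = None
) -> CompareResult:
    """Protein families, diversity stats, HCL and habitat sharing."""
    record_of = {rec.record_id: rec for rec in detect.records}
    proteins = {}
    for cl in detect.clusters:
        rec = record_of[cl.genome_record_id]
        feats = {f.feature_id: f for f in rec.features}
        for fid in cl.member_feature_ids:
            call = detect.roles[fid]
            if call.is_pseudo or not feats[fid].translation:
                continue  # pseudogenes stay out of alignment/family stages
            proteins[fid] = feats[fid].translation
    from .homology import all_vs_all

    edges = all_vs_all(
        proteins,
        min_identity=config.loose_min_identity,
        min_coverage=config.min_coverage,
    )
    strict, loose = build_two_level_families(
        proteins,
        loose_min_identity=config.loose_min_identity,
        strict_min_identity=config.strict_min_identity,
        min_coverage=config.min_coverage,
        loose_inflation=config.loose_inflation,
        strict_inflation=config.strict_inflation,
        edges=edges,
    )
    missing_counts = {}
    for c in detect.classifications:
        for gene in c.missing_essential | c.missing_dispensable:
            missing_counts[gene] = missing_counts.get(gene, 0) + 1
    stats = diversity_stats(strict, loose, detect.clusters, detect.roles, missing_counts)
    level = strict if config.matrix_level == "strict" else loose
    matrix = build_matrix(level, detect.clusters)
    habitat_of_strain = {
        s: detect.habitat_table.habitat(s) for s in {cl.strain for cl in detect.clusters}
    }
    hcl_result = hcl(matrix, distance=config.distance, linkage=config.linkage)
    k = min(config.k_groups, len(hcl_result.leaves))
    groups = cut_groups(hcl_result, k)
    habitat_of_cluster = {cl.cluster_id: habitat_of_strain[cl.strain] for cl in detect.clusters}
    composition = group_habitat_composition(groups, habitat_of_cluster)
    sharing = habitat_sharing(level, detect.clusters, detect.roles, habitat_of_strain)
    result = CompareResult(
        strict=strict,
        loose=loose,
        edges=edges,
        stats=stats,
        matrix=matrix,
        hcl_result=hcl_result,
        groups=groups,
        group_composition=composition,
        sharing=sharing,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_families_tsv(strict, loose, out / "families.tsv")
        write_edges_tsv(edges, out / "edges.tsv")
        stats.to_csv(out / "family_stats.tsv", sep="\t")
        write_matrix(matrix, out / "presence_matrix.tsv", out / "presence_matrix.mtx")
        (out / "clusters.nwk").write_text(hcl_result.newick + "\n")
        (out / "groups.tsv").write_text(
            "cluster_id\tgroup\n"
            + "".join(f"{c}\t{g}\n" for c, g in sorted(groups.items()))
        )
        sharing.to_json(out / "habitat_sharing.json")
    return result


def run_all(
    records: list[GenomeRecord],
    library: ReferenceLibrary,
    habitat_table: HabitatTable,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> tuple[DetectResult, CompareResult]:
    t0 = time.time()
    detect = run_detect(records, library, habitat_table, config, out_dir)
    compare = run_compare(detect, config, out_dir)
    if out_dir is not None:
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "elapsed_seconds": round(time.time() - t0, 2),
            "outputs": sorted(
                p.name for p in Path(out_dir).iterdir() if p.is_file()
            ),
        }
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return detect, compare


def load_inputs(
    genome_dir: str | Path, reference_fasta: str | Path, habitat_tsv: str | Path
) -> tuple[list[GenomeRecord], ReferenceLibrary, HabitatTable]:
    """Read a directory of GenBank files plus reference/habitat metadata."""
    genome_dir = Path(genome_dir)
    if not Path(reference_fasta).exists():
        raise FileNotFoundError(f"reference FASTA not found: {reference_fasta}")
    records = []
    paths = sorted(genome_dir.glob("*.gbk")) + sorted(genome_dir.glob("*.gb")) + sorted(
        genome_dir.glob("*.gbff")
    )
    if not paths:
        raise FileNotFoundError(f"no GenBank files (*.gbk, *.gb, *.gbff) in {genome_dir}")
    for p in paths:
        records.extend(read_genbank(p))
    library = ReferenceLibrary.read_fasta(reference_fasta)
    habitat_table = (
        read_habitat_tsv(habitat_tsv) if Path(habitat_tsv).exists() else HabitatTable()
    )
    return records, library, habitat_table
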