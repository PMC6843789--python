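"""The synthetic-genome generator and its truth bookkeeping."""
import filecmp
import json

import numpy as np
import pytest
from scipy.stats import binom

from epsclust.genome_io import compute_gc
from epsclust.homology import align_pair
from epsclust.reference import ReferenceAligner
from epsclust.synthetic_data import (
    GeneSpec,
    SimulationConfig,
    backtranslate,
    build_family_pools,
    generate_run,
    make_template,
    mutate_protein,
    plant_cluster,
    pools_to_library,
    random_protein,
    template_is_generic,
)


def test_mutate_protein_counts_substitutions_exactly(rng):
    ref = random_protein(100, rng)
    same, n0 = mutate_protein(ref, 1.0, rng)
    assert same == ref and n0 == 0
    variant, n = mutate_protein(ref, 0.8, rng)
    assert n == 20
    assert sum(a != b for a, b in zip(ref, variant)) == 20
    assert len(variant) == len(ref)
    assert variant[0] == "M"  # start methionine kept for back-translation


def test_mutate_protein_rejects_unalignable_targets(rng):
    ref = random_protein(50, rng)
    with pytest.raises(ValueError):
        mutate_protein(ref, 0.01, rng)
    with pytest.raises(ValueError):
        mutate_protein(ref, 1.5, rng)


def test_mutant_realigns_near_target_identity(rng):
    devs = []
    for _ in range(10):
        ref = random_protein(200, rng)
        variant, _ = mutate_protein(ref, 0.85, rng)
        devs.append(align_pair(ref, variant).percent_identity - 85.0)
    assert abs(float(np.mean(devs))) <= 2.0


@pytest.mark.parametrize("target", [0.35, 0.45, 0.55])
def test_backtranslation_hits_gc_target_and_round_trips(rng, target):
    from Bio.Seq import Seq

    protein = random_protein(300, rng)
    nt = backtranslate(protein, target, rng)
    assert len(nt) == 3 * (len(protein) + 1)
    assert str(Seq(nt).translate(table=11)).rstrip("*") == protein
    assert compute_gc(nt) == pytest.approx(target, abs=0.02)


def test_plant_cluster_layout_and_truth(rng):
    cfg = SimulationConfig(seed=0, pseudo_prob=0.0, truncation_prob=0.0)
    pools = build_family_pools(cfg, rng)
    template = [
        GeneSpec("epsA", "EpsA.host-adapted.f1"),
        GeneSpec("epsB", "EpsB.host-adapted.f1"),
        GeneSpec("gt", "GT2.host-adapted.f1", cazy="GT2"),
        GeneSpec("wzy", "Wzy.host-adapted.f1"),
    ]
    seq, feats, truth = plant_cluster("", template, pools, cfg, rng, "rec", 1, "+")
    assert [t["symbol"] for t in truth] == ["epsA", "epsB", "gt", "wzy"]
    assert [f.strand for f in feats] == ["+"] * 4
    starts = [f.start for f in feats]
    assert starts == sorted(starts)
    # gt/wzy carry the low-GC offset, regulatory genes the background
    assert truth[2]["target_gc"] == pytest.approx(cfg.background_gc + cfg.low_gc_offset)
    assert truth[0]["target_gc"] == pytest.approx(cfg.background_gc)
    for f, t in zip(feats, truth):
        gene_gc = compute_gc(seq, (f.start, f.end))
        assert gene_gc == pytest.approx(t["target_gc"], abs=0.02)

    # minus-strand planting reverses the genomic order, not the truth order
    seq2, feats2, truth2 = plant_cluster("", template, pools, cfg, rng, "rec2", 1, "-")
    assert [t["symbol"] for t in truth2] == ["epsA", "epsB", "gt", "wzy"]
    id_by_symbol = {t["symbol"]: t["feature_id"] for t in truth2}
    genomic_order = [f.feature_id for f in feats2]
    assert genomic_order == [
        id_by_symbol["wzy"], id_by_symbol["gt"], id_by_symbol["epsB"], id_by_symbol["epsA"]
    ]
    assert all(f.strand == "-" for f in feats2)


def test_template_generic_label_rules():
    five = [
        GeneSpec("epsA", None), GeneSpec("epsB", None), GeneSpec("epsC", None),
        GeneSpec("epsD", None), GeneSpec("epsE", None),
    ]
    tail = [GeneSpec("gt", None), GeneSpec("wzx", None), GeneSpec("wzy", None)]
    assert template_is_generic(five + tail)
    # transposase interleaved in the stretch does not break genericity
    with_is = five[:2] + [GeneSpec("transposase", None)] + five[2:] + tail
    assert template_is_generic(with_is)
    # dropout of epsC breaks it
    assert not template_is_generic(five[:2] + five[3:] + tail)
    # relocation breaks it
    moved = five[1:] + [GeneSpec("epsA", None)] + tail
    assert not template_is_generic(moved)


def test_nomadic_templates_never_contain_epsa(rng):
    cfg = SimulationConfig(seed=3)
    pools = build_family_pools(cfg, rng)
    for _ in range(20):
        template = make_template("nomadic", False, pools, cfg, rng)
        assert all(g.symbol != "epsA" for g in template)
        assert not template_is_generic(template)


def test_generate_run_is_byte_deterministic(tmp_path):
    cfg = SimulationConfig(seed=7, n_genomes=3)
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    generate_run(cfg, out1)
    generate_run(cfg, out2)
    files1 = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes(), rel


def test_cluster_count_distribution_matches_configuration():
    cfg = SimulationConfig(seed=11, n_genomes=60)
    _, _, _, truth = generate_run(cfg)
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for g in truth["genomes"].values():
        counts[g["n_clusters"]] += 1
    n = sum(counts.values())
    assert n == 60
    for k, p in zip((1, 2, 3, 4), cfg.cluster_count_probs):
        lo, hi = binom.ppf(0.025, n, p), binom.ppf(0.975, n, p)
        assert lo <= counts[k] <= hi, (k, counts[k], lo, hi)


def test_truth_table_covers_every_planted_gene(bench):
    seen = set()
    for g in bench.truth["genomes"].values():
        for cl in g["clusters"]:
            for m in cl["members"]:
                assert m["feature_id"] not in seen
                seen.add(m["feature_id"])
                assert m["feature_id"] in bench.truth["proteins"]
                assert m["feature_id"] in bench.features


def test_within_family_identity_brackets_configuration(bench):
    """Planted proteins realign to their family reference close to the
    configured within-family identity on average."""
    pool_refs = {e.ref_id: e.sequence for e in bench.library.entries}
    devs = []
    rng = np.random.default_rng(3)
    members = [
        m
        for cl in bench.planted
        for m in cl["members"]
        if m["family"] in pool_refs and not m["truncated"]
    ]
    for m in rng.choice(len(members), size=30, replace=False):
        entry = members[int(m)]
        seq = bench.features[entry["feature_id"]].translation
        ident = align_pair(seq, pool_refs[entry["family"]]).percent_identity
        devs.append(ident - 100 * bench.cfg.within_family_identity)
    assert abs(float(np.mean(devs))) <= 3.0


def test_housekeeping_pool_never_matches_references(rng):
    """Filler proteins stay invisible to the reference library, so spurious
    seeds cannot arise by construction."""
    cfg = SimulationConfig(seed=23)
    pools = build_family_pools(cfg, rng)
    library = pools_to_library(pools)
    aligner = ReferenceAligner(library)
    for hk_id, seq in pools.housekeeping.items():
        assert aligner.best_hit(hk_id, seq) is None


def test_habitat_pools_structure(bench):
    """Planted cluster proteins draw only from their habitat's pools (plus
    global precursor/transposase references)."""
    pools = build_family_pools(bench.cfg, np.random.default_rng(bench.cfg.seed))
    for strain, g in bench.truth["genomes"].items():
        habitat = g["habitat"]
        for cl in g["clusters"]:
            for m in cl["members"]:
                fam = m["family"]
                if fam is None or fam.startswith("HKPOOL"):
                    continue
                fam_meta = pools.strict_meta[fam]
                assert fam_meta["habitat"] in (habitat, "global"), (strain, fam)
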