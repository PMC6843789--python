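"""Markov clustering, the strict/loose family hierarchy and diversity
statistics."""
import itertools

import numpy as np
import pytest

from epsclust.family_clustering import (
    FamilySet,
    build_two_level_families,
    diversity_stats,
    mcl,
    partition_to_familyset,
    ratio,
    singleton_percent,
)
from epsclust.homology import SimilarityEdge, align_pair
from epsclust.model import EpsCluster, RoleCall
from epsclust.synthetic_data import mutate_protein, random_protein

from oracles import mcl_oracle


def _edge(a, b, identity=90.0):
    a, b = sorted((a, b))
    return SimilarityEdge(a, b, identity, 80.0)


def test_disjoint_cliques_never_merge():
    nodes = [f"p{i}" for i in range(6)]
    edges = [_edge(a, b) for a, b in itertools.combinations(nodes[:3], 2)]
    edges += [_edge(a, b) for a, b in itertools.combinations(nodes[3:], 2)]
    part = mcl(edges, nodes, inflation=2.0)
    assert sorted(map(sorted, part)) == [["p0", "p1", "p2"], ["p3", "p4", "p5"]]


def test_weak_middle_edge_splits_a_path():
    # 6-path with one weak middle edge: the walk concentrates on both halves
    nodes = [f"n{i}" for i in range(6)]
    edges = [
        _edge("n0", "n1", 100.0),
        _edge("n1", "n2", 100.0),
        _edge("n2", "n3", 10.0),  # weak bridge
        _edge("n3", "n4", 100.0),
        _edge("n4", "n5", 100.0),
    ]
    part = mcl(edges, nodes, inflation=2.0)
    assert sorted(map(sorted, part)) == [["n0", "n1", "n2"], ["n3", "n4", "n5"]]
    weighted = [(e.protein_a, e.protein_b, e.percent_identity / 100) for e in edges]
    oracle = mcl_oracle(nodes, weighted, inflation=2.0)
    assert sorted(map(sorted, part)) == sorted(map(sorted, oracle))


def test_isolated_proteins_become_singletons():
    part = mcl([], [f"p{i}" for i in range(5)], inflation=2.0)
    assert sorted(map(sorted, part)) == [["p0"], ["p1"], ["p2"], ["p3"], ["p4"]]


def test_inflation_domain_checked():
    with pytest.raises(ValueError):
        mcl([], ["a"], inflation=1.0)


def test_unknown_edge_endpoint_rejected():
    with pytest.raises(KeyError):
        mcl([_edge("a", "zz")], ["a", "b"], inflation=2.0)


def test_mcl_matches_dense_oracle_on_small_graphs():
    """Partition identity with an independently implemented dense MCL on
    every fixture graph of up to 8 nodes."""
    rng = np.random.default_rng(2024)
    agree = total = 0
    for trial in range(40):
        n = int(rng.integers(2, 9))
        nodes = [f"v{i}" for i in range(n)]
        edges = []
        for a, b in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                ident = float(rng.uniform(30, 100))
                edges.append(_edge(nodes[a], nodes[b], ident))
        for inflation in (1.5, 2.0):
            part = mcl(edges, nodes, inflation=inflation)
            weighted = [(e.protein_a, e.protein_b, e.percent_identity / 100) for e in edges]
            oracle = mcl_oracle(nodes, weighted, inflation=inflation)
            total += 1
            agree += sorted(map(sorted, part)) == sorted(map(sorted, oracle))
    assert agree == total


def test_partition_invariant_to_edge_order_and_relabeling():
    rng = np.random.default_rng(7)
    nodes = [f"p{i}" for i in range(8)]
    edges = [
        _edge(nodes[a], nodes[b], float(rng.uniform(50, 100)))
        for a, b in itertools.combinations(range(8), 2)
        if rng.random() < 0.4
    ]
    base = sorted(map(sorted, mcl(edges, nodes, inflation=2.0)))
    shuffled = list(edges)
    rng.shuffle(shuffled)
    assert sorted(map(sorted, mcl(shuffled, nodes, inflation=2.0))) == base
    # relabel p -> q preserves structure up to renaming
    ren = {n: n.replace("p", "q") for n in nodes}
    redges = [
        SimilarityEdge(*sorted((ren[e.protein_a], ren[e.protein_b])), e.percent_identity, e.min_coverage)
        for e in edges
    ]
    got = sorted(map(sorted, mcl(redges, list(ren.values()), inflation=2.0)))
    assert got == sorted(sorted(ren[m] for m in fam) for fam in base)


def test_family_sizes_conserve_protein_count():
    rng = np.random.default_rng(19)
    nodes = [f"p{i}" for i in range(12)]
    edges = [
        _edge(nodes[a], nodes[b], float(rng.uniform(40, 100)))
        for a, b in itertools.combinations(range(12), 2)
        if rng.random() < 0.3
    ]
    part = mcl(edges, nodes, inflation=2.0)
    fs = partition_to_familyset(part, "strict", "S")
    assert sum(fs.sizes().values()) == len(nodes)
    assert set(fs.assignment) == set(nodes)


def test_two_level_hierarchy_from_counted_substitutions():
    rng = np.random.default_rng(31)
    base = random_protein(250, rng)

    def trio(ref):
        return [mutate_protein(ref, 0.95, rng)[0] for _ in range(3)]

    # one tight family
    proteins = {f"t{i}": p for i, p in enumerate(trio(base))}
    strict, loose = build_two_level_families(proteins)
    assert len(set(strict.assignment.values())) == 1
    assert len(set(loose.assignment.values())) == 1

    # two trios at ~40% between: distinct strict families, one loose family
    ref_a, _ = mutate_protein(base, 0.63, rng)
    ref_b, _ = mutate_protein(base, 0.63, rng)
    between = align_pair(ref_a, ref_b).percent_identity
    assert 35 <= between < 50
    proteins2 = {}
    proteins2.update({f"a{i}": p for i, p in enumerate(trio(ref_a))})
    proteins2.update({f"b{i}": p for i, p in enumerate(trio(ref_b))})
    strict2, loose2 = build_two_level_families(proteins2)
    assert len(set(strict2.assignment.values())) == 2
    assert len(set(loose2.assignment.values())) == 1

    # unrelated trios: distinct at both levels
    ref_c = random_protein(250, rng)
    proteins3 = {}
    proteins3.update({f"a{i}": p for i, p in enumerate(trio(ref_a))})
    proteins3.update({f"c{i}": p for i, p in enumerate(trio(ref_c))})
    strict3, loose3 = build_two_level_families(proteins3)
    assert len(set(strict3.assignment.values())) == 2
    assert len(set(loose3.assignment.values())) == 2


@pytest.mark.parametrize("k", list(range(2, 11)))
def test_planted_family_count_recovered_exactly(k):
    """k families at ~85% within / ~25% between identity come back as
    exactly k strict families with the nesting invariant intact."""
    rng = np.random.default_rng(100 + k)
    base = random_protein(250, rng)
    refs = [mutate_protein(base, 0.5, rng)[0] for _ in range(k)]
    proteins, truth = {}, {}
    for fi, ref in enumerate(refs):
        for m in range(5):
            pid = f"F{fi}_m{m}"
            proteins[pid] = mutate_protein(ref, 0.85, rng)[0]
            truth[pid] = fi
    strict, loose = build_two_level_families(proteins)
    by_family: dict[str, set] = {}
    for pid, fam in strict.assignment.items():
        by_family.setdefault(fam, set()).add(truth[pid])
    assert len(by_family) == k
    assert all(len(sources) == 1 for sources in by_family.values())
    # strict subset of loose: one loose family per strict family
    loose_of_strict: dict[str, str] = {}
    for pid in proteins:
        s = strict.assignment[pid]
        assert loose_of_strict.setdefault(s, loose.assignment[pid]) == loose.assignment[pid]


def test_nesting_invariant_on_benchmark(bench):
    strict, loose = bench.compare.strict, bench.compare.loose
    assert set(strict.assignment) == set(loose.assignment)
    seen: dict[str, str] = {}
    for pid, s in strict.assignment.items():
        assert seen.setdefault(s, loose.assignment[pid]) == loose.assignment[pid]
    assert sum(FamilySet("strict", strict.assignment).sizes().values()) == len(
        strict.assignment
    )


def test_ratio_and_singleton_arithmetic():
    assert ratio(97, 11) == 8.8
    assert ratio(78, 8) == 9.8
    assert ratio(8, 2) == 4.0
    assert ratio(1, 0) == 0.0
    assert singleton_percent([1]) == 100.0
    assert singleton_percent([1, 1, 2, 5]) == 50.0
    assert singleton_percent([]) == 0.0


def test_diversity_stats_columns_on_a_toy_run():
    # two clusters; gt present twice in c1 (two families), once in c2
    roles = {
        "g1": RoleCall("g1", "GT", "homology"),
        "g2": RoleCall("g2", "GT", "homology"),
        "g3": RoleCall("g3", "GT", "homology"),
        "e1": RoleCall("e1", "EpsA", "homology"),
        "p1": RoleCall("p1", "EpsB", "homology", is_pseudo=True),
    }
    strict = FamilySet("strict", {"g1": "S.g1", "g2": "S.g2", "g3": "S.g1", "e1": "S.e1", "p1": "S.p1"})
    loose = FamilySet("loose", {"g1": "L.g1", "g2": "L.g1", "g3": "L.g1", "e1": "L.e1", "p1": "L.p1"})
    clusters = [
        EpsCluster("c1", "r", "s1", ["g1", "g2", "e1", "p1"], 0, 100, "+", "chromosome"),
        EpsCluster("c2", "r", "s2", ["g3"], 0, 100, "+", "chromosome"),
    ]
    stats = diversity_stats(strict, loose, clusters, roles, missing_counts={"wzy": 2})
    gt = stats.loc["gt"]
    assert gt["n_proteins"] == 3
    assert gt["n_strict_families"] == 2
    assert gt["n_loose_families"] == 1
    assert gt["proteins_per_strict_family"] == 1.5
    assert gt["strict_per_loose"] == 2.0
    assert gt["singleton_percent"] == 50.0
    assert gt["n_clusters_with_multicopy"] == 1
    assert gt["mean_copies_when_multicopy"] == 2.0
    assert gt["mean_families_when_multicopy"] == 2.0
    assert stats.loc["wzy", "n_clusters_missing"] == 2
    # pseudogenes never enter the family statistics
    assert stats.loc["epsB", "n_proteins"] == 0
    assert stats.loc["epsA", "singleton_percent"] == 100.0
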