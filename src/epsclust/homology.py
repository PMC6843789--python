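"""Pairwise protein alignment and the all-vs-all similarity graph.

This layer stands in for the BLASTP steps of the original workflow: local
Smith-Waterman alignments under BLOSUM62 with affine gaps (open 11,
extend 1), reported as percent identity plus per-direction query coverage.
No E-values are computed; filtering is by identity/coverage thresholds,
which is self-contained and database-size independent.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from ._sw import BLOSUM62, _sw_core, encode


@dataclass(frozen=True)
class AlignmentParams:
    gap_open: int = 11
    gap_extend: int = 1


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment.

    ``query_coverage`` / ``subject_coverage`` are aligned residues of each
    sequence over its full (unaligned) length, times 100 — the same
    semantics as BLAST's query coverage, evaluated on both sides of the
    single symmetric local alignment.
    """

    query_id: str
    subject_id: str
    score: int
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    aligned_length: int


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge; endpoints stored with a < b."""

    protein_a: str
    protein_b: str
    percent_identity: float
    min_coverage: float


def align_pair(
    a: str,
    b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Best local alignment of two protein sequences.

    Raises ValueError on an empty sequence.  A zero score (nothing aligns
    with positive score) yields identity/coverage 0.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score, matches, cols, a0, a1, b0, b1 = _sw_core(
        encode(a), encode(b), BLOSUM62, params.gap_open, params.gap_extend
    )
    if cols == 0:
        return AlignmentResult(query_id, subject_id, 0, 0.0, 0.0, 0.0, 0)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        percent_identity=100.0 * matches / cols,
        query_coverage=100.0 * (a1 - a0) / len(a),
        subject_coverage=100.0 * (b1 - b0) / len(b),
        aligned_length=cols,
    )


def bidirectional_hit(
    a_id: str,
    a: str,
    b_id: str,
    b: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> SimilarityEdge | None:
    """Reciprocal similarity test at >= min_identity and >= min_coverage.

    Local alignment is symmetric, so one alignment supplies both
    directions: the a-as-query coverage is the aligned fraction of a, the
    b-as-query coverage the aligned fraction of b.  Both must pass.
    """
    res = align_pair(a, b, params, query_id=a_id, subject_id=b_id)
    if (
        res.percent_identity >= min_identity
        and res.query_coverage >= min_coverage
        and res.subject_coverage >= min_coverage
    ):
        pa, pb = sorted((a_id, b_id))
        return SimilarityEdge(
            protein_a=pa,
            protein_b=pb,
            percent_identity=res.percent_identity,
            min_coverage=min(res.query_coverage, res.subject_coverage),
        )
    return None


def all_vs_all(
    proteins: dict[str, str] | list[tuple[str, str]],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> list[SimilarityEdge]:
    """All-against-all reciprocal similarity edges.

    Pairs whose length ratio alone caps the longer sequence's coverage
    below the threshold are skipped — that bound is exact, so the skip can
    never drop a passing pair.
    """
    if not isinstance(proteins, dict):
        check_unique_ids(list(proteins))
        proteins = dict(proteins)
    ids = sorted(proteins)
    seqs = {i: proteins[i] for i in ids}
    for pid, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {pid}")
    edges: list[SimilarityEdge] = []
    for ia, ib in itertools.combinations(ids, 2):
        la, lb = len(seqs[ia]), len(seqs[ib])
        if 100.0 * min(la, lb) / max(la, lb) < min_coverage:
            continue  # coverage of the longer sequence provably < threshold
        edge = bidirectional_hit(
            ia, seqs[ia], ib, seqs[ib], params, min_identity, min_coverage
        )
        if edge is not None:
            edges.append(edge)
    return edges


def check_unique_ids(proteins: list[tuple[str, str]]) -> None:
    seen = set()
    for pid, _ in proteins:
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r}")
        seen.add(pid)


def write_edges_tsv(edges: list[SimilarityEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tidentity\tmin_coverage\n")
        for e in sorted(edges, key=lambda e: (e.protein_a, e.protein_b)):
            fh.write(
                f"{e.protein_a}\t{e.protein_b}\t{e.percent_identity:.2f}\t{e.min_coverage:.2f}\n"
            )
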