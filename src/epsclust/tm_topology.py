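"""Transmembrane helix prediction for Wzx/Wzy candidates.

A hydropathy-based predictor: Kyte-Doolittle averages over a sliding
window (default 19 residues) mark candidate helices, and the
positive-inside rule (cytoplasmic loops are enriched in K/R) orients the
topology.  This is a self-contained approximation of HMM-based predictors
such as TMHMM — adequate for counting helices and calling the termini of
strongly polytopic transporters, not a reproduction of their per-residue
posteriors.
"""
from __future__ import annotations

from .model import TmProfile

# Kyte & Doolittle (1982) hydropathy index
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

WINDOW = 19
THRESHOLD = 1.6
MIN_LOOP = 3


def predict_helices(
    sequence: str,
    window: int = WINDOW,
    threshold: float = THRESHOLD,
    min_loop: int = MIN_LOOP,
) -> list[tuple[int, int]]:
    """Predict transmembrane helix segments as half-open residue ranges.

    Every window position whose mean hydropathy reaches ``threshold`` is a
    candidate; candidates are accepted greedily by descending mean score
    (ties by lower start) provided they keep at least ``min_loop`` residues
    of loop to every previously accepted helix.  Sequences shorter than the
    window yield no helices.
    """
    n = len(sequence)
    if n < window:
        return []
    scores = [KD_HYDROPATHY.get(aa, 0.0) for aa in sequence.upper()]
    acc = 0.0
    means = []
    for i, s in enumerate(scores):
        acc += s
        if i >= window:
            acc -= scores[i - window]
        if i >= window - 1:
            means.append(acc / window)
    candidates = [
        (means[start], start) for start in range(len(means)) if means[start] >= threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[tuple[int, int]] = []
    for _, start in candidates:
        end = start + window
        ok = all(
            end + min_loop <= s or e + min_loop <= start for s, e in accepted
        )
        if ok:
            accepted.append((start, end))
    accepted.sort()
    return accepted


def predict_orientation(
    sequence: str, segments: list[tuple[int, int]]
) -> tuple[str, str]:
    """Orient a predicted topology by the positive-inside rule.

    The loops (tails included) alternate between the two sides of the
    membrane; of the two possible assignments, the one putting more
    lysine+arginine on the cytoplasmic (inside) face wins.  Ties, and
    helix-free proteins, default to an inside N-terminus.
    """
    if not segments:
        return ("inside", "inside")
    seq = sequence.upper()
    bounds = [0] + [b for seg in segments for b in seg] + [len(seq)]
    loop_kr = []
    for i in range(0, len(bounds) - 1, 2):
        lo, hi = bounds[i], bounds[i + 1]
        loop_kr.append(seq[lo:hi].count("K") + seq[lo:hi].count("R"))
    inside_first = sum(loop_kr[0::2])
    inside_second = sum(loop_kr[1::2])
    n_side = "inside" if inside_first >= inside_second else "outside"
    if len(segments) % 2 == 0:
        c_side = n_side
    else:
        c_side = "outside" if n_side == "inside" else "inside"
    return (n_side, c_side)


def profile(feature_id: str, sequence: str, **kwargs) -> TmProfile:
    segments = predict_helices(sequence, **kwargs)
    n_side, c_side = predict_orientation(sequence, segments)
    return TmProfile(
        feature_id=feature_id,
        helix_segments=segments,
        n_terminus_side=n_side,
        c_terminus_side=c_side,
    )


def write_topology_tsv(profiles: list[TmProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tn_helices\tn_side\tc_side\tsegments\n")
        for p in profiles:
            segs = ",".join(f"{s}-{e}" for s, e in p.helix_segments)
            fh.write(
                f"{p.feature_id}\t{p.n_helices}\t{p.n_terminus_side}\t{p.c_terminus_side}\t{segs}\n"
            )
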