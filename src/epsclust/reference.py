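"""Role-tagged reference protein library and a cached aligner over it.

The library plays the part of the characterised EPS-cluster proteins used
to seed the homology search: each entry carries a functional role (EpsA-E,
GT, Wzx, Wzy, a precursor enzyme, Transposase) and, for GTs, a CAZy-style
family label.  FASTA headers follow ``>ref_id role=<role> family=<label>``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .homology import AlignmentParams, AlignmentResult, DEFAULT_PARAMS, align_pair

SEED_ROLES = ("EpsA", "EpsB", "EpsC", "EpsD", "EpsE")


@dataclass(frozen=True)
class ReferenceProtein:
    ref_id: str
    role: str
    family: str  # CAZy-like family for GTs, MCL-pool label otherwise; may be ""
    sequence: str


class ReferenceLibrary:
    def __init__(self, entries: list[ReferenceProtein]):
        if not entries:
            raise ValueError("empty reference library")
        ids = [e.ref_id for e in entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids")
        self.entries = list(entries)
        self._by_role: dict[str, list[ReferenceProtein]] = {}
        for e in entries:
            self._by_role.setdefault(e.role, []).append(e)

    def roles(self) -> list[str]:
        return sorted(self._by_role)

    def by_role(self, role: str) -> list[ReferenceProtein]:
        return self._by_role.get(role, [])

    def seed_entries(self) -> list[ReferenceProtein]:
        return [e for e in self.entries if e.role in SEED_ROLES]

    def gt_entries(self) -> list[ReferenceProtein]:
        return [e for e in self.entries if e.role == "GT"]

    def role_median_length(self, role: str) -> float:
        lens = sorted(len(e.sequence) for e in self.by_role(role))
        if not lens:
            return 0.0
        mid = len(lens) // 2
        if len(lens) % 2:
            return float(lens[mid])
        return (lens[mid - 1] + lens[mid]) / 2.0

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.ref_id} role={e.role.replace(' ', '_')} family={e.family}\n")
                for i in range(0, len(e.sequence), 70):
                    fh.write(e.sequence[i : i + 70] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferenceLibrary":
        entries = []
        header = None
        chunks: list[str] = []

        def flush():
            if header is None:
                return
            m_role = re.search(r"role=(\S+)", header)
            m_fam = re.search(r"family=(\S*)", header)
            if m_role is None:
                raise ValueError(f"reference header lacks role tag: {header!r}")
            role = m_role.group(1)
            if role.startswith("Precursor:"):
                role = "Precursor:" + role.split(":", 1)[1].replace("_", " ")
            entries.append(
                ReferenceProtein(
                    ref_id=header.split()[0],
                    role=role,
                    family=m_fam.group(1) if m_fam else "",
                    sequence="".join(chunks),
                )
            )

        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    chunks = []
                elif line:
                    chunks.append(line.strip())
        flush()
        return cls(entries)


class ReferenceAligner:
    """Aligns query proteins against the library, caching by query id.

    A pair is skipped without alignment when the length ratio alone proves
    the required coverage cannot be met.
    """

    def __init__(
        self,
        library: ReferenceLibrary,
        params: AlignmentParams = DEFAULT_PARAMS,
        min_identity: float = 30.0,
        min_coverage: float = 50.0,
        min_score: int = 100,
    ):
        # min_score replaces an E-value cut-off: chance local alignments
        # between unrelated proteins rarely exceed raw score ~60 at these
        # lengths, while genuine homologs at the identity/coverage bar
        # score several-fold higher
        self.library = library
        self.params = params
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.min_score = min_score
        self._cache: dict[str, tuple[ReferenceProtein, AlignmentResult] | None] = {}

    def best_hit(
        self, query_id: str, sequence: str, roles: tuple[str, ...] | None = None
    ) -> tuple[ReferenceProtein, AlignmentResult] | None:
        """Best passing hit (by score, ties by identity then ref_id).

        The hit must reach ``min_identity`` and ``min_coverage`` on the
        query side, i.e. at least half of the gene product must align so
        that short spurious local matches never assign a role, while
        truncated but genuine cluster genes still do.
        """
        key = query_id if roles is None else f"{query_id}|{','.join(roles)}"
        if key in self._cache:
            return self._cache[key]
        best: tuple[ReferenceProtein, AlignmentResult] | None = None
        for entry in self.library.entries:
            if roles is not None and entry.role not in roles:
                continue
            lq, lr = len(sequence), len(entry.sequence)
            if 100.0 * min(lq, lr) / lq < self.min_coverage:
                continue  # query coverage provably below threshold
            res = align_pair(sequence, entry.sequence, self.params, query_id, entry.ref_id)
            if (
                res.percent_identity <= self.min_identity
                or res.query_coverage < self.min_coverage
                or res.score < self.min_score
            ):
                continue
            if best is None:
                best = (entry, res)
            else:
                cur = (best[1].score, best[1].percent_identity)
                new = (res.score, res.percent_identity)
                if new > cur or (new == cur and entry.ref_id < best[0].ref_id):
                    best = (entry, res)
        self._cache[key] = best
        return best
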