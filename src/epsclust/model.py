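"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open throughout; GenBank's 1-based inclusive
intervals are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

HABITATS = ("host-adapted", "nomadic", "free-living")
UNKNOWN_HABITAT = "unknown"

#: Gene roles recognised inside EPS clusters.  ``Precursor:<enzyme>`` and
#: ``Regulator:<family>`` are open sub-vocabularies (see PRECURSOR_ENZYMES).
CORE_ROLES = (
    "EpsA", "EpsB", "EpsC", "EpsD", "EpsE",
    "GT", "Wzx", "Wzy", "Transposase", "Adhesin", "Other",
)

#: Controlled vocabulary of activated-sugar precursor biosynthesis enzymes.
PRECURSOR_ENZYMES = (
    "UDP-galactopyranose mutase",
    "UDP-glucose 4-epimerase",
    "rmlA",
    "rmlB",
    "rmlC",
    "rmlD",
    "UDP-N-acetylglucosamine 2-epimerase",
)

#: Genes required for heteropolysaccharide assembly via the Wzy-dependent
#: pathway; a cluster missing any of these is "incomplete".
ESSENTIAL_GENES = ("epsE", "gt", "wzx", "wzy", "epsC", "epsB")
DISPENSABLE_GENES = ("epsA", "epsD")

#: RoleCall role -> lower-case gene symbol used in completeness accounting.
ROLE_TO_GENE = {
    "EpsA": "epsA", "EpsB": "epsB", "EpsC": "epsC", "EpsD": "epsD",
    "EpsE": "epsE", "GT": "gt", "Wzx": "wzx", "Wzy": "wzy",
}


@dataclass
class GeneFeature:
    """One CDS: genomic interval, strand, conceptual translation, annotation."""

    feature_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str
    product_text: str = ""
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be '+' or '-'")
        if not self.translation and not self.is_pseudo:
            raise ValueError(f"feature {self.feature_id}: empty translation on a non-pseudo CDS")


@dataclass
class GenomeRecord:
    """One replicon (chromosome or plasmid) with its ordered CDS features."""

    record_id: str
    strain: str
    species: str
    replicon_kind: str  # chromosome | plasmid | unknown
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.feature_id} extends past record {self.record_id} "
                    f"({f.end} > {len(self.sequence)})"
                )

    def feature_index(self) -> dict[str, int]:
        """Map feature_id -> position in genomic feature order."""
        return {f.feature_id: i for i, f in enumerate(self.features)}

    def get_feature(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


class HabitatTable:
    """strain -> (species, habitat) lookup with species fallback.

    Habitat labels are assigned at species level but strains carry them in
    the outputs, so an unseen strain of a known species resolves through the
    species; anything else resolves to ``unknown`` rather than erroring.
    """

    def __init__(self, entries: dict[str, tuple[str, str]] | None = None) -> None:
        self._by_strain: dict[str, tuple[str, str]] = {}
        self._by_species: dict[str, str] = {}
        for strain, (species, habitat) in (entries or {}).items():
            self.add(strain, species, habitat)

    def add(self, strain: str, species: str, habitat: str) -> None:
        if habitat not in HABITATS and habitat != UNKNOWN_HABITAT:
            raise ValueError(
                f"habitat {habitat!r} for strain {strain!r} not in "
                f"{HABITATS + (UNKNOWN_HABITAT,)}"
            )
        self._by_strain[strain] = (species, habitat)
        self._by_species.setdefault(species, habitat)

    def habitat(self, strain: str, species: str | None = None) -> str:
        if strain in self._by_strain:
            return self._by_strain[strain][1]
        if species is not None and species in self._by_species:
            return self._by_species[species]
        return UNKNOWN_HABITAT

    def species(self, strain: str) -> str:
        if strain in self._by_strain:
            return self._by_strain[strain][0]
        return "unknown"

    def strains(self) -> list[str]:
        return sorted(self._by_strain)

    def __len__(self) -> int:
        return len(self._by_strain)


@dataclass(frozen=True)
class SeedHit:
    """A CDS matching one of the conserved seed proteins (EpsA-EpsE)."""

    genome_record_id: str
    feature_id: str
    seed_role: str
    best_identity: float
    best_reference_id: str


@dataclass
class EpsCluster:
    """An ordered run of cluster genes on one replicon."""

    cluster_id: str
    genome_record_id: str
    strain: str
    member_feature_ids: list[str]
    start: int
    end: int
    strand: str  # strand of the majority of members
    replicon_kind: str
    seed_feature_ids: list[str] = field(default_factory=list)
    label: str = ""  # strain plus a/b/c suffix when a strain has several clusters


@dataclass(frozen=True)
class RoleCall:
    feature_id: str
    role: str
    evidence: str  # homology | keyword | topology | combined
    best_identity: float = 0.0
    best_reference_id: str = ""
    is_truncated: bool = False
    is_pseudo: bool = False


@dataclass(frozen=True)
class GtFamilyCall:
    feature_id: str
    family: str  # e.g. GT2, GT4, ... or "unknown"
    method_agreement: int

    def __post_init__(self) -> None:
        if self.family != "unknown" and self.method_agreement < 2:
            raise ValueError("a named GT family requires at least two concurring methods")


@dataclass
class TmProfile:
    """Transmembrane topology summary for one protein."""

    feature_id: str
    helix_segments: list[tuple[int, int]]
    n_terminus_side: str  # inside | outside
    c_terminus_side: str

    @property
    def n_helices(self) -> int:
        return len(self.helix_segments)
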