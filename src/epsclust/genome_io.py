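"""Reading and writing annotated genomes and run metadata.

GenBank flat files are the preferred input; GFF3 + genomic FASTA is the
alternative route and must yield the identical internal model for the same
locus.  All coordinates are converted to 0-based half-open on input.
"""
from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, GenomeRecord, HabitatTable

TRANSLATION_TABLE = 11  # bacterial


def _translate_cds(nt: str, phase: int = 0) -> str:
    """Translate a CDS nucleotide string (already on the coding strand).

    Trailing partial codons and a trailing stop are dropped.  A CDS that
    does not begin with a start codon is translated from the first in-frame
    codon with a warning (partial CDS).
    """
    nt = nt[phase:]
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        return ""
    if nt[:3].upper() not in ("ATG", "GTG", "TTG"):
        warnings.warn("CDS without a start codon; translating from the first in-frame codon")
    aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    # internal stops arise only in pseudogenes; keep the prefix
    if "*" in aa:
        aa = aa.split("*")[0]
    return aa


def _feature_translation(feat: GeneFeature, sequence: str, phase: int = 0) -> str:
    nt = sequence[feat.start : feat.end]
    if feat.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    return _translate_cds(nt, phase)


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecords (one per LOCUS).

    /translation qualifiers are used verbatim; CDS lacking one are
    translated from the spanned sequence (table 11, honouring
    /codon_start).  /pseudo marks pseudogenes.  A record whose LOCUS or
    DEFINITION mentions "plasmid" is typed as a plasmid replicon.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise ValueError(f"unparseable GenBank file {path}: no LOCUS records found")
    out = []
    for rec in seq_records:
        strain = rec.annotations.get("source", "") or rec.id
        species = rec.annotations.get("organism", "") or "unknown"
        for feat in rec.features:
            if feat.type == "source":
                strain = feat.qualifiers.get("strain", [strain])[0]
                species = feat.qualifiers.get("organism", [species])[0]
        text = f"{rec.description} {rec.id} {rec.annotations.get('topology', '')}".lower()
        replicon = "plasmid" if "plasmid" in text else "chromosome"
        sequence = str(rec.seq).upper()
        features = []
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            fid = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("protein_id", [f"{rec.id}_cds{i}"])
            )[0]
            is_pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
            product = feat.qualifiers.get("product", [""])[0]
            translation = feat.qualifiers.get("translation", [""])[0]
            if not translation:
                phase = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
                nt = sequence[start:end]
                if strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                translation = _translate_cds(nt, phase)
            features.append(
                GeneFeature(
                    feature_id=fid,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation,
                    product_text=product,
                    is_pseudo=is_pseudo,
                )
            )
        if not features:
            warnings.warn(f"record {rec.id} in {path} contains no CDS features")
        out.append(
            GenomeRecord(
                record_id=rec.id,
                strain=strain,
                species=species,
                replicon_kind=replicon,
                sequence=sequence,
                features=features,
            )
        )
    return out


def read_gff_fasta(gff_path: str | Path, fasta_path: str | Path) -> list[GenomeRecord]:
    """Parse GFF3 annotation plus genomic FASTA into GenomeRecords.

    Produces the same model as :func:`read_genbank`; CDS phase is honoured
    during translation.  Every GFF seqid must exist in the FASTA.
    """
    import gffutils

    fasta = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    cds_by_seqid: dict[str, list] = {sid: [] for sid in fasta}
    missing = set()
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        db = None  # annotation body empty: records carry no features
    if db is not None:
        for feat in db.all_features(featuretype="CDS"):
            if feat.seqid not in fasta:
                missing.add(feat.seqid)
                continue
            cds_by_seqid[feat.seqid].append(feat)
    if missing:
        raise ValueError(
            "GFF seqids absent from the FASTA: " + ", ".join(sorted(missing))
        )
    out = []
    for seqid in fasta:
        sequence = fasta[seqid]
        features = []
        for i, feat in enumerate(cds_by_seqid[seqid]):
            start = feat.start - 1  # GFF is 1-based inclusive
            end = feat.end
            strand = "-" if feat.strand == "-" else "+"
            fid = feat.attributes.get("ID", [f"{seqid}_cds{i}"])[0]
            product = feat.attributes.get("product", [""])[0]
            is_pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
            phase = int(feat.frame) if feat.frame not in (".", None) else 0
            gf = GeneFeature(
                feature_id=fid,
                start=start,
                end=end,
                strand=strand,
                translation="x",  # placeholder, replaced below
                product_text=product,
                is_pseudo=is_pseudo,
            )
            gf.translation = _feature_translation(gf, sequence, phase)
            if not gf.translation and not is_pseudo:
                gf.is_pseudo = True
            features.append(gf)
        if not features:
            warnings.warn(f"no CDS features for {seqid} in {gff_path}")
        out.append(
            GenomeRecord(
                record_id=seqid,
                strain=seqid,
                species="unknown",
                replicon_kind="plasmid" if "plasmid" in seqid.lower() else "chromosome",
                sequence=sequence,
                features=features,
            )
        )
    return out


def compute_gc(sequence: str, interval: tuple[int, int] | None = None) -> float:
    """GC fraction (G+C)/(A+C+G+T) over an optional half-open interval.

    N (and any other ambiguity letter) is excluded from numerator and
    denominator; an interval with no unambiguous base returns NaN.
    """
    if interval is not None:
        lo, hi = interval
        if lo < 0 or hi > len(sequence) or lo > hi:
            raise ValueError(f"interval {interval} outside sequence of length {len(sequence)}")
        sequence = sequence[lo:hi]
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# habitat metadata


def read_habitat_tsv(path: str | Path) -> HabitatTable:
    """Read strain metadata TSV with header ``strain\\tspecies\\thabitat``."""
    table = HabitatTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["strain", "species", "habitat"]:
            raise ValueError(f"unexpected habitat TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            strain, species, habitat = line.rstrip("\n").split("\t")[:3]
            table.add(strain, species, habitat)
    return table


def write_habitat_tsv(table: HabitatTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tspecies\thabitat\n")
        for strain in table.strains():
            fh.write(f"{strain}\t{table.species(strain)}\t{table.habitat(strain)}\n")


# ---------------------------------------------------------------------------
# JSON round-trip of the internal model


def records_to_json(records: list[GenomeRecord], path: str | Path) -> None:
    payload = [
        {
            "record_id": r.record_id,
            "strain": r.strain,
            "species": r.species,
            "replicon_kind": r.replicon_kind,
            "sequence": r.sequence,
            "features": [
                {
                    "feature_id": f.feature_id,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "translation": f.translation,
                    "product_text": f.product_text,
                    "is_pseudo": f.is_pseudo,
                }
                for f in r.features
            ],
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def records_from_json(path: str | Path) -> list[GenomeRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        GenomeRecord(
            record_id=r["record_id"],
            strain=r["strain"],
            species=r["species"],
            replicon_kind=r["replicon_kind"],
            sequence=r["sequence"],
            features=[GeneFeature(**f) for f in r["features"]],
        )
        for r in payload
    ]


# ---------------------------------------------------------------------------
# GenBank writing (used by the synthetic generator)


def write_genbank(records: list[GenomeRecord], path: str | Path) -> None:
    seq_records = []
    for r in records:
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.record_id,
            name=r.record_id[:16].replace(".", "_"),
            description=f"{r.species} strain {r.strain}"
            + (", plasmid" if r.replicon_kind == "plasmid" else ", complete genome"),
            annotations={
                "molecule_type": "DNA",
                "organism": r.species,
                "source": r.strain,
                "topology": "circular",
            },
        )
        src = SeqFeature(FeatureLocation(0, len(r.sequence)), type="source")
        src.qualifiers["organism"] = [r.species]
        src.qualifiers["strain"] = [r.strain]
        rec.features.append(src)
        for f in r.features:
            feat = SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
            )
            feat.qualifiers["locus_tag"] = [f.feature_id]
            if f.product_text:
                feat.qualifiers["product"] = [f.product_text]
            if f.is_pseudo:
                feat.qualifiers["pseudo"] = [None]
            else:
                feat.qualifiers["translation"] = [f.translation]
            rec.features.append(feat)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "genbank")
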