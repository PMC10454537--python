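"""Annotated mitogenome I/O and feature classification.

Mitochondrial genomes of Agaricales fungi are circular molecules of roughly
40-260 kb carrying 15 conserved protein-coding genes (core PCGs), the two
ribosomal RNAs *rns*/*rnl*, ~24-28 tRNAs, group I/II introns (often hosting
homing-endonuclease genes, HEGs) and a variable complement of uncharacterised
open reading frames (un_ORFs).  This module reads and writes such genomes in
GenBank flat-file format, resolves multi-exon coding sequences on the circle
(including features that span the sequence origin) and assigns every feature
to one of the composition classes used throughout the package.

Coordinates are 1-based inclusive internally, matching the GenBank dialect;
any BED-style export converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 15 conserved mitochondrial protein-coding genes of fungi.
CORE_PCGS = frozenset(
    {
        "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
    }
)

#: Case-insensitive substrings marking a product as a homing-endonuclease /
#: mobile-element gene.
HEG_KEYWORDS = (
    "laglidadg",
    "giy-yig",
    "giy",
    "homing endonuclease",
    "reverse transcriptase",
)

FEATURE_KINDS = frozenset(
    {"core_pcg", "rrna", "trna", "heg", "un_orf", "intron", "exon_segment"}
)

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (uppercase)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class GenbankParseError(ValueError):
    """Raised when a GenBank record cannot be parsed into a MitogenomeRecord."""


class FeatureValidationError(ValueError):
    """Raised when a feature's coordinates fall outside the sequence."""


@dataclass
class Feature:
    """A typed annotation on a mitogenome.

    ``segments`` are ordered (start, end) pairs, 1-based inclusive, listed in
    genome order.  On circular molecules a single feature may wrap the origin,
    in which case its last segment ends at the sequence end and the wrap
    continues in a first-of-next-round segment.
    """

    name: str
    kind: str
    strand: str = "+"
    segments: list[tuple[int, int]] = field(default_factory=list)
    product: str = ""
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]


@dataclass
class MitogenomeRecord:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    organism: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in {"circular", "linear"}:
            raise ValueError(f"topology must be circular/linear, got {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        for feat in self.features:
            for s, e in feat.segments:
                if not (1 <= s <= e <= self.length):
                    raise FeatureValidationError(
                        f"feature {feat.name}: segment {s}..{e} outside 1..{self.length}"
                    )


def segment_sequence(record: MitogenomeRecord, start: int, end: int) -> str:
    """Plus-strand sequence of a 1-based inclusive segment."""
    if not (1 <= start <= end <= record.length):
        raise FeatureValidationError(
            f"segment {start}..{end} outside 1..{record.length}"
        )
    return record.sequence[start - 1 : end]


def extract_cds(record: MitogenomeRecord, feature: Feature) -> str:
    """Spliced coding sequence of a (possibly multi-exon) gene.

    Exon segments are concatenated in genome order and the concatenation is
    reverse-complemented for minus-strand genes, matching the semantics of
    GenBank ``complement(join(...))`` locations.  Intron sequence never
    appears in the output.
    """
    if feature.kind not in {"core_pcg", "un_orf", "heg", "rrna", "trna"}:
        raise ValueError(f"cannot extract CDS from kind {feature.kind!r}")
    parts = [segment_sequence(record, s, e) for s, e in feature.segments]
    seq = "".join(parts)
    return reverse_complement(seq) if feature.strand == "-" else seq


def classify_features(record: MitogenomeRecord) -> dict[int, str]:
    """Assign each non-intron feature to {core_pcg, rna, heg, un_orf}.

    Keys are indices into ``record.features``.  Classification is by gene
    symbol for the 17 conserved markers and tRNAs, and by product keyword for
    HEGs; everything else defaults to un_orf (with a warning, so curation
    gaps are visible in logs).
    """
    classes: dict[int, str] = {}
    for i, feat in enumerate(record.features):
        if feat.kind in {"intron", "exon_segment"}:
            continue
        name = feat.name
        if name in CORE_PCGS:
            classes[i] = "core_pcg"
        elif name in {"rns", "rnl"} or name.startswith("trn") or feat.kind in {"rrna", "trna"}:
            classes[i] = "rna"
        elif is_heg_product(feat.product):
            classes[i] = "heg"
        else:
            if feat.kind not in {"un_orf", "heg", "core_pcg"}:
                log.warning("feature %s defaulted to un_orf", name)
            classes[i] = "un_orf"
    return classes


def is_heg_product(product: str) -> bool:
    p = product.lower()
    return any(k in p for k in HEG_KEYWORDS)


# ---------------------------------------------------------------------------
# GenBank reading


def _location_to_segments(loc) -> tuple[list[tuple[int, int]], str]:
    """Convert a Biopython location to ordered 1-based inclusive segments."""
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    segments = [(int(p.start) + 1, int(p.end)) for p in parts]
    strand = "-" if loc.strand == -1 else "+"
    if strand == "-":
        # Biopython lists complement(join(...)) parts in transcription order;
        # store in genome order.
        segments = sorted(segments)
    return segments, strand


_KIND_BY_GB_TYPE = {"tRNA": "trna", "rRNA": "rrna", "intron": "intron"}


def _feature_name(sf: SeqFeature) -> str:
    q = sf.qualifiers
    for key in ("gene", "locus_tag", "label", "note"):
        if key in q and q[key]:
            return str(q[key][0]).split()[0]
    return sf.type


def _classify_cds_kind(name: str, product: str) -> str:
    if name in CORE_PCGS:
        return "core_pcg"
    if is_heg_product(product):
        return "heg"
    return "un_orf"


def from_seqrecord(rec: SeqRecord) -> MitogenomeRecord:
    """Build a MitogenomeRecord from a parsed Biopython SeqRecord."""
    seq = str(rec.seq).upper()
    if not seq:
        raise GenbankParseError(f"record {rec.id}: missing ORIGIN sequence")
    topology = rec.annotations.get("topology", "circular")
    organism = rec.annotations.get("organism", rec.description or rec.id)
    features: list[Feature] = []
    seen_cds_for_gene: set[tuple[str, tuple]] = set()
    for sf in rec.features:
        if sf.type == "source":
            continue
        segments, strand = _location_to_segments(sf.location)
        product = str(sf.qualifiers.get("product", [""])[0])
        name = _feature_name(sf)
        host = sf.qualifiers.get("gene", [None])[0] if sf.type == "intron" else None
        if sf.type == "CDS":
            kind = _classify_cds_kind(name, product)
        elif sf.type in _KIND_BY_GB_TYPE:
            kind = _KIND_BY_GB_TYPE[sf.type]
        elif sf.type == "gene":
            # gene features shadow their CDS/tRNA/rRNA children; skip to avoid
            # double counting
            continue
        else:
            kind = "un_orf"
        key = (name, tuple(segments))
        if key in seen_cds_for_gene:
            continue
        seen_cds_for_gene.add(key)
        features.append(
            Feature(
                name=name,
                kind=kind,
                strand=strand,
                segments=segments,
                product=product,
                host_gene=host,
            )
        )
    record = MitogenomeRecord(
        id=rec.id, organism=organism, sequence=seq, topology=topology, features=features
    )
    record.validate()
    return record


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a single-record GenBank flat file into a MitogenomeRecord."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenbankParseError(f"{path}: {exc}") from exc
    return from_seqrecord(rec)


def read_genbank_dir(path: str | Path) -> list[MitogenomeRecord]:
    """Read every *.gb / *.gbk file in a directory, sorted by filename."""
    paths = sorted(Path(path).glob("*.gb")) + sorted(Path(path).glob("*.gbk"))
    return [read_genbank(p) for p in paths]


# ---------------------------------------------------------------------------
# GenBank writing


_GB_TYPE_BY_KIND = {
    "core_pcg": "CDS",
    "heg": "CDS",
    "un_orf": "CDS",
    "trna": "tRNA",
    "rrna": "rRNA",
    "intron": "intron",
}


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description=record.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": record.topology,
            "organism": record.organism,
            "date": "01-JAN-2023",  # fixed so output is byte-reproducible
        },
    )
    for feat in record.features:
        strand = -1 if feat.strand == "-" else 1
        locs = [SimpleLocation(s - 1, e, strand) for s, e in feat.segments]
        if strand == -1:
            locs = locs[::-1]  # transcription order for complement(join(...))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        q: dict[str, list[str]] = {"gene": [feat.name]}
        if feat.product:
            q["product"] = [feat.product]
        if feat.kind == "intron" and feat.host_gene:
            q["gene"] = [feat.host_gene]
            q["note"] = [f"intron in {feat.host_gene}"]
        rec.features.append(SeqFeature(loc, type=_GB_TYPE_BY_KIND[feat.kind], qualifiers=q))
    return rec


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(record), str(path), "genbank")


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.id, description=record.organism)
    SeqIO.write(rec, str(path), "fasta")


def feature_table(record: MitogenomeRecord) -> "pandas.DataFrame":  # noqa: F821
    """Flat TSV-ready table of features (one row per segment).

    Exported coordinates are 0-based half-open (BED convention).
    """
    import pandas as pd

    rows = []
    for feat in record.features:
        for s, e in feat.segments:
            rows.append(
                {
                    "genome": record.id,
                    "name": feat.name,
                    "kind": feat.kind,
                    "strand": feat.strand,
                    "start": s - 1,
                    "end": e,
                    "product": feat.product,
                    "host_gene": feat.host_gene or "",
                }
            )
    return pd.DataFrame(rows)


def get_gene(record: MitogenomeRecord, name: str) -> Feature | None:
    """First non-intron feature with the given gene symbol, or None."""
    for feat in record.features:
        if feat.name == name and feat.kind not in {"intron", "exon_segment"}:
            return feat
    return None
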