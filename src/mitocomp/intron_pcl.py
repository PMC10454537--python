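"""Intron insertion sites (position classes, Pcl) in reference coordinates.

Fungal mitochondrial genes — cox1 above all — carry variable complements of
group I/II introns.  An intron's insertion site is characterised by the
position class (Pcl): the coordinate, in a reference species' spliced cox1
CDS, of the exonic base immediately 5' of the insertion point.  A site
present in at least 20% of the surveyed panel is called a common insertion
site, the rest rare.

Site extraction reads exon junctions straight from the annotation (spliced
CDS coordinates); projection onto the reference runs through a deterministic
global alignment (match 1, mismatch -1, gap open -5, extend -1).  When the
junction column has a reference gap, the nearest aligned reference base 5'
of it supplies the label and the assignment is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .evolution import global_align
from .genbank_io import MitogenomeRecord

__all__ = [
    "IntronSite",
    "PclAssignment",
    "extract_intron_sites",
    "map_to_reference",
    "classify_pcls",
    "COMMON_PREVALENCE",
]

#: Panel prevalence at or above which a Pcl counts as a common insertion site.
COMMON_PREVALENCE = 0.20


@dataclass(frozen=True)
class IntronSite:
    species: str
    host_gene: str
    query_pos: int  # spliced CDS coordinate of the last exon base 5' of the intron
    group: str = "unknown"  # {I, II, unknown}; passthrough from annotation


@dataclass
class PclAssignment:
    label: str
    species_set: set[str] = field(default_factory=set)
    prevalence: float = 0.0
    status: str = "rare"


def extract_intron_sites(
    record: MitogenomeRecord, gene: str, species: str | None = None
) -> list[IntronSite]:
    """Intron insertion sites of one gene, in spliced CDS coordinates.

    One site per inter-exon junction; a single-exon gene yields an empty
    list.  Positions are cumulative exon lengths in transcription order.
    """
    feat = None
    for f in record.features:
        if f.name == gene and f.kind not in {"intron", "exon_segment"}:
            feat = f
            break
    if feat is None:
        raise ValueError(f"gene {gene!r} not annotated in {record.id}")
    segs = sorted(feat.segments)
    if feat.strand == "-":
        # transcription order is right-to-left on the genome
        exon_lengths = [e - s + 1 for s, e in reversed(segs)]
    else:
        exon_lengths = [e - s + 1 for s, e in segs]
    sites = []
    pos = 0
    sp = species or record.id
    for length in exon_lengths[:-1]:
        pos += length
        sites.append(IntronSite(species=sp, host_gene=gene, query_pos=pos))
    return sites


def project_position(ref_aln: str, query_aln: str, query_pos: int) -> tuple[int, bool]:
    """Project a 1-based query coordinate through an alignment to the reference.

    Returns (reference position, flagged): flagged is True when the query base
    sits in a reference gap run and the nearest 5' aligned reference base was
    used instead.
    """
    if query_pos < 1:
        raise ValueError(f"query_pos must be >= 1, got {query_pos}")
    qcount = rcount = 0
    last_ref_at_query = 0
    for rbase, qbase in zip(ref_aln, query_aln):
        if rbase != "-":
            rcount += 1
        if qbase != "-":
            qcount += 1
            if qcount == query_pos:
                if rbase != "-":
                    return rcount, False
                return (rcount, True) if rcount else (1, True)
    raise ValueError(f"query_pos {query_pos} beyond aligned query length {qcount}")


def map_to_reference(
    query_cds: str, reference_cds: str, sites: list[IntronSite]
) -> list[tuple[IntronSite, str, bool]]:
    """Assign Pcl labels ("P" + reference position) to query intron sites.

    Both CDSs must be spliced (intron-free).  Returns
    (site, label, flagged) triples; flagged marks junctions that fell inside
    a reference gap.
    """
    for site in sites:
        if not (1 <= site.query_pos < len(query_cds)):
            raise ValueError(
                f"site {site.query_pos} outside 1..{len(query_cds) - 1} for {site.species}"
            )
    if not sites:
        return []
    aln = global_align(reference_cds, query_cds)
    out = []
    for site in sites:
        ref_pos, flagged = project_position(aln.seq_a, aln.seq_b, site.query_pos)
        out.append((site, f"P{ref_pos}", flagged))
    return out


def classify_pcls(
    assignments: dict[str, set[str]], panel_size: int | None = None
) -> pd.DataFrame:
    """Common/rare classification of Pcl labels across a species panel.

    ``assignments`` maps species -> set of Pcl labels.  A label is common
    when its prevalence is >= 20% of the panel (inclusive boundary).  The
    returned table is sorted by decreasing prevalence, then label.
    """
    n = panel_size if panel_size is not None else len(assignments)
    if n < 1:
        raise ValueError("classify_pcls: panel_size must be >= 1")
    species_by_label: dict[str, set[str]] = {}
    for species, labels in assignments.items():
        for label in labels:
            species_by_label.setdefault(label, set()).add(species)
    rows = []
    for label, spp in species_by_label.items():
        prevalence = len(spp) / n
        rows.append(
            {
                "pcl": label,
                "n_species": len(spp),
                "prevalence": prevalence,
                "status": "common" if prevalence >= COMMON_PREVALENCE else "rare",
                "species": ",".join(sorted(spp)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["pcl", "n_species", "prevalence", "status", "species"])
    return df.sort_values(["prevalence", "pcl"], ascending=[False, True]).reset_index(drop=True)


def pcl_matrix(assignments: dict[str, set[str]]) -> pd.DataFrame:
    """Presence/absence matrix (species x Pcl label), for reporting."""
    labels = sorted({l for s in assignments.values() for l in s}, key=lambda x: int(x[1:]))
    rows = {
        sp: {l: int(l in labs) for l in labels} for sp, labs in sorted(assignments.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index")
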