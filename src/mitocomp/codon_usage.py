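"""Codon counting, RSCU, start/stop audit under the mold-mitochondrial code.

Fungal mitochondria translate with genetic code 4, in which TGA encodes
tryptophan instead of stop; the synonymous families used for relative
synonymous codon usage (RSCU) are taken from that table.  For a codon c in a
family of k synonymous codons,

    RSCU(c) = k * n_c / sum(n_c' for c' in family)

so a uniformly used family has RSCU 1 for every member.  Stop codons are
excluded from RSCU (they are audited separately per gene); the start codon is
counted as its literal triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genbank_io import MitogenomeRecord, classify_features, extract_cds

__all__ = [
    "CodonCountTable",
    "RSCUTable",
    "count_codons",
    "rscu",
    "start_stop_audit",
    "rich_codon_usage",
    "codon_families",
    "rscu_matrix",
]

_BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def _table(code_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


def codon_families(code_id: int = 4) -> dict[str, str]:
    """Map codon -> amino acid for the given genetic code (stops excluded)."""
    return dict(_table(code_id).forward_table)


def stop_codons(code_id: int = 4) -> frozenset[str]:
    return frozenset(_table(code_id).stop_codons)


@dataclass
class CodonCountTable:
    counts: dict[str, int]
    gene_set: list[str] = field(default_factory=list)
    code_id: int = 4
    skipped_ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.code_id != other.code_id:
            raise ValueError("cannot add tables with different genetic codes")
        merged = {c: self.counts.get(c, 0) + other.counts.get(c, 0) for c in ALL_CODONS}
        return CodonCountTable(
            counts=merged,
            gene_set=self.gene_set + other.gene_set,
            code_id=self.code_id,
            skipped_ambiguous=self.skipped_ambiguous + other.skipped_ambiguous,
        )


@dataclass
class RSCUTable:
    rscu: dict[str, float | None]
    family: dict[str, str]
    code_id: int = 4


def count_codons(
    cds_list: list[str], code_id: int = 4, gene_names: list[str] | None = None
) -> CodonCountTable:
    """Count frame-0 codons across coding sequences.

    The trailing incomplete codon (if any) is dropped; a terminal stop codon
    is excluded (it is audited by :func:`start_stop_audit`); codons containing
    ambiguity codes are skipped and tallied in ``skipped_ambiguous``.
    """
    stops = stop_codons(code_id)
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for cds in cds_list:
        seq = cds.upper()
        if len(seq) < 3:
            raise ValueError(f"CDS shorter than one codon: {seq!r}")
        bad = set(seq) - set("ACGTRYKMBVDHSWN")
        if bad:
            raise ValueError(f"non-IUPAC characters in CDS: {sorted(bad)}")
        codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        for codon in codons:
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    return CodonCountTable(
        counts=counts,
        gene_set=list(gene_names or []),
        code_id=code_id,
        skipped_ambiguous=skipped,
    )


def rscu(table: CodonCountTable) -> RSCUTable:
    """Relative synonymous codon usage for every sense codon.

    Families with zero total usage get RSCU None for all members.
    """
    fam = codon_families(table.code_id)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fam.items():
        by_aa.setdefault(aa, []).append(codon)
    values: dict[str, float | None] = {}
    for aa, codons in by_aa.items():
        total = sum(table.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = (table.counts.get(c, 0) * k / total) if total else None
    return RSCUTable(rscu=values, family=fam, code_id=table.code_id)


def rich_codon_usage(table: CodonCountTable) -> dict[str, float]:
    """Fraction of codon usage falling on AT-rich vs GC-rich codons.

    A codon is AT-rich when at least 2 of its 3 bases are A or T, GC-rich
    when at least 2 are G or C; over the ACGT alphabet every codon is exactly
    one of the two.
    """
    at_usage = gc_usage = 0
    for codon, n in table.counts.items():
        at = sum(b in "AT" for b in codon)
        if at >= 2:
            at_usage += n
        else:
            gc_usage += n
    total = at_usage + gc_usage
    if total == 0:
        return {"at_rich_frac": 0.0, "gc_rich_frac": 0.0, "total_codons": 0}
    return {
        "at_rich_frac": at_usage / total,
        "gc_rich_frac": gc_usage / total,
        "total_codons": total,
    }


def start_stop_audit(
    records: list[MitogenomeRecord], code_id: int = 4
) -> pd.DataFrame:
    """Start and stop codons of every core PCG across a species panel.

    Returns a long table (genome, gene, start, stop, frame_ok) — genes whose
    spliced CDS length is not a multiple of 3 are flagged, not fatal.
    """
    rows = []
    for rec in records:
        classes = classify_features(rec)
        for i, cls in classes.items():
            if cls != "core_pcg":
                continue
            feat = rec.features[i]
            cds = extract_cds(rec, feat)
            rows.append(
                {
                    "genome": rec.id,
                    "gene": feat.name,
                    "start_codon": cds[:3],
                    "stop_codon": cds[-3:] if len(cds) >= 6 else "",
                    "frame_ok": len(cds) % 3 == 0,
                }
            )
    return pd.DataFrame(rows)


def modal_codons(audit: pd.DataFrame) -> pd.DataFrame:
    """Modal start/stop codon per gene across the panel."""
    if audit.empty:
        return pd.DataFrame(columns=["gene", "modal_start", "modal_stop"])
    rows = []
    for gene, sub in audit.groupby("gene"):
        rows.append(
            {
                "gene": gene,
                "modal_start": sub["start_codon"].mode().iloc[0],
                "modal_stop": sub["stop_codon"].mode().iloc[0],
            }
        )
    return pd.DataFrame(rows)


def genome_codon_table(
    record: MitogenomeRecord, genes: str = "core", code_id: int = 4
) -> CodonCountTable:
    """Codon counts for one genome over a gene class selection.

    ``genes`` is one of core (15 core PCGs), unorf, or all (every CDS-like
    feature: core + un_ORF + HEG).
    """
    classes = classify_features(record)
    wanted = {"core": {"core_pcg"}, "unorf": {"un_orf"}, "all": {"core_pcg", "un_orf", "heg"}}[
        genes
    ]
    cds_list, names = [], []
    for i, cls in classes.items():
        if cls in wanted:
            feat = record.features[i]
            cds = extract_cds(record, feat)
            if len(cds) >= 3:
                cds_list.append(cds)
                names.append(feat.name)
    if not cds_list:
        return CodonCountTable(counts={c: 0 for c in ALL_CODONS}, code_id=code_id)
    return count_codons(cds_list, code_id=code_id, gene_names=names)


def rscu_matrix(
    records: list[MitogenomeRecord], genes: str = "core", code_id: int = 4
) -> pd.DataFrame:
    """Species x 64 RSCU matrix (sense codons; stop columns omitted).

    This export is the input for external embedding/clustering tools.
    """
    rows = {}
    for rec in records:
        table = genome_codon_table(rec, genes=genes, code_id=code_id)
        values = rscu(table).rscu
        rows[rec.id] = {c: (v if v is not None else 0.0) for c, v in values.items()}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
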