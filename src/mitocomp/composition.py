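"""Nucleotide composition, strand skews, and genome partitioning.

Definitions (all computed on the deposited plus strand):

    GC content = (G + C) / (G + C + A + T)
    GC skew    = (G - C) / (G + C)
    AT skew    = (A - T) / (A + T)

Each genome is also partitioned base-by-base into six mutually exclusive
classes — core-PCG exons, RNA genes (rRNA + tRNA), HEGs, un_ORFs, introns,
and intergenic remainder — whose lengths sum exactly to the genome length.
Overlaps are resolved by the fixed priority core exon > RNA > HEG > un_ORF >
intron > intergenic, which generalises the rule that a gene nested inside an
intron is subtracted from the intronic length.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genbank_io import (
    FeatureValidationError,
    MitogenomeRecord,
    classify_features,
)

__all__ = [
    "SkewStats",
    "CompositionBreakdown",
    "nucleotide_stats",
    "partition_genome",
    "component_table",
    "CLASS_NAMES",
]

CLASS_NAMES = ("core_pcg", "rna", "heg", "un_orf", "intron", "intergenic")

# Painting codes ordered so that higher-priority classes overwrite lower ones.
_PAINT_ORDER = ("intron", "un_orf", "heg", "rna", "core_pcg")


@dataclass(frozen=True)
class SkewStats:
    gc_content: float
    at_content: float
    gc_skew: float | None
    at_skew: float | None


@dataclass(frozen=True)
class CompositionBreakdown:
    core_pcg_bp: int
    rna_bp: int
    heg_bp: int
    un_orf_bp: int
    intron_bp: int
    intergenic_bp: int
    genome_bp: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def proportions(self) -> dict[str, float]:
        return {
            name: getattr(self, f"{name}_bp") / self.genome_bp for name in CLASS_NAMES
        }


def nucleotide_stats(seq: str) -> SkewStats:
    """Exact GC/AT content and skews from letter counts.

    Ambiguity codes are excluded from both numerators and denominators.
    A skew is reported as None when its denominator is zero.
    """
    if not seq:
        raise ValueError("nucleotide_stats: empty sequence")
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    acgt = a + c + g + t
    if acgt == 0:
        raise ValueError("nucleotide_stats: no unambiguous ACGT bases")
    gc = g + c
    at = a + t
    return SkewStats(
        gc_content=gc / acgt,
        at_content=at / acgt,
        gc_skew=(g - c) / gc if gc else None,
        at_skew=(a - t) / at if at else None,
    )


def _paint(mask: np.ndarray, segments, code: int, length: int) -> None:
    for s, e in segments:
        if not (1 <= s <= e <= length):
            raise FeatureValidationError(f"segment {s}..{e} outside 1..{length}")
        mask[s - 1 : e] = code


def partition_genome(record: MitogenomeRecord) -> CompositionBreakdown:
    """Partition every base of the genome into the six composition classes.

    Explicit intron features are painted first; for multi-exon genes without
    explicit intron annotations the inter-exon gaps are painted as intronic.
    Genes nested inside introns (typically HEG ORFs) overwrite the intron
    paint, implementing the subtraction rule; core-PCG exons take ultimate
    priority.
    """
    n = record.length
    mask = np.zeros(n, dtype=np.uint8)  # 0 == intergenic
    code = {name: i + 1 for i, name in enumerate(_PAINT_ORDER)}

    classes = classify_features(record)
    segs_by_class: dict[str, list[tuple[int, int]]] = {k: [] for k in _PAINT_ORDER}

    for i, feat in enumerate(record.features):
        if feat.kind == "intron":
            segs_by_class["intron"].extend(feat.segments)
        elif feat.kind == "exon_segment":
            continue
        else:
            cls = classes[i]
            segs_by_class[cls].extend(feat.segments)
            # implicit introns between exon segments of one feature
            if len(feat.segments) > 1:
                ordered = sorted(feat.segments)
                for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                    if s2 > e1 + 1:
                        segs_by_class["intron"].append((e1 + 1, s2 - 1))

    for name in _PAINT_ORDER:
        _paint(mask, segs_by_class[name], code[name], n)

    counts = np.bincount(mask, minlength=len(_PAINT_ORDER) + 1)
    bp = {name: int(counts[code[name]]) for name in _PAINT_ORDER}
    bp["intergenic"] = int(counts[0])
    return CompositionBreakdown(
        core_pcg_bp=bp["core_pcg"],
        rna_bp=bp["rna"],
        heg_bp=bp["heg"],
        un_orf_bp=bp["un_orf"],
        intron_bp=bp["intron"],
        intergenic_bp=bp["intergenic"],
        genome_bp=n,
    )


def component_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """Per-genome class lengths, proportions and skew statistics.

    One row per genome plus a "mean" row.  ``pcg_bp``/``pcg_frac`` columns
    report core PCGs + un_ORFs combined, so both readings of "protein-coding"
    (with or without un_ORFs) are available side by side.
    """
    if not records:
        raise ValueError("component_table: need at least one record")
    rows = []
    for rec in records:
        bd = partition_genome(rec)
        stats = nucleotide_stats(rec.sequence)
        row: dict[str, object] = {"genome": rec.id, "organism": rec.organism}
        row["genome_bp"] = bd.genome_bp
        row.update(bd.as_dict())
        for name, frac in bd.proportions().items():
            row[f"{name}_frac"] = frac
        row["pcg_bp"] = bd.core_pcg_bp + bd.un_orf_bp
        row["pcg_frac"] = row["pcg_bp"] / bd.genome_bp
        row["gc_content"] = stats.gc_content
        row["gc_skew"] = stats.gc_skew
        row["at_skew"] = stats.at_skew
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns=["genome", "organism"]).mean(numeric_only=True)
    mean_row["genome"] = "mean"
    mean_row["organism"] = ""
    df = pd.concat([df, mean_row.to_frame().T], ignore_index=True)
    return df
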