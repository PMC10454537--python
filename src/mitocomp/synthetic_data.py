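"""Synthetic annotated mitogenomes and codon-evolution pairs with manifests.

Every analysis stage in this package is validated against planted truth: the
generator writes a genome whose gene order, intron insertion sites, repeats,
composition-class totals and base composition are all chosen up front and
recorded in a manifest, so downstream modules can be checked exactly.

The defaults emulate a Cyathus-like mitogenome: a circular molecule of
~120 kb at ~28% GC with the 17-marker gene arrangement reported for the
genus, 15 core PCGs under genetic code 4, rns/rnl, 26 tRNAs, cox1/cob
introns hosting LAGLIDADG ORFs, a handful of un_ORFs, and planted
interspersed + tandem repeats.  A five-genome panel mirroring the study
system's divergence structure (A,((B1,B2),(C,D))) is available from
:func:`cyathus5_panel`.

A single integer seed drives one dedicated random stream per genome;
identical specs and seeds give byte-identical GenBank output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codon_usage import ALL_CODONS, stop_codons
from .genbank_io import Feature, MitogenomeRecord, reverse_complement

__all__ = [
    "SimSpec",
    "CodonEvolSpec",
    "IntronPlan",
    "RepeatPlan",
    "simulate_mitogenome",
    "simulate_codon_pair",
    "cyathus5_panel",
    "CYATHUS_GENE_ORDER",
    "GENE_CDS_LENGTHS",
]

#: The 17-marker arrangement shared by four of the five Cyathus genomes.
CYATHUS_GENE_ORDER = (
    "cox1", "nad6", "cox2", "rnl", "nad2", "nad3", "atp6", "rps3", "nad1",
    "cob", "nad4", "rns", "atp8", "cox3", "atp9", "nad4L", "nad5",
)

#: Typical fungal-mitochondrial CDS lengths (nt, excluding the stop codon);
#: rns/rnl entries are full gene lengths.
GENE_CDS_LENGTHS = {
    "atp6": 780, "atp8": 150, "atp9": 225, "cob": 1161, "cox1": 1599,
    "cox2": 750, "cox3": 810, "nad1": 1101, "nad2": 1701, "nad3": 420,
    "nad4": 1482, "nad4L": 270, "nad5": 2001, "nad6": 651, "rps3": 1404,
    "rns": 1500, "rnl": 3200,
}

_TRNA_AA = "ACDEFGHIKLMNPQRSTVWY"
_ANTICODONS = {
    "A": "ugc", "C": "gca", "D": "guc", "E": "uuc", "F": "gaa", "G": "ucc",
    "H": "gug", "I": "gau", "K": "uuu", "L": "uaa", "M": "cau", "N": "guu",
    "P": "ugg", "Q": "uug", "R": "ucu", "S": "uga", "T": "ugu", "V": "uac",
    "W": "uca", "Y": "gua",
}

_PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class IntronPlan:
    host_gene: str
    position: int  # spliced CDS/gene coordinate of the last exon base 5' of the intron
    length: int
    embed_heg: bool = False


@dataclass(frozen=True)
class RepeatPlan:
    kind: str  # "interspersed" | "tandem"
    length: int  # pair length (interspersed) or unit length (tandem)
    copies: int = 2  # tandem copy number
    identity: float = 100.0  # interspersed second-copy identity (percent)


@dataclass
class SimSpec:
    genome_bp: int = 120_000
    gc_target: float = 0.28
    gc_skew_target: float = -0.13
    at_skew_target: float = 0.08
    gene_order: tuple[str, ...] = CYATHUS_GENE_ORDER
    trna_count: int = 26
    n_un_orf: int = 3
    intron_plan: tuple[IntronPlan, ...] = (
        IntronPlan("cox1", 612, 1300, True),
        IntronPlan("cox1", 1305, 1100, False),
        IntronPlan("cob", 450, 1500, True),
        IntronPlan("nad5", 900, 1000, False),
    )
    repeat_plan: tuple[RepeatPlan, ...] = (
        RepeatPlan("interspersed", 300, identity=100.0),
        RepeatPlan("tandem", 12, copies=8),
    )
    codon_bias: dict[str, float] | None = None
    gene_seqs: dict[str, str] | None = None  # pre-evolved CDS/RNA sequences
    species: str = "synthetic"
    organism: str = "Synthetica mitogenomica"
    seed: int = 0
    code_id: int = 4


@dataclass(frozen=True)
class CodonEvolSpec:
    omega: float = 0.2
    kappa: float = 1.0
    branch_len: float = 0.3  # expected proposed substitutions per codon
    n_codons: int = 10_000
    seed: int = 0
    code_id: int = 4


class InfeasibleSpecError(ValueError):
    """Planned features do not fit in the requested genome size."""


# ---------------------------------------------------------------------------
# base- and codon-level sampling


def base_probabilities(gc: float, gc_skew: float, at_skew: float) -> dict[str, float]:
    """Solve per-base probabilities from (GC content, GC skew, AT skew)."""
    if not (0 < gc < 1):
        raise ValueError("gc_target must be in (0,1)")
    return {
        "G": gc * (1 + gc_skew) / 2,
        "C": gc * (1 - gc_skew) / 2,
        "A": (1 - gc) * (1 + at_skew) / 2,
        "T": (1 - gc) * (1 - at_skew) / 2,
    }


def random_seq(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    p = p / p.sum()
    return "".join(rng.choice(bases, size=n, p=p))


def _codon_weights(
    spec_bias: dict[str, float] | None, probs: dict[str, float], code_id: int
) -> tuple[list[str], np.ndarray]:
    stops = stop_codons(code_id)
    codons = [c for c in ALL_CODONS if c not in stops]
    if spec_bias:
        w = np.array([spec_bias.get(c, 0.0) for c in codons], dtype=float)
        if w.sum() <= 0:
            raise ValueError("codon_bias has no weight on sense codons")
    else:
        w = np.array(
            [probs[c[0]] * probs[c[1]] * probs[c[2]] for c in codons], dtype=float
        )
    return codons, w / w.sum()


def random_cds(
    rng: np.random.Generator,
    length_nt: int,
    codons: list[str],
    weights: np.ndarray,
) -> str:
    """Random CDS of ``length_nt`` (multiple of 3, sans stop) + TAA stop."""
    if length_nt % 3:
        raise ValueError("CDS length must be a multiple of 3")
    n = length_nt // 3
    idx = rng.choice(len(codons), size=n, p=weights)
    body = "".join(codons[i] for i in idx)
    return "ATG" + body[3:] + "TAA"


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class _Block:
    seq: str
    features: list[Feature]  # coordinates relative to block start (1-based)
    classes: list[tuple[str, int, int]]  # (class, rel_start, rel_end) for manifest
    label: str = ""


def _mirror(segments, block_len):
    return sorted((block_len - e + 1, block_len - s + 1) for s, e in segments)


def _gene_block(
    name: str,
    strand: str,
    cds: str,
    introns: list[IntronPlan],
    rng: np.random.Generator,
    probs: dict[str, float],
    codons: list[str],
    weights: np.ndarray,
    kind: str,
) -> tuple[_Block, list[int]]:
    """Assemble one gene with its planted introns (and intron-hosted HEGs)."""
    introns = sorted(introns, key=lambda ip: ip.position)
    for ip in introns:
        if not (1 <= ip.position < len(cds)):
            raise InfeasibleSpecError(
                f"{name}: intron position {ip.position} outside 1..{len(cds) - 1}"
            )
    parts: list[str] = []
    exon_segs_rel: list[tuple[int, int]] = []
    intron_feats: list[tuple[int, int, IntronPlan]] = []
    heg_feats: list[tuple[int, int, str]] = []
    classes: list[tuple[str, int, int]] = []
    offset = 0  # block coordinate built so far
    site_positions = []
    exon_bounds = [0] + [ip.position for ip in introns] + [len(cds)]
    for i, (a, b) in enumerate(zip(exon_bounds, exon_bounds[1:])):
        exon = cds[a:b]
        parts.append(exon)
        exon_segs_rel.append((offset + 1, offset + len(exon)))
        offset += len(exon)
        if i >= len(introns):
            break
        ip = introns[i]
        site_positions.append(ip.position)
        intron_seq = list(random_seq(rng, ip.length, probs))
        intron_seq[-1] = "G"  # group I convention: introns close with G
        if ip.embed_heg:
            heg_len = min(720, 3 * ((ip.length - 60) // 3))
            if heg_len >= 150:
                heg_cds = random_cds(rng, heg_len - 3, codons, weights)
                at = 30
                intron_seq[at : at + heg_len] = list(heg_cds)
                heg_feats.append(
                    (offset + at + 1, offset + at + heg_len, f"orf{heg_len // 3}")
                )
        intron_feats.append((offset + 1, offset + ip.length, ip))
        parts.append("".join(intron_seq))
        offset += ip.length
    block_seq = "".join(parts)
    block_len = offset
    assert len(block_seq) == block_len

    features = []
    if strand == "-":
        block_seq = reverse_complement(block_seq)
        exon_rel = _mirror(exon_segs_rel, block_len)
        intron_rel = [
            ((block_len - e + 1, block_len - s + 1), ip) for s, e, ip in intron_feats
        ]
        heg_rel = [((block_len - e + 1, block_len - s + 1), nm) for s, e, nm in heg_feats]
    else:
        exon_rel = exon_segs_rel
        intron_rel = [((s, e), ip) for s, e, ip in intron_feats]
        heg_rel = [((s, e), nm) for s, e, nm in heg_feats]

    product = {"core_pcg": f"{name} protein", "rrna": f"{name} ribosomal RNA"}.get(
        kind, name
    )
    features.append(
        Feature(name=name, kind=kind, strand=strand, segments=list(exon_rel), product=product)
    )
    for (s, e), ip in intron_rel:
        features.append(
            Feature(name=name, kind="intron", strand=strand,
                    segments=[(s, e)], host_gene=name)
        )
        classes.append(("intron", s, e))
    for (s, e), nm in heg_rel:
        features.append(
            Feature(name=nm, kind="heg", strand=strand, segments=[(s, e)],
                    product="LAGLIDADG homing endonuclease", host_gene=name)
        )
        classes.append(("heg", s, e))
    cls = "rna" if kind == "rrna" else "core_pcg"
    for s, e in exon_rel:
        classes.append((cls, s, e))
    return _Block(seq=block_seq, features=features, classes=classes, label=name), site_positions


def _mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute bases until the copy has roughly the target percent identity."""
    n_mut = round(len(seq) * (100.0 - identity) / 100.0)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


def simulate_mitogenome(spec: SimSpec) -> tuple[MitogenomeRecord, dict]:
    """Generate an annotated circular mitogenome and its truth manifest.

    The manifest records, from the generator's own bookkeeping (independent
    of the analysis modules): per-class bp totals, the signed gene order,
    intron insertion sites in spliced coordinates, planted repeat
    coordinates, tRNA count and the realised base composition targets.
    """
    rng = np.random.default_rng(spec.seed)
    probs = base_probabilities(spec.gc_target, spec.gc_skew_target, spec.at_skew_target)
    codons, weights = _codon_weights(spec.codon_bias, probs, spec.code_id)

    introns_by_gene: dict[str, list[IntronPlan]] = {}
    for ip in spec.intron_plan:
        introns_by_gene.setdefault(ip.host_gene, []).append(ip)

    blocks: list[_Block] = []
    intron_sites: dict[str, list[int]] = {}
    gene_order_signed: list[str] = []

    for marker in spec.gene_order:
        strand = "-" if marker.startswith("-") else "+"
        name = marker.lstrip("-")
        gene_order_signed.append(marker)
        if name in {"rns", "rnl"}:
            kind = "rrna"
            seq = (spec.gene_seqs or {}).get(name) or random_seq(
                rng, GENE_CDS_LENGTHS[name], probs
            )
        else:
            kind = "core_pcg"
            seq = (spec.gene_seqs or {}).get(name) or random_cds(
                rng, GENE_CDS_LENGTHS[name], codons, weights
            )
        block, sites = _gene_block(
            name, strand, seq, introns_by_gene.get(name, []), rng, probs,
            codons, weights, kind,
        )
        if sites:
            intron_sites[name] = sites
        blocks.append(block)

    # tRNAs
    for i in range(spec.trna_count):
        aa = _TRNA_AA[i % len(_TRNA_AA)]
        name = f"trn{aa}({_ANTICODONS[aa]})"
        seq = random_seq(rng, 72, probs)
        blocks.append(
            _Block(
                seq=seq,
                features=[Feature(name=name, kind="trna", strand="+",
                                  segments=[(1, 72)], product=f"tRNA-{aa}")],
                classes=[("rna", 1, 72)],
                label=name,
            )
        )

    # un_ORFs
    for i in range(spec.n_un_orf):
        ln = int(3 * rng.integers(100, 200))
        seq = random_cds(rng, ln, codons, weights)
        name = f"orf{(ln + 3) // 3}"
        blocks.append(
            _Block(
                seq=seq,
                features=[Feature(name=name, kind="un_orf", strand="+",
                                  segments=[(1, len(seq))], product="hypothetical protein")],
                classes=[("un_orf", 1, len(seq))],
                label=name,
            )
        )

    # repeats (intergenic-class sequence, coordinates recorded)
    repeat_blocks: list[tuple[str, _Block]] = []
    planted_repeats: list[dict] = []
    for rp in spec.repeat_plan:
        if rp.kind == "interspersed":
            unit = random_seq(rng, rp.length, probs)
            copy = _mutate_to_identity(unit, rp.identity, rng)
            b1 = _Block(seq=unit, features=[], classes=[], label="rep_a")
            b2 = _Block(seq=copy, features=[], classes=[], label="rep_b")
            repeat_blocks.extend([("interspersed_a", b1), ("interspersed_b", b2)])
            planted_repeats.append(
                {"kind": "interspersed", "length": rp.length, "identity": rp.identity}
            )
        elif rp.kind == "tandem":
            unit = random_seq(rng, rp.length, probs)
            b = _Block(seq=unit * rp.copies, features=[], classes=[], label="tandem")
            repeat_blocks.append(("tandem", b))
            planted_repeats.append(
                {"kind": "tandem", "period": rp.length, "copies": rp.copies}
            )
        else:
            raise ValueError(f"unknown repeat kind {rp.kind!r}")

    # interleave auxiliary blocks (tRNA/un_ORF come after markers; repeats
    # appended last so their coordinates are easy to track) then compute gaps
    aux = blocks[len(spec.gene_order):]
    marker_blocks = blocks[: len(spec.gene_order)]
    all_blocks: list[tuple[str, _Block]] = [(b.label, b) for b in marker_blocks]
    for b in aux:
        all_blocks.append((b.label, b))
    all_blocks.extend(repeat_blocks)

    total_feature_bp = sum(len(b.seq) for _, b in all_blocks)
    n_gaps = len(all_blocks)
    spare = spec.genome_bp - total_feature_bp
    if spare < n_gaps:
        raise InfeasibleSpecError(
            f"features need {total_feature_bp} bp + {n_gaps} gap bp "
            f"> genome_bp {spec.genome_bp}"
        )
    # split the intergenic budget across gaps (each gap >= 1 bp)
    props = rng.dirichlet(np.ones(n_gaps))
    gaps = np.maximum(1, np.floor(props * spare).astype(int))
    while gaps.sum() > spare:
        gaps[np.argmax(gaps)] -= 1
    gaps[-1] += spare - gaps.sum()

    # solve the filler base distribution so that GENOME-wide composition hits
    # the targets despite the feature blocks' own base content
    placed = "".join(b.seq for _, b in all_blocks)
    placed_counts = {b: placed.count(b) for b in "ACGT"}
    target_counts = {
        b: spec.genome_bp * p for b, p in probs.items()
    }
    needed = {b: max(0.0, target_counts[b] - placed_counts[b]) for b in "ACGT"}
    total_needed = sum(needed.values())
    if total_needed > 0:
        filler_probs = {b: needed[b] / total_needed for b in "ACGT"}
    else:
        filler_probs = probs

    seq_parts: list[str] = []
    features: list[Feature] = []
    class_intervals: list[tuple[str, int, int]] = []
    repeat_coords: dict[str, tuple[int, int]] = {}
    pos = 0
    for (label, block), gap in zip(all_blocks, gaps):
        start = pos + 1
        seq_parts.append(block.seq)
        for feat in block.features:
            features.append(
                replace(
                    feat,
                    segments=[(s + pos, e + pos) for s, e in feat.segments],
                )
            )
        for cls, s, e in block.classes:
            class_intervals.append((cls, s + pos, e + pos))
        if label in {"interspersed_a", "interspersed_b", "tandem"}:
            key = label
            idx = sum(1 for k in repeat_coords if k.startswith(label))
            repeat_coords[f"{label}_{idx}"] = (start, start + len(block.seq) - 1)
        pos += len(block.seq)
        seq_parts.append(random_seq(rng, int(gap), filler_probs))
        pos += int(gap)
    sequence = "".join(seq_parts)
    assert len(sequence) == spec.genome_bp

    record = MitogenomeRecord(
        id=spec.species,
        organism=spec.organism,
        sequence=sequence,
        topology="circular",
        features=features,
    )
    record.validate()

    totals = {c: 0 for c in ("core_pcg", "rna", "heg", "un_orf", "intron")}
    for cls, s, e in class_intervals:
        totals[cls] += e - s + 1
    # nested HEGs were counted inside their intron spans too; subtract
    totals["intron"] -= sum(
        e - s + 1 for cls, s, e in class_intervals if cls == "heg"
    )
    totals["intergenic"] = spec.genome_bp - sum(totals.values())

    manifest = {
        "species": spec.species,
        "seed": spec.seed,
        "genome_bp": spec.genome_bp,
        "gc_target": spec.gc_target,
        "gc_skew_target": spec.gc_skew_target,
        "at_skew_target": spec.at_skew_target,
        "class_bp": totals,
        "gene_order": gene_order_signed,
        "intron_sites": intron_sites,
        "repeats": planted_repeats,
        "repeat_coords": repeat_coords,
        "trna_count": spec.trna_count,
        "n_un_orf": spec.n_un_orf,
    }
    return record, manifest


# ---------------------------------------------------------------------------
# codon-pair evolution


def _propose(rng: np.random.Generator, base: str, kappa: float) -> str:
    """Propose a substitution: transition weight kappa, transversions 1 each."""
    transition = _PURINE_PARTNER[base]
    others = [b for b in "ACGT" if b != base and b != transition]
    w = np.array([kappa, 1.0, 1.0])
    w = w / w.sum()
    choice = rng.choice(3, p=w)
    return ([transition] + others)[choice]


def simulate_codon_pair(spec: CodonEvolSpec) -> tuple[str, str, dict]:
    """Evolve a random ancestral CDS under an omega-filtered mutation model.

    Substitutions are proposed per site with kappa-weighted transition bias;
    synonymous proposals are always accepted, nonsynonymous ones with
    probability omega (stop-creating changes are rejected outright).  True
    accepted event counts are returned alongside the sequence pair.
    """
    if spec.omega <= 0 or spec.n_codons < 1:
        raise ValueError("omega must be > 0 and n_codons >= 1")
    rng = np.random.default_rng(spec.seed)
    probs = {b: 0.25 for b in "ACGT"}
    codons, weights = _codon_weights(None, probs, spec.code_id)
    idx = rng.choice(len(codons), size=spec.n_codons, p=weights)
    ancestral = "".join(codons[i] for i in idx)
    derived = evolve_cds(ancestral, spec.branch_len, rng, omega=spec.omega,
                         kappa=spec.kappa, code_id=spec.code_id, counts=(cnt := {}))
    return ancestral, derived, cnt


def evolve_cds(
    cds: str,
    branch_len: float,
    rng: np.random.Generator,
    omega: float = 1.0,
    kappa: float = 1.0,
    code_id: int = 4,
    counts: dict | None = None,
) -> str:
    """Apply the omega-filtered substitution process along one branch.

    ``branch_len`` is the expected number of proposed substitutions per
    codon.  Accepted synonymous/nonsynonymous events are tallied into
    ``counts`` when given.
    """
    from .codon_usage import codon_families

    fam = codon_families(code_id)
    stops = stop_codons(code_id)
    seq = list(cds)
    n_codons = len(cds) // 3
    n_events = rng.poisson(branch_len * n_codons)
    accepted_syn = accepted_nonsyn = proposed = 0
    for _ in range(n_events):
        proposed += 1
        site = int(rng.integers(len(cds) // 3 * 3))
        ci = site // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        if codon in stops:
            continue
        new_base = _propose(rng, seq[site], kappa)
        cand = codon[: site % 3] + new_base + codon[site % 3 + 1 :]
        if cand in stops:
            continue
        if fam[cand] == fam[codon]:
            seq[site] = new_base
            accepted_syn += 1
        elif rng.random() < omega:
            seq[site] = new_base
            accepted_nonsyn += 1
    if counts is not None:
        counts.update(
            {"proposed": proposed, "syn": accepted_syn, "nonsyn": accepted_nonsyn}
        )
    return "".join(seq)


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Neutral per-site substitutions at the given expected rate (non-coding)."""
    n = rng.poisson(rate * len(seq))
    out = list(seq)
    for _ in range(n):
        p = int(rng.integers(len(seq)))
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# the five-genome study panel


#: Planted topology of the panel: (A,((B1,B2),(C,D))).
PANEL_NEWICK = "(A,((B1,B2),(C,D)));"

_PANEL_BRANCHES = {
    # per-site expected substitution loads from the root
    "A": [("A", 0.10)],
    "B1": [("rest", 0.03), ("B", 0.025), ("B1", 0.004)],
    "B2": [("rest", 0.03), ("B", 0.025), ("B2", 0.004)],
    "C": [("rest", 0.03), ("CD", 0.02), ("C", 0.012)],
    "D": [("rest", 0.03), ("CD", 0.02), ("D", 0.012)],
}

_PANEL_SIZES = {"A": 116_000, "B1": 128_000, "B2": 120_500, "C": 114_000, "D": 129_000}

#: Species A carries a rearranged order (block moves + one inversion),
#: mirroring the odd genome out in the study system.
_A_ORDER = (
    "cox1", "cox2", "nad6", "rnl", "atp6", "rps3", "nad2", "nad3", "nad1",
    "cob", "nad4", "rns", "-atp8", "cox3", "atp9", "nad4L", "nad5",
)

_PANEL_INTRONS = {
    "A": (
        IntronPlan("cox1", 1305, 1200, True),
        IntronPlan("cox1", 941, 1000, False),
        IntronPlan("cox2", 300, 900, False),
    ),
    "B1": (
        IntronPlan("cox1", 213, 1100, False),
        IntronPlan("cox1", 612, 1300, True),
        IntronPlan("cox1", 1305, 1000, False),
        IntronPlan("cob", 450, 1400, True),
        IntronPlan("nad5", 900, 1000, False),
    ),
    "B2": (
        IntronPlan("cox1", 213, 1050, False),
        IntronPlan("cox1", 612, 1250, True),
        IntronPlan("cox1", 1305, 980, False),
        IntronPlan("cob", 450, 1450, True),
        IntronPlan("nad5", 900, 950, False),
    ),
    "C": (
        IntronPlan("cox1", 612, 1200, True),
        IntronPlan("cox1", 1305, 1000, False),
        IntronPlan("cob", 450, 1350, True),
    ),
    "D": (
        IntronPlan("cox1", 612, 1150, False),
        IntronPlan("cox1", 723, 1000, False),
        IntronPlan("cox1", 1305, 1050, True),
        IntronPlan("cob", 450, 1500, True),
    ),
}

_PANEL_COMPOSITION = {
    # (gc, gc_skew, at_skew): A mirrors the outlier with positive GC skew
    "A": (0.301, 0.010, -0.011),
    "B1": (0.279, -0.147, 0.094),
    "B2": (0.273, -0.135, 0.090),
    "C": (0.283, -0.122, 0.066),
    "D": (0.284, -0.130, 0.080),
}

_PANEL_REPEATS = {
    "A": (RepeatPlan("interspersed", 624, identity=100.0),
          RepeatPlan("interspersed", 502, identity=92.0),
          RepeatPlan("tandem", 14, copies=10)),
    "B1": (RepeatPlan("interspersed", 300, identity=100.0),
           RepeatPlan("tandem", 12, copies=4)),
    "B2": (RepeatPlan("interspersed", 280, identity=96.0),
           RepeatPlan("tandem", 12, copies=4)),
    "C": (RepeatPlan("interspersed", 200, identity=100.0),
          RepeatPlan("tandem", 11, copies=22)),
    "D": (RepeatPlan("interspersed", 150, identity=90.0),
          RepeatPlan("tandem", 15, copies=3)),
}


def cyathus5_panel(
    seed: int = 0, omega: float = 0.2, kappa: float = 1.0
) -> tuple[list[MitogenomeRecord], list[dict], dict]:
    """Five synthetic genomes with the planted topology (A,((B1,B2),(C,D))).

    Shared ancestral genes are evolved along the planted tree under a
    purifying (omega < 1) codon model (rRNAs neutrally), then wrapped in
    per-species genome architectures that mirror the study panel: species A
    is the outlier in size, skew, gene order and repeat load.

    Returns (records, per-genome manifests, panel manifest).  The ancestral
    cox1 CDS in the panel manifest is the Pcl projection reference.
    """
    rng = np.random.default_rng(seed)
    probs = base_probabilities(0.28, -0.13, 0.08)
    codons, weights = _codon_weights(None, probs, 4)

    ancestor: dict[str, str] = {}
    for gene, ln in GENE_CDS_LENGTHS.items():
        if gene in {"rns", "rnl"}:
            ancestor[gene] = random_seq(rng, ln, probs)
        else:
            ancestor[gene] = random_cds(rng, ln, codons, weights)

    # evolve along shared internal branches first so sister species inherit
    # identical internal-node states
    node_states: dict[str, dict[str, str]] = {"root": ancestor}

    def evolve_genes(genes: dict[str, str], length: float, stream: np.random.Generator):
        out = {}
        for gene, seq in genes.items():
            if gene in {"rns", "rnl"}:
                out[gene] = mutate_sequence(seq, length, stream)
            else:
                out[gene] = evolve_cds(seq, 3 * length, stream, omega=omega, kappa=kappa)
        return out

    # internal nodes
    streams = {name: np.random.default_rng(rng.integers(2**31)) for name in
               ["A", "rest", "B", "CD", "B1", "B2", "C", "D"]}
    node_states["rest"] = evolve_genes(ancestor, 0.03, streams["rest"])
    node_states["B"] = evolve_genes(node_states["rest"], 0.025, streams["B"])
    node_states["CD"] = evolve_genes(node_states["rest"], 0.02, streams["CD"])
    tip_states = {
        "A": evolve_genes(ancestor, 0.10, streams["A"]),
        "B1": evolve_genes(node_states["B"], 0.004, streams["B1"]),
        "B2": evolve_genes(node_states["B"], 0.004, streams["B2"]),
        "C": evolve_genes(node_states["CD"], 0.012, streams["C"]),
        "D": evolve_genes(node_states["CD"], 0.012, streams["D"]),
    }

    records, manifests = [], []
    for name in ["A", "B1", "B2", "C", "D"]:
        gc, gcs, ats = _PANEL_COMPOSITION[name]
        spec = SimSpec(
            genome_bp=_PANEL_SIZES[name],
            gc_target=gc,
            gc_skew_target=gcs,
            at_skew_target=ats,
            gene_order=_A_ORDER if name == "A" else CYATHUS_GENE_ORDER,
            intron_plan=_PANEL_INTRONS[name],
            repeat_plan=_PANEL_REPEATS[name],
            gene_seqs=tip_states[name],
            n_un_orf={"A": 8, "B1": 4, "B2": 2, "C": 5, "D": 6}[name],
            trna_count={"A": 24, "B1": 28, "B2": 27, "C": 25, "D": 26}[name],
            species=name,
            organism=f"Cyathus-like sp. {name}",
            seed=int(rng.integers(2**31)),
        )
        rec, manifest = simulate_mitogenome(spec)
        records.append(rec)
        manifests.append(manifest)

    panel = {
        "newick": PANEL_NEWICK,
        "omega": omega,
        "reference_cox1": ancestor["cox1"],
        "species": ["A", "B1", "B2", "C", "D"],
        "intron_sites": {
            name: {
                gene: sorted(
                    ip.position for ip in _PANEL_INTRONS[name] if ip.host_gene == gene
                )
                for gene in {ip.host_gene for ip in _PANEL_INTRONS[name]}
            }
            for name in _PANEL_INTRONS
        },
    }
    return records, manifests, panel
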