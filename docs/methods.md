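# Methods

This note documents the models and conventions implemented in mitocomp, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the choices made where the design was genuinely open.

## Composition and partitioning

GC content is (G+C)/(G+C+A+T); GC skew (G−C)/(G+C); AT skew (A−T)/(A+T).
Ambiguity codes are excluded from both numerator and denominator of every
skew/content statistic but still count toward genome length in
partitioning.  Skews are computed on the deposited plus strand of the full
genome and are undefined (reported null) when a denominator is zero.

Each genome is partitioned base-by-base into six mutually exclusive
classes.  Overlaps are resolved by a fixed priority:

    core-PCG exon > RNA (rRNA/tRNA) > HEG > un_ORF > intron > intergenic

The only overlap rule the source analyses state is that a gene nested
inside an intron is subtracted from the intronic length; the total order
above generalises that rule deterministically to every overlap that can
occur.  Introns are painted both from explicit intron features and from
inter-exon gaps of multi-exon genes, so annotations that omit explicit
intron features still partition correctly.  The painting construction makes
the conservation identity (six class totals = genome length) structural;
tests verify it on 1,000 fuzzed layouts anyway, as a regression guard.

Feature classification: the 15 core PCG names are matched exactly; RNA is
rns/rnl/trn*; HEGs are recognised by case-insensitive product keywords
{LAGLIDADG, GIY-YIG, GIY, homing endonuclease, reverse transcriptase};
everything else defaults to un_ORF with a warning.  Coordinates are 1-based
inclusive (GenBank dialect) internally; BED-style exports are 0-based
half-open.

## Codon usage

All translation uses genetic code 4 (mold mitochondrial; UGA = Trp), whose
synonymous families come from the standard code table.  RSCU(c) = k·n_c /
Σ_family n, k the family size; a family with zero usage reports null rather
than 0, to distinguish "unused" from "absent".  Terminal stop codons are
excluded from counting (standard practice) and audited separately per
gene; start codons are counted as their literal triplet.  A codon is
AT-rich when ≥2 of its three bases are A/T and GC-rich when ≥2 are G/C;
over the ACGT alphabet these classes are exhaustive and disjoint, so the
definition needs no tie-break.

## Molecular evolution

K2P: transition proportion P and transversion proportion Q are computed
over ungapped ACGT columns (pairwise deletion), then
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q).  Arguments of the logarithms at or below
zero raise a saturation error; saturated pairs are excluded from panel
summaries (and counted) rather than imputed.

Ka/Ks follows Nei–Gojobori (1986).  Per-codon synonymous site fractions
are computed per position over the non-stop single-base changes at that
position, which keeps Sa + Ss = 3 × codons exactly.  Codons differing at
d > 1 positions average their substitution counts over all d! minimal
pathways with equal weights; pathways passing through a stop codon are
excluded unless every pathway does (then all are used).  Proportions are
Jukes–Cantor corrected, rate = −¾·ln(1 − 4/3·p).  Gapped or ambiguous
codons are dropped pairwise; premature stops exclude the codon.  Ka/Ks is
null when Ks = 0.  Panel summaries report both the mean of per-pair ratios
and the ratio of mean Ka to mean Ks, since the averaging scheme materially
changes the number and either may be wanted.

Equal-length inputs are treated as already aligned; unequal inputs go
through the built-in global affine-gap aligner (match 1, mismatch −1, gap
open −5, extend −1 — Biopython's PairwiseAligner, first traceback, hence
deterministic).  The built-in aligner is for desk-scale inputs; externally
aligned FASTA is the intended path for real panels.

The NJ tree is standard neighbor joining (scikit-bio) over a symmetric
distance matrix, with negative branch lengths clamped to zero.  It is a
topology sanity check, not a substitute for ML/BI phylogenetics, which are
out of scope.

## Intron position classes

An insertion site is recorded as the spliced-CDS coordinate of the last
exon base 5′ of the intron, read directly from exon-segment annotations
(minus-strand genes use transcription order).  Sites are projected onto a
user-supplied reference cox1 CDS through the global alignment above; the
Pcl label is "P" + the reference coordinate of the aligned base, falling
back to the nearest 5′ aligned reference base (flagged) when the junction
sits in a reference gap.  Labels use reference nucleotide positions, not
alignment columns — chosen because published labels such as P1305 are on
the nucleotide scale; the convention is recorded in output metadata.  A
site is a common insertion site when its panel prevalence is ≥ 0.20
(inclusive), otherwise rare.  The reference CDS is a required input, not
bundled.

## Gene order

The 17 markers (15 core PCGs + rns + rnl) are sorted by start coordinate
around the circle, rotated to put cox1 first, and reverse-complemented
first if cox1 lies on the minus strand — making the extraction invariant
to both the GenBank origin placement and the deposited strand.  tRNAs are
excluded from order comparison.  Comparison is by circular adjacency sets;
the breakpoint distance counts adjacencies of one order missing from the
other.  Unsigned comparison (unordered marker pairs) is the default, with
a signed mode in which an adjacency matches its reverse complement;
rearrangement-scenario inference is out of scope.  Duplicate marker
annotations raise an error rather than being silently resolved, forcing
explicit curation.

## Repeats

Interspersed repeats: exact 15-mer seeds between the genome and itself
(and its reverse complement), chained per diagonal and extended ungapped
with an x-drop rule (match +1, mismatch −2, drop 20); hits are reported at
≥30 bp and ≥80% identity, with the self-diagonal and mirror duplicates
removed and overlapping same-diagonal hits merged.  Fixed length/identity
thresholds replace database-size-dependent e-value cutoffs so the scan is
reproducible; the defaults sit at the identity floor observed in real
congeneric panels.  Tandem repeats: for each period p ≤ 500, maximal runs
with s[i] = s[i+p] are reported when the tract exceeds 10 bp and reaches
two copies, with runs explained by a smaller period that divides p
suppressed.  This is a periodicity scan, not a reimplementation of the TRF
alignment-scoring model, so results are validated against planted truth
rather than against TRF outputs.  Coverage fractions use interval unions
(each base counted once).

## Statistics

Pearson correlations test H0: ρ = 0 via t = r·√((n−2)/(1−r²)) with n−2 df,
two-sided, matching R's cor.test.  Correlations pair genome length with
each of the six component lengths.  The Wilcoxon rank-sum test is exact
(full null enumeration) when n₁+n₂ ≤ 20 with no ties, and otherwise uses
the normal approximation with continuity and tie corrections; p-values are
two-sided.  No multiple-testing adjustment is applied (raw p-values are
reported, as in the analyses this mirrors).

## Synthetic data

The generator emulates the architecture of a Cyathus-like mitogenome:
defaults are a 120 kb circle at GC 0.28, GC skew −0.13, AT skew +0.08
(the composition observed in the real genus), the 17-marker arrangement
cox1–nad6–cox2–rnl–nad2–nad3–atp6–rps3–nad1–cob–nad4–rns–atp8–cox3–atp9–
nad4L–nad5, 26 tRNAs, introns in cox1/cob/nad5 with LAGLIDADG ORFs
embedded, three un_ORFs, and planted interspersed + tandem repeats.  Gene
CDSs are sampled codon-wise (no in-frame stops, ATG start, TAA stop);
intergenic filler is sampled per-base from a distribution solved so the
genome-wide composition hits the targets despite the fixed feature
content.  Infeasible plans (features exceeding the genome size) are
rejected before any output.  A single integer seed drives one dedicated
random stream per genome; identical specs give byte-identical GenBank
files (the LOCUS date is pinned for this reason).

The manifest records class totals, gene order, intron sites, repeat
coordinates and targets from the generator's own bookkeeping, so it is an
oracle independent of the analysis modules.

The five-genome panel mirrors the real study system at its natural scale:
sizes 114–129 kb, topology (A,((B1,B2),(C,D))) with per-site branch loads
chosen so B1/B2 are nearly identical, C/D are close sisters, and A is
~15% diverged; A also carries the outlier composition (positive GC skew),
a rearranged gene order and the heaviest repeat load.  Genes evolve under
an ω-filtered substitution process (proposals with optional transition
bias; synonymous changes always accepted, nonsynonymous accepted with
probability ω, stop-creating changes rejected) at ω = 0.2; rRNAs evolve
neutrally.  The codon-pair simulator defaults to kappa = 1 because NG86
counting assumes no transition bias; kappa is exposed for sensitivity
analyses.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indel evolution inside coding sequences (indels
appear only in the Pcl test fixtures), intron sequence homology across
species, tRNA cloverleaf structure, base-composition heterogeneity along
the genome, and recombination.  Planted-truth recovery therefore validates
the algorithms, not annotation quality on real records; the deposited-
record spot checks exist for that and require the published files locally.

## Problem sizes

The test suite and the acceptance script run the panel at its natural
114–129 kb sizes (generation and analysis take seconds); estimator
recovery uses 10,000 codons per ω; calibration uses 10,000 null
replicates; conservation fuzzing uses 1,000 random layouts at 2–6 kb,
where layout diversity, not length, is what exercises the partition logic.

## Known limitations

* NG86 is the classic counting method; it underestimates Ka/Ks mildly at
  high divergence and ignores transition bias in site counting.  The
  recovery tests bound the bias at ±0.1 under the simulator's conditions.
* The tandem scan reports maximal periodic runs, which can fragment
  imperfect arrays with indels; copy numbers are exact only for
  substitution-free arrays.
* Pcl projection depends on the alignment; junctions inside long reference
  gap runs are resolved 5′-ward and flagged rather than dropped.
* The composition partition trusts the annotation; dubious ORFs
  overlapping core genes are preserved as annotated and resolved only by
  the partition priority.
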