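"""Intron site extraction, reference projection, common/rare classification."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomp.genbank_io import Feature, MitogenomeRecord
from mitocomp.intron_pcl import (
    classify_pcls,
    extract_intron_sites,
    map_to_reference,
    IntronSite,
    pcl_matrix,
)


def gene_record(exon_lengths, strand="+", gene="cox1", intron_len=50):
    """Record with one gene whose exons have the given spliced lengths."""
    segments = []
    pos = 1
    for i, ln in enumerate(exon_lengths):
        segments.append((pos, pos + ln - 1))
        pos += ln + (intron_len if i < len(exon_lengths) - 1 else 0)
    seq_len = pos + 10
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=seq_len))
    return MitogenomeRecord(
        id="sp1", organism="x", sequence=seq,
        features=[Feature(gene, "core_pcg", strand, segments)],
    )


class TestExtractSites:
    def test_two_exon_junction(self):
        rec = gene_record([100, 200])
        (site,) = extract_intron_sites(rec, "cox1")
        assert site.query_pos == 100

    def test_intronless_gene_gives_empty_list(self):
        rec = gene_record([300])
        assert extract_intron_sites(rec, "cox1") == []

    def test_three_exon_cumulative_sums(self):
        rec = gene_record([50, 60, 70])
        sites = extract_intron_sites(rec, "cox1")
        assert [s.query_pos for s in sites] == [50, 110]

    def test_minus_strand_uses_transcription_order(self):
        # exons of genomic lengths [50, 60, 70]; on the minus strand the
        # transcript reads the rightmost segment first
        rec = gene_record([50, 60, 70], strand="-")
        sites = extract_intron_sites(rec, "cox1")
        assert [s.query_pos for s in sites] == [70, 130]

    def test_unannotated_gene_raises(self):
        rec = gene_record([100])
        with pytest.raises(ValueError):
            extract_intron_sites(rec, "cob")


def _sites(*positions):
    return [IntronSite("sp", "cox1", p) for p in positions]


class TestProjection:
    def test_identity_projection(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), size=1500))
        out = map_to_reference(ref, ref, _sites(1305))
        (_, label, flagged) = out[0]
        assert label == "P1305" and not flagged

    def test_identity_projection_all_positions(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        for pos in (1, 37, 200, 399):
            (_, label, _) = map_to_reference(ref, ref, _sites(pos))[0]
            assert label == f"P{pos}"

    def test_deletion_shifts_projection_by_offset(self):
        # query lacks 3 reference bases upstream of the site: the junction at
        # query_pos q maps to reference position q + 3
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=900))
        query = ref[:300] + ref[303:]  # 3-base deletion at ref 301..303
        q_pos = 612 - 3
        (_, label, flagged) = map_to_reference(query, ref, _sites(q_pos))[0]
        assert label == "P612" and not flagged

    def test_insertion_in_query_flags_gap_junction(self):
        rng = np.random.default_rng(4)
        ref = "".join(rng.choice(list("ACGT"), size=600))
        ins = "ACGTACGTAC"
        query = ref[:400] + ins + ref[400:]
        # a junction inside the inserted run has no reference base: nearest
        # 5' aligned reference base is 400
        (_, label, flagged) = map_to_reference(query, ref, _sites(405))[0]
        assert flagged and label == "P400"

    def test_position_zero_rejected(self):
        with pytest.raises(ValueError):
            map_to_reference("ACGTACGT", "ACGTACGT", _sites(0))


class TestPlantedRecovery:
    def test_recovery_under_mutation_and_indels(self):
        """>= 95% of planted labels recovered from mutated queries."""
        rng = np.random.default_rng(10)
        ref = "".join(rng.choice(list("ACGT"), size=1602))
        planted = [213, 612, 723, 941, 1305]
        recovered = total = 0
        for trial in range(20):
            # mutate ~8% of sites, plus one 3-bp deletion and one 3-bp
            # insertion placed away from the planted junctions
            q = list(ref)
            n_mut = int(0.08 * len(q))
            for p in rng.choice(len(q), size=n_mut, replace=False):
                q[p] = "ACGT"[int(rng.integers(4))]
            del_at = 450
            ins_at = 1100
            query = "".join(q[:del_at]) + "".join(q[del_at + 3 :])
            query = query[:ins_at] + "TGCA"[: 3] + query[ins_at:]
            # planted sites in query coordinates
            def to_query(rp):
                qp = rp
                if rp > del_at + 3:
                    qp -= 3
                if qp > ins_at:
                    qp += 3
                return qp

            sites = _sites(*[to_query(rp) for rp in planted])
            out = map_to_reference(query, ref, sites)
            for (site, label, _), rp in zip(out, planted):
                total += 1
                if label == f"P{rp}":
                    recovered += 1
        assert recovered / total >= 0.95


class TestClassify:
    def test_inclusive_twenty_percent_boundary(self):
        assignments = {f"s{i}": set() for i in range(10)}
        assignments["s0"].add("P100")
        assignments["s1"].add("P100")
        table = classify_pcls(assignments, panel_size=10)
        assert table.iloc[0]["status"] == "common"  # 2/10 = 0.20 inclusive

    def test_seven_of_thirtyfour_is_common(self):
        assignments = {f"s{i}": {"P612"} for i in range(7)}
        table = classify_pcls(assignments, panel_size=34)
        row = table.iloc[0]
        assert row["prevalence"] == pytest.approx(7 / 34)
        assert row["status"] == "common"

    def test_singleton_is_rare(self):
        table = classify_pcls({"s0": {"P262"}}, panel_size=34)
        assert table.iloc[0]["status"] == "rare"

    def test_permutation_invariance_and_count_conservation(self):
        rng = np.random.default_rng(6)
        labels = [f"P{p}" for p in (10, 20, 30, 40)]
        assignments = {
            f"s{i}": {l for l in labels if rng.random() < 0.5} for i in range(12)
        }
        t1 = classify_pcls(assignments, panel_size=12)
        shuffled = dict(reversed(list(assignments.items())))
        t2 = classify_pcls(shuffled, panel_size=12)
        assert t1.drop(columns="species").equals(t2.drop(columns="species"))
        assert t1["n_species"].sum() == sum(len(v) for v in assignments.values())

    def test_invalid_panel_size(self):
        with pytest.raises(ValueError):
            classify_pcls({}, panel_size=0)


def test_pcl_matrix_shape(panel):
    from mitocomp.genbank_io import extract_cds, get_gene
    from mitocomp.intron_pcl import extract_intron_sites

    records, _, pm = panel
    ref = pm["reference_cox1"]
    assignments = {}
    for rec in records:
        sites = extract_intron_sites(rec, "cox1")
        cds = extract_cds(rec, get_gene(rec, "cox1"))
        assignments[rec.id] = {l for _, l, _ in map_to_reference(cds, ref, sites)}
    mat = pcl_matrix(assignments)
    assert set(mat.index) == {"A", "B1", "B2", "C", "D"}
    assert mat.loc["B1", "P1305"] == 1 and mat.loc["A", "P612"] == 0
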