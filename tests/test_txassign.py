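import numpy as np
import pandas as pd
import pytest

from clipsite.model import (
    BindingSite,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptAnnotation,
)
from clipsite.txassign import (
    assign_gene,
    assign_region,
    assign_sites,
    canonical_transcript,
    filter_genes_by_level,
    sites_per_region_normalized,
    strongest_site_grouping,
)

from conftest import make_track


def simple_gene(gid="g1", start=0, end=500, strand="+", level="1",
                biotype="protein_coding"):
    return Gene(id=gid, chrom="chr1", start=start, end=end, strand=strand,
                level=level, biotype=biotype)


def tx_with(gene, tid="t1", level="1", exons=None, cds=None, utr5=None, utr3=None):
    tx = Transcript(id=tid, gene_id=gene.id, chrom=gene.chrom, strand=gene.strand,
                    level=level, exons=exons or [], cds=cds or [],
                    utr5=utr5 or [], utr3=utr3 or [])
    gene.transcripts[tid] = tx
    return tx


def site_at(center, strand="+", count=10, sid="s1"):
    return BindingSite(
        id=sid,
        interval=GenomicInterval("chr1", center - 2, center + 3, strand),
        center=center,
        total_count=count,
        per_replicate_counts=(count, 0, 0, 0),
        center_score=1.0,
    )


class TestLevelFilter:
    def test_level3_inside_level1_excluded(self):
        g1 = simple_gene("g1", 0, 1000, level="1")
        tx_with(g1, exons=[(0, 1000)])
        g3 = simple_gene("g3", 200, 400, level="3")
        tx_with(g3, "t3", exons=[(200, 400)])
        ann = TranscriptAnnotation(genes={"g1": g1, "g3": g3})
        assert set(filter_genes_by_level(ann).genes) == {"g1"}

    def test_level3_without_overlap_included(self):
        g3 = simple_gene("g3", 200, 400, level="3")
        tx_with(g3, "t3", exons=[(200, 400)])
        ann = TranscriptAnnotation(genes={"g3": g3})
        assert set(filter_genes_by_level(ann).genes) == {"g3"}

    def test_na_transcript_dropped_when_leveled_exists(self):
        g = simple_gene()
        tx_with(g, "tA", level="NA", exons=[(0, 500)])
        tx_with(g, "tB", level="2", exons=[(0, 500)])
        kept = filter_genes_by_level(TranscriptAnnotation(genes={"g1": g}))
        assert set(kept.genes["g1"].transcripts) == {"tB"}

    def test_na_transcript_kept_when_alone(self):
        g = simple_gene()
        tx_with(g, "tA", level="NA", exons=[(0, 500)])
        kept = filter_genes_by_level(TranscriptAnnotation(genes={"g1": g}))
        assert set(kept.genes["g1"].transcripts) == {"tA"}


class TestAssignGene:
    def test_unique_overlap_deterministic(self):
        g = simple_gene()
        assert assign_gene(site_at(100), [g], np.random.default_rng(0)) == "g1"

    def test_no_overlap_returns_none(self):
        g = simple_gene(start=1000, end=2000)
        assert assign_gene(site_at(100), [g], np.random.default_rng(0)) is None

    def test_two_gene_choice_reproducible(self):
        genes = [simple_gene("gA", 0, 500), simple_gene("gB", 50, 600)]
        picks = {assign_gene(site_at(100), genes, np.random.default_rng(3))
                 for _ in range(5)}
        assert len(picks) == 1

    def test_two_gene_choice_uniform(self):
        genes = [simple_gene("gA", 0, 500), simple_gene("gB", 50, 600)]
        rng = np.random.default_rng(12)
        picks = [assign_gene(site_at(100), genes, rng) for _ in range(10**4)]
        frac = picks.count("gA") / len(picks)
        assert abs(frac - 0.5) < 0.02


class TestAssignRegion:
    def test_hierarchy_prefers_3utr_over_cds(self):
        g = simple_gene()
        tx_with(g, "tA", exons=[(0, 500)], cds=[(50, 350)], utr5=[(0, 50)],
                utr3=[(350, 500)])
        tx_with(g, "tB", exons=[(0, 500)], cds=[(50, 450)], utr5=[(0, 50)],
                utr3=[(450, 500)])
        # position 400: 3'UTR in tA, CDS in tB
        assert assign_region(site_at(400), g) == "3UTR"

    def test_intronic_site(self):
        g = simple_gene()
        tx_with(g, exons=[(0, 100), (300, 500)], cds=[(50, 100), (300, 400)],
                utr5=[(0, 50)], utr3=[(400, 500)])
        assert assign_region(site_at(200), g) == "intron"

    def test_lncrna_exon_is_noncoding(self):
        g = simple_gene(biotype="lncRNA")
        tx_with(g, exons=[(0, 500)])
        assert assign_region(site_at(100), g) == "noncoding"


class TestStrongestGrouping:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["site_id", "transcript_id", "region", "strength",
                     "total_count", "center", "strand"],
        )

    def test_argmax_strength_wins(self):
        table = self._table([
            ("s1", "t1", "CDS", 0.4, 10, 100, "+"),
            ("s2", "t1", "3UTR", 0.1, 3, 400, "+"),
        ])
        assert strongest_site_grouping(table) == {"t1": "CDS"}

    def test_single_site_defines_group(self):
        table = self._table([("s1", "t1", "5UTR", 0.2, 5, 20, "+")])
        assert strongest_site_grouping(table) == {"t1": "5UTR"}

    def test_tie_breaks_to_five_prime_site(self):
        table = self._table([
            ("s1", "t1", "CDS", 0.3, 9, 300, "+"),
            ("s2", "t1", "3UTR", 0.3, 9, 100, "+"),
        ])
        assert strongest_site_grouping(table) == {"t1": "3UTR"}
        minus = self._table([
            ("s1", "t1", "CDS", 0.3, 9, 300, "-"),
            ("s2", "t1", "3UTR", 0.3, 9, 100, "-"),
        ])
        assert strongest_site_grouping(minus) == {"t1": "CDS"}


class TestRegionDensity:
    def _ann_two_genes(self):
        g1 = simple_gene("g1", 0, 500)
        tx_with(g1, "t1", exons=[(0, 500)], cds=[(50, 350)], utr5=[(0, 50)],
                utr3=[(350, 450)])
        g2 = simple_gene("g2", 1000, 1800)
        tx_with(g2, "t2", exons=[(1000, 1800)], cds=[(1100, 1400)],
                utr5=[(1000, 1100)], utr3=[(1400, 1700)])
        return TranscriptAnnotation(genes={"g1": g1, "g2": g2})

    def test_density_formula(self):
        ann = self._ann_two_genes()
        tracks = [make_track({100: 1, 1200: 1})]
        table = pd.DataFrame({"region": ["3UTR", "3UTR"]})
        out = sites_per_region_normalized(table, ann, tracks).set_index("region")
        # mean 3'UTR lengths 100 and 300 -> density 2/400
        assert out.loc["3UTR", "density"] == pytest.approx(2 / 400)

    def test_zero_sites_zero_density(self):
        ann = self._ann_two_genes()
        tracks = [make_track({100: 1, 1200: 1})]
        out = sites_per_region_normalized(
            pd.DataFrame({"region": []}), ann, tracks
        ).set_index("region")
        assert out.loc["5UTR", "density"] == 0.0

    def test_uncrosslinked_genes_excluded_from_length_sum(self):
        ann = self._ann_two_genes()
        tracks = [make_track({100: 1})]  # only g1 crosslinked
        table = pd.DataFrame({"region": ["3UTR"]})
        out = sites_per_region_normalized(table, ann, tracks).set_index("region")
        assert out.loc["3UTR", "density"] == pytest.approx(1 / 100)


class TestTranscriptCoords:
    def test_plus_strand_cumulative_exon_arithmetic(self):
        g = simple_gene(end=600)
        tx = tx_with(g, exons=[(100, 200), (300, 400)])
        assert tx.genomic_to_tx(310) == 110
        assert tx.tx_to_genomic(110) == 310

    def test_minus_strand_orientation(self):
        g = simple_gene(strand="-", end=600)
        tx = tx_with(g, exons=[(100, 200), (300, 400)])
        # 5' end of a minus-strand transcript is the highest genomic position
        assert tx.genomic_to_tx(399) == 0
        assert tx.genomic_to_tx(100) == 199

    def test_round_trip_identity(self):
        g = simple_gene(strand="-", end=600)
        tx = tx_with(g, exons=[(100, 250), (300, 400), (450, 500)])
        for tpos in range(tx.spliced_length):
            assert tx.genomic_to_tx(tx.tx_to_genomic(tpos)) == tpos

    def test_junction_spanning_site_dropped(self):
        g = simple_gene(end=600)
        tx_with(g, exons=[(100, 200), (300, 400)], cds=[(100, 200), (300, 400)])
        ann = TranscriptAnnotation(genes={"g1": g})
        tracks = [make_track({150: 5, 198: 5}, label=f"r{i}") for i in range(4)]
        inside = site_at(150, sid="in")
        straddle = site_at(198, sid="x")  # spans genomic 196..201
        result = assign_sites([inside, straddle], ann, tracks, seed=0)
        got = result.table.set_index("site_id")["tx_pos"]
        assert got["in"] == 50
        assert got["x"] == -1
        assert result.n_junction_dropped == 1


class TestAssignmentProperties:
    def test_every_assigned_site_has_one_region(self, small_run):
        from clipsite.sitecall import call_binding_sites

        sites, _ = call_binding_sites(small_run["tracks"])
        result = assign_sites(sites, small_run["ann"], small_run["tracks"], seed=1)
        assert len(result.table) + result.n_unassigned == len(sites)
        assert result.table["region"].isin(
            ["3UTR", "5UTR", "CDS", "intron", "noncoding"]
        ).all()
        counts = result.table["region"].value_counts().sum()
        assert counts == len(result.table)

    def test_region_labels_match_planted_truth(self, small_run):
        from clipsite.sitecall import call_binding_sites

        sites, _ = call_binding_sites(small_run["tracks"])
        result = assign_sites(sites, small_run["ann"], small_run["tracks"], seed=1)
        truth = small_run["truth"].planted_sites
        merged = result.table.merge(
            truth, left_on=["chrom", "strand", "center"],
            right_on=["chrom", "strand", "center"],
        )
        match = (merged["region_x"] == merged["region_y"]).mean()
        assert match >= 0.9

    def test_adding_3utr_transcript_only_promotes(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            cds_end = int(rng.integers(200, 400))
            g = simple_gene(end=600)
            tx_with(g, "tA", exons=[(0, 500)], cds=[(50, cds_end)], utr5=[(0, 50)],
                    utr3=[(cds_end, 500)])
            center = int(rng.integers(55, 495))
            before = assign_region(site_at(center), g)
            tx_with(g, "tB", exons=[(0, 500)], cds=[(50, 150)], utr5=[(0, 50)],
                    utr3=[(150, 500)])
            after = assign_region(site_at(center), g)
            if before == "3UTR":
                assert after == "3UTR"
            assert after in ("3UTR", before)

    def test_canonical_transcript_is_longest(self):
        g = simple_gene()
        tx_with(g, "tShort", exons=[(0, 200)])
        tx_with(g, "tLong", exons=[(0, 450)])
        assert canonical_transcript(g).id == "tLong"
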