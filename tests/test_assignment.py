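"""Feature-to-bin assignment and 1/n ambiguity weighting."""

import numpy as np
import pytest

from _oracles import oracle_assign
from conftest import mirror_transcript, random_transcript, single_annotation
from metaguitar.annotation import (
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
)
from metaguitar.assignment import (
    Feature,
    assign,
    bin_weight_vector,
    overlapping_transcripts,
    read_bed,
)
from metaguitar.coordinates import build_guitar_coordinates


def guitar(ann, B=100, **kw):
    return build_guitar_coordinates(ann, B=B, **kw)


class TestOverlappingTranscripts:
    def test_feature_in_single_cds(self, equal_component_mrna):
        ann = single_annotation(equal_component_mrna)
        f = Feature("f", GenomicInterval("chr1", 1400, 1410, "+"))
        assert overlapping_transcripts(f, ann) == {"eq"}

    def test_purely_intronic_feature_matches_nothing(self, two_exon_plus):
        ann = single_annotation(two_exon_plus)
        f = Feature("f", GenomicInterval("chr1", 220, 280, "+"))
        assert overlapping_transcripts(f, ann) == set()

    def test_two_isoforms_give_n_two(self):
        txs = [
            Transcript(f"t{i}", "g",
                       (GenomicInterval("chr1", 0, 1000, "+"),))
            for i in range(2)
        ]
        f = Feature("f", GenomicInterval("chr1", 10, 20, "+"))
        assert len(overlapping_transcripts(f, TranscriptomeAnnotation(txs))) == 2


class TestWeightLaw:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_weight_is_one_over_n(self, n):
        """A feature spanning n disjoint transcripts is split 1/n ways."""
        txs = [
            Transcript(
                f"t{i}", f"g{i}",
                (GenomicInterval("chr1", 1000 * i, 1000 * i + 400, "+"),),
            )
            for i in range(n)
        ]
        ann = TranscriptomeAnnotation(txs)
        f = Feature("f", GenomicInterval("chr1", 0, 1000 * (n - 1) + 400, "+"))
        recs = assign([f], guitar(ann, B=10), ann)
        assert recs and all(r.weight == pytest.approx(1.0 / n) for r in recs)
        assert {r.tx_id for r in recs} == {t.tx_id for t in txs}

    def test_unassociated_feature_yields_no_records(self, two_exon_plus):
        ann = single_annotation(two_exon_plus)
        f = Feature("f", GenomicInterval("chr5", 0, 100, "+"))
        assert assign([f], guitar(ann, B=10), ann) == []


class TestJunctionSplit:
    def test_feature_split_70_30_across_utr5_cds(self, equal_component_mrna):
        """A 300-nt feature lying 70% on the 5'UTR and 30% on the CDS of an
        equal-component mRNA hits 70% 5'UTR bins and 30% CDS bins."""
        ann = single_annotation(equal_component_mrna)
        # mature [90, 390): 210 nt of 5'UTR, 90 nt of CDS
        f = Feature("f", GenomicInterval("chr1", 1090, 1390, "+"))
        recs = assign([f], guitar(ann, B=100), ann)
        by_comp = {}
        for r in recs:
            by_comp[r.component] = by_comp.get(r.component, 0.0) + r.weight
        total = sum(by_comp.values())
        assert by_comp["utr5"] / total == pytest.approx(0.70)
        assert by_comp["cds"] / total == pytest.approx(0.30)
        assert set(by_comp) == {"utr5", "cds"}

    def test_single_nt_site_on_bin_boundary_hits_one_bin(self, equal_component_mrna):
        ann = single_annotation(equal_component_mrna)
        # mature 303 = first nt of cds bin 1 (bins are 3 nt; half-open)
        f = Feature("f", GenomicInterval("chr1", 1303, 1304, "+"))
        recs = assign([f], guitar(ann, B=100), ann)
        assert [(r.component, r.bin_index) for r in recs] == [("cds", 1)]


class TestOracleEquivalence:
    def random_instance(self, rng, B):
        n_tx = int(rng.integers(1, 6))
        txs = [
            random_transcript(rng, tx_id=f"t{i}", min_component=B + 2)
            for i in range(n_tx)
        ]
        feats = []
        for j in range(int(rng.integers(1, 51))):
            s = int(rng.integers(0, 9800))
            w = int(rng.integers(1, 201))
            strand = ["+", "-", "."][int(rng.integers(3))]
            feats.append(
                Feature(f"f{j}", GenomicInterval("chr1", s, s + w, strand))
            )
        return txs, feats

    @pytest.mark.parametrize("seed", range(25))
    def test_assign_matches_per_nucleotide_oracle(self, seed):
        rng = np.random.default_rng(seed)
        B = int(rng.integers(3, 12))
        txs, feats = self.random_instance(rng, B)
        ann = TranscriptomeAnnotation(txs)
        recs = assign(feats, guitar(ann, B=B), ann)
        got = {(r.feature_id, r.tx_id, r.component, r.bin_index,
                round(r.weight, 12)) for r in recs}
        want = {(f, t, c, i, round(w, 12))
                for f, t, c, i, w in oracle_assign(feats, txs, B)}
        assert got == want


class TestWeightVectors:
    def test_contiguous_cds_hit(self, equal_component_mrna):
        ann = single_annotation(equal_component_mrna)
        gs = guitar(ann, B=100)
        # cds mature [300,600); bins 40-49 cover mature [420,450) -> genomic
        f = Feature("f", GenomicInterval("chr1", 1420, 1450, "+"))
        vec = bin_weight_vector(assign([f], gs, ann), gs)[("mRNA", None)]
        hit = vec[vec > 0]
        assert list(hit.index) == [("cds", i) for i in range(40, 50)]
        assert (hit == 1.0).all()

    def test_additivity_of_feature_sets(self, equal_component_mrna):
        ann = single_annotation(equal_component_mrna)
        gs = guitar(ann, B=100)
        f1 = Feature("a", GenomicInterval("chr1", 1420, 1450, "+"))
        f2 = Feature("b", GenomicInterval("chr1", 1050, 1080, "+"))
        v12 = bin_weight_vector(assign([f1, f2], gs, ann), gs)[("mRNA", None)]
        v1 = bin_weight_vector(assign([f1], gs, ann), gs)[("mRNA", None)]
        v2 = bin_weight_vector(assign([f2], gs, ann), gs)[("mRNA", None)]
        assert np.allclose(v12.to_numpy(), (v1 + v2).to_numpy())

    def test_total_weight_sums_bins_over_n(self):
        """Total summed weight = sum_i k_i / n over the transcripts hit."""
        rng = np.random.default_rng(11)
        txs = [random_transcript(rng, tx_id=f"t{i}", min_component=12)
               for i in range(3)]
        ann = TranscriptomeAnnotation(txs)
        gs = guitar(ann, B=10)
        f = Feature("f", GenomicInterval("chr1", 0, 5000, "."))
        recs = assign([f], gs, ann)
        if recs:
            n = len({r.tx_id for r in recs})
            k = {t: sum(1 for r in recs if r.tx_id == t)
                 for t in {r.tx_id for r in recs}}
            assert sum(r.weight for r in recs) == pytest.approx(
                sum(k.values()) / n
            )

    def test_strand_mirror_invariance_of_weight_vector(self):
        rng = np.random.default_rng(5)
        tx = random_transcript(rng, tx_id="t", min_component=12, coding=True)
        M = 10**6
        mir = mirror_transcript(tx, M)
        s = int(rng.integers(tx.exons[0].start, tx.exons[-1].end - 20))
        f = Feature("f", GenomicInterval("chr1", s, s + 20, tx.strand))
        fm = Feature("f", GenomicInterval("chr1", M - (s + 20), M - s,
                                          mir.strand))
        ann, annm = single_annotation(tx), single_annotation(mir)
        gs, gsm = guitar(ann, B=10), guitar(annm, B=10)
        v = bin_weight_vector(assign([f], gs, ann), gs)
        vm = bin_weight_vector(assign([fm], gsm, annm), gsm)
        key = list(v)[0]
        assert np.allclose(v[key].to_numpy(), vm[key].to_numpy())


def test_read_bed_strand_and_defaults(tmp_path):
    p = tmp_path / "f.bed"
    p.write_text(
        "chr1\t10\t20\tsiteA\t0\t-\n"
        "chr1\t30\t40\n"
    )
    feats = read_bed(str(p), group="g1")
    assert feats[0].id == "siteA" and feats[0].interval.strand == "-"
    assert feats[1].interval.strand == "."
    assert all(f.group == "g1" for f in feats)
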