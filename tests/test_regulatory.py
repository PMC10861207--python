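"""DEG filtering, IUPAC expansion, motif scanning, promoter extraction."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from nemaspan import (
    SKN1_MOTIFS,
    DegRecord,
    IupacMotif,
    PromoterSeq,
    annotate_degs_with_sites,
    expand_iupac,
    extract_promoters,
    filter_degs,
    scan_motifs,
)


def brute_force_hits(seq: str, motifs=SKN1_MOTIFS, both_strands=True):
    """Window-by-window membership in the concrete expansion; the oracle
    deliberately shares no code with the regex scanner."""
    found = []
    for motif in motifs:
        k = len(motif.pattern)
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if window in motif.expansion:
                found.append((i, "+", motif.pattern))
            if both_strands:
                rc = str(Seq(window).reverse_complement())
                if rc in motif.expansion:
                    found.append((i, "-", motif.pattern))
    return sorted(found)


def random_seq(rng, n=1500, gc=0.36):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestFilterDegs:
    def test_boundary_row_kept(self):
        up, down, rejects = filter_degs([DegRecord("g", 1.0, 0.05)])
        assert [d.gene_id for d in up] == ["g"] and not down and not rejects

    def test_below_fold_threshold_dropped(self):
        up, down, _ = filter_degs([DegRecord("g", 0.99, 0.001)])
        assert not up and not down

    def test_toy_table_brute_force(self):
        rows = [DegRecord(f"g{i}", lfc, fdr) for i, (lfc, fdr) in enumerate([
            (1.5, 0.01), (-2.0, 0.04), (0.5, 0.001), (3.0, 0.2),
            (1.0, 0.05), (-0.9, 0.01), (2.2, 0.06), (-1.1, 0.05),
            (0.0, 0.0), (4.0, 0.049),
        ])]
        expect = {r.gene_id for r in rows
                  if abs(r.log2fc) >= 1 and r.fdr <= 0.05}
        up, down, _ = filter_degs(rows)
        assert {d.gene_id for d in up + down} == expect

    def test_bad_fdr_rejected_with_message(self):
        up, down, rejects = filter_degs([("g", 2.0, 1.5)])
        assert not up and not down
        assert len(rejects) == 1 and "fdr" in rejects[0]

    def test_idempotent_and_fc_log2fc_equivalence(self, rng):
        rows = [DegRecord(f"g{i}", float(l), float(f))
                for i, (l, f) in enumerate(zip(rng.normal(0, 2, 200),
                                               rng.uniform(0, 1, 200)))]
        up, down, _ = filter_degs(rows)
        up2, down2, _ = filter_degs(up + down)
        assert up2 + down2 == up + down
        for d in up + down:
            assert 2 ** abs(d.log2fc) >= 2 - 1e-12


class TestExpandIupac:
    def test_concrete_word_singleton(self):
        assert expand_iupac("ACGT") == {"ACGT"}

    @pytest.mark.parametrize("pattern,size", [("TTDTCATC", 3), ("WWTRTCAT", 8)])
    def test_expansion_sizes(self, pattern, size):
        words = expand_iupac(pattern)
        assert len(words) == size
        assert all(len(w) == len(pattern) for w in words)

    def test_d_covers_g(self):
        assert "TTGTCATC" in expand_iupac("TTDTCATC")

    def test_unsupported_code_errors(self):
        with pytest.raises(ValueError, match="unsupported"):
            expand_iupac("ANGT")


class TestScanMotifs:
    def test_gc_only_sequence_no_w_hits(self):
        prom = PromoterSeq("g", "GC" * 50)
        assert scan_motifs(prom, motifs=(IupacMotif("WWTRTCAT"),)) == []

    def test_hand_aligned_hit(self):
        hits = scan_motifs(PromoterSeq("g", "AATTATCATCAA"),
                           motifs=(IupacMotif("TTDTCATC"),))
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 2 and plus[0].matched_word == "TTATCATC"

    def test_minus_strand_hit_found(self):
        word = "TTGTCATC"
        rc = str(Seq(word).reverse_complement())
        prom = PromoterSeq("g", "CCCC" + rc + "CCCC")
        hits = scan_motifs(prom, motifs=(IupacMotif("TTDTCATC"),))
        assert [(h.start, h.strand, h.matched_word) for h in hits] == [(4, "-", word)]

    def test_n_never_matches(self):
        prom = PromoterSeq("g", "TTNTCATC")
        assert scan_motifs(prom) == []

    def test_short_sequence_empty(self):
        assert scan_motifs(PromoterSeq("g", "ACGT")) == []

    def test_oracle_equivalence_random_sequences(self, rng):
        for _ in range(50):
            seq = random_seq(rng, n=400)
            got = sorted((h.start, h.strand, h.pattern)
                         for h in scan_motifs(PromoterSeq("g", seq)))
            assert got == brute_force_hits(seq)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_strand_duality(self, seed):
        # minus-strand hits equal plus-strand hits on the RC sequence,
        # with mirrored coordinates
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, n=200)
        rc_seq = str(Seq(seq).reverse_complement())
        minus = {(len(seq) - h.end, h.pattern)
                 for h in scan_motifs(PromoterSeq("g", seq)) if h.strand == "-"}
        plus_on_rc = {(h.start, h.pattern)
                      for h in scan_motifs(PromoterSeq("g", rc_seq))
                      if h.strand == "+"}
        assert minus == plus_on_rc


class TestAnnotate:
    def test_missing_promoters_unknown_not_zero(self):
        degs = [DegRecord("g1", 2.0, 0.01), DegRecord("g2", -2.0, 0.01)]
        out = annotate_degs_with_sites(degs, [])
        assert out["has_site"].isna().all() or (out["has_site"] == None).all()  # noqa: E711
        assert out["n_sites"].isna().all()

    def test_planted_truth_recovery(self, rng):
        # 85 genes, sites planted in exactly 26 promoters
        genes = [f"g{i}" for i in range(85)]
        planted = set(rng.choice(genes, size=26, replace=False))
        promoters = []
        for g in genes:
            seq = random_seq(rng, n=300)
            # scrub background hits so the planted set is exact
            while brute_force_hits(seq):
                seq = random_seq(rng, n=300)
            if g in planted:
                seq = seq[:100] + "TTGTCATC" + seq[108:]
            promoters.append(PromoterSeq(g, seq))
        degs = [DegRecord(g, 2.0, 0.01) for g in genes]
        out = annotate_degs_with_sites(degs, promoters).set_index("gene_id")
        assert set(out.index[out.has_site == True]) == planted  # noqa: E712

    def test_both_strand_sites_counted(self):
        word = "TTGTCATC"
        rc = str(Seq(word).reverse_complement())
        seq = "CC" + word + "CCCC" + rc + "CC"
        out = annotate_degs_with_sites(
            [DegRecord("g", 2.0, 0.01)], [PromoterSeq("g", seq)],
            motifs=(IupacMotif("TTDTCATC"),))
        assert out.loc[0, "n_sites"] == 2

    def test_duplicate_promoter_errors(self):
        p = PromoterSeq("g", "ACGTACGTACGT")
        with pytest.raises(ValueError, match="duplicate"):
            annotate_degs_with_sites([DegRecord("g", 2.0, 0.01)], [p, p])


class TestExtractPromoters:
    def make_genome(self, rng, n=3000):
        return {"chrI": random_seq(rng, n=n)}

    def test_plus_strand_coordinates(self, rng):
        genome = self.make_genome(rng)
        ann = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "start": 2001,
                             "end": 2500, "strand": "+"}])
        [prom] = extract_promoters(genome, ann)
        assert prom.length == 1500 and not prom.truncated
        assert prom.seq == genome["chrI"][500:2000]  # 1-based 501..2000

    def test_contig_edge_truncated(self, rng):
        genome = self.make_genome(rng)
        ann = pd.DataFrame([{"gene_id": "g", "contig": "chrI", "start": 10,
                             "end": 200, "strand": "+"}])
        [prom] = extract_promoters(genome, ann)
        assert prom.length == 9 and prom.truncated

    def test_minus_strand_reverse_complement(self):
        contig = "AAAACCCGGGTTTTACGT"
        ann = pd.DataFrame([{"gene_id": "g", "contig": "c", "start": 3,
                             "end": 10, "strand": "-"}])
        [prom] = extract_promoters({"c": contig}, ann, flank=5)
        # downstream-in-contig flank is bases 11..15 (1-based) = "TTTTA"
        assert prom.seq == str(Seq("TTTTA").reverse_complement())

    def test_missing_contig_errors(self, rng):
        ann = pd.DataFrame([{"gene_id": "gX", "contig": "nope", "start": 100,
                             "end": 200, "strand": "+"}])
        with pytest.raises(ValueError, match="gX"):
            extract_promoters(self.make_genome(rng), ann)
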