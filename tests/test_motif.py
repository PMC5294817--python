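import numpy as np
import pytest

from cistrovar.motif import (
    MotifModel,
    RefMismatchError,
    default_dr3_model,
    delta_lod,
    reverse_complement,
    scan,
    snp_in_motif,
)
from oracles import score_window_brute

CONSENSUS = "AGGTCA" + "AAG" + "AGGTCA"  # a planted DR3 with arbitrary spacer


@pytest.fixture
def model():
    return default_dr3_model()


class TestModel:
    def test_width_and_consensus(self, model):
        assert model.width == 15
        assert model.consensus_core() == "AGGTCA"

    def test_pwm_columns_validated(self):
        bad = np.full((4, 6), 0.3)
        with pytest.raises(ValueError):
            MotifModel(half_site_pwm=bad)

    def test_spacer_columns_carry_no_weight(self, model):
        W = model.weight_matrix()
        assert np.all(W[6:9] == 0.0)
        assert model.scored_offsets() == [0, 1, 2, 3, 4, 5, 9, 10, 11, 12, 13, 14]

    def test_score_additivity_against_brute_force(self, model):
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=15))
            expected = score_window_brute(
                seq, model.half_site_pwm.tolist(), 3, [0.25] * 4, model.pseudocount
            )
            assert model.score_window(seq) == pytest.approx(expected, rel=1e-9)


class TestScan:
    def test_planted_consensus_found_exactly_once(self, model):
        seq = "T" * 10 + CONSENSUS + "T" * 10
        hits = scan(seq, model, chrom="chr5", origin=100)
        assert len(hits) == 1
        h = hits[0]
        assert (h.chrom, h.start, h.end, h.strand) == ("chr5", 110, 125, "+")
        assert h.score == pytest.approx(model.max_score())
        assert h.sequence == CONSENSUS

    def test_reverse_complement_symmetry(self, model):
        seq = "T" * 10 + CONSENSUS + "T" * 10
        fwd = scan(seq, model)
        rev = scan(reverse_complement(seq), model)
        assert len(rev) == 1 and rev[0].strand == "-"
        assert rev[0].score == pytest.approx(fwd[0].score)
        # mirrored coordinates: same offset from the other end
        assert rev[0].start == len(seq) - fwd[0].end
        assert rev[0].sequence == fwd[0].sequence

    def test_all_n_and_short_sequences(self, model):
        assert scan("N" * 50, model) == []
        assert scan("ACGT", model) == []

    def test_window_with_single_n_skipped(self, model):
        seq = CONSENSUS[:7] + "N" + CONSENSUS[8:]
        assert scan(seq, model) == []

    def test_scan_scores_match_brute_force(self, model):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        lenient = default_dr3_model(score_threshold=-100.0)
        hits = scan(seq, lenient, both_strands=True)
        assert len(hits) == 2 * (200 - 15 + 1)
        for h in hits[:40]:
            window = seq[h.start : h.end]
            w = window if h.strand == "+" else reverse_complement(window)
            expected = score_window_brute(
                w, model.half_site_pwm.tolist(), 3, [0.25] * 4, model.pseudocount
            )
            assert h.score == pytest.approx(expected, rel=1e-9)


class TestSnpInMotif:
    def hits(self, model, strand="+"):
        seq = CONSENSUS if strand == "+" else reverse_complement(CONSENSUS)
        return scan(seq, model, chrom="chr1", origin=1000)

    def test_first_base_plus_strand(self, model):
        anns = snp_in_motif([("s", "chr1", 1000)], self.hits(model, "+"))
        assert anns[0].position_in_motif == 1

    def test_offset_ten_gives_position_eleven(self, model):
        anns = snp_in_motif([("s", "chr1", 1010)], self.hits(model, "+"))
        assert anns[0].position_in_motif == 11

    def test_minus_strand_positions_count_from_far_end(self, model):
        hits = self.hits(model, "-")
        assert hits[0].strand == "-"
        anns = snp_in_motif([("s", "chr1", 1002)], hits)
        assert anns[0].position_in_motif == 13

    def test_snp_outside_all_hits_unannotated(self, model):
        assert snp_in_motif([("s", "chr1", 5000)], self.hits(model)) == []


class TestDeltaLod:
    def ctx(self, flank="TTTTT"):
        return flank + CONSENSUS + flank

    def hit(self, model):
        return scan(self.ctx(), model, chrom="chr1", origin=0)[0]

    def test_alt_equal_ref_is_zero(self, model):
        h = self.hit(model)
        snp = ("s", "chr1", 7, "G", "G")  # offset 2 into the motif at start 5
        assert delta_lod(model, self.ctx(), snp, h) == 0.0

    @pytest.mark.parametrize("offset", [6, 7, 8])
    def test_spacer_positions_score_zero(self, model, offset):
        h = self.hit(model)
        pos = h.start + offset
        ref = self.ctx()[pos]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        assert delta_lod(model, self.ctx(), ("s", "chr1", pos, ref, alt), h) == 0.0

    def test_single_column_closed_form(self, model):
        # consensus base -> lowest-probability base at column 4 (C, p=0.425+pc)
        h = self.hit(model)
        pos = h.start + 4  # column 5 of hexamer 1: consensus C
        ref = self.ctx()[pos]
        assert ref == "C"
        p = model.half_site_pwm + model.pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        closed = np.log2(p[0, 4] / 0.25) - np.log2(p[1, 4] / 0.25)  # A vs C
        dl = delta_lod(model, self.ctx(), ("s", "chr1", pos, "C", "A"), h)
        assert dl == pytest.approx(float(closed), rel=1e-9)
        assert dl < 0  # consensus lost -> reference favored

    def test_minus_strand_rescoring(self, model):
        ctx = "TTTTT" + reverse_complement(CONSENSUS) + "TTTTT"
        h = scan(ctx, model, chrom="chr1", origin=0)[0]
        assert h.strand == "-"
        pos = h.start + 1
        ref = ctx[pos]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        dl = delta_lod(model, ctx, ("s", "chr1", pos, ref, alt), h)
        # verified by full rescoring of both windows
        alt_ctx = ctx[:pos] + alt + ctx[pos + 1 :]
        expected = model.score_window(
            alt_ctx[h.start : h.end], "-"
        ) - model.score_window(ctx[h.start : h.end], "-")
        assert dl == pytest.approx(expected, rel=1e-9)
        assert dl != 0.0

    def test_ref_mismatch_rejected_with_position(self, model):
        h = self.hit(model)
        with pytest.raises(RefMismatchError, match="chr1:7"):
            delta_lod(model, self.ctx(), ("s", "chr1", 7, "T", "A"), h)


class TestPlantedRecovery:
    def test_recall_and_background_rate(self, model):
        rng = np.random.default_rng(2024)
        n_seq, found = 100, 0
        bg_hits = bg_windows = 0
        for _ in range(n_seq):
            bg = "".join(rng.choice(list("ACGT"), size=400))
            pos = int(rng.integers(0, 400 - 15))
            spacer = "".join(rng.choice(list("ACGT"), size=3))
            planted = bg[:pos] + "AGGTCA" + spacer + "AGGTCA" + bg[pos + 15 :]
            hits = scan(planted, model)
            if any(h.start == pos and h.strand == "+" for h in hits):
                found += 1
            bg_hits += len(scan(bg, model))
            bg_windows += 2 * (400 - 15 + 1)
        assert found == n_seq  # planted consensus is always the maximal score
        # false-positive rate at the 80%-of-max threshold stays rare
        assert bg_hits / bg_windows < 1e-3
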