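"""Aligner: loss values, filter boundaries, decoding contract, memorization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alnvec.aligner import (
    AlignmentRecord,
    DeepBLASTModel,
    GroundTruthAlignment,
    align_pair,
    alignment_loss,
    filter_training_alignments,
    max_gap_run,
    render_alignment_text,
    train_deepblast,
)
from alnvec.diffdp import AlignmentPath
from alnvec.embedder import ToyEmbedder
from alnvec.scoring_heads import ScoringHeadConfig


def _rec(states: str, label: float, name: str = "r") -> AlignmentRecord:
    return AlignmentRecord(f"{name}_a", f"{name}_b", GroundTruthAlignment.from_states(states, label), label)


class TestGroundTruth:
    def test_from_states_round_trip(self):
        t = GroundTruthAlignment.from_states("MXYMM", source_label=0.9)
        assert t.shape == (4, 4)
        assert t.estar.sum() == 3
        assert t.to_path().states == "MXYMM"

    def test_double_match_in_a_row_rejected(self):
        m = np.zeros((2, 2))
        m[0, 0] = m[0, 1] = 1
        with pytest.raises(ValueError):
            GroundTruthAlignment(m)

    def test_crossing_matches_rejected(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 1
        with pytest.raises(ValueError):
            GroundTruthAlignment(m)


class TestAlignmentLoss:
    def test_perfect_binary_prediction_has_zero_loss(self):
        t = GroundTruthAlignment.from_states("MM")
        assert alignment_loss(t, t.estar) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_half_prediction_costs_log_two_per_cell(self):
        e = np.full((2, 2), 0.5)
        t = GroundTruthAlignment.from_states("MM")
        assert alignment_loss(t, e) == pytest.approx(math.log(2.0))
        assert alignment_loss(t, e, reduction="sum") == pytest.approx(4 * math.log(2.0))

    def test_hand_computed_value(self):
        estar = np.zeros((2, 2))
        estar[0, 0] = 1.0
        e = np.full((2, 2), 0.1)
        e[0, 0] = 0.9
        expect = -(math.log(0.9) + 3 * math.log(0.9)) / 4
        assert alignment_loss(estar, e) == pytest.approx(expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alignment_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestFilter:
    def test_eleven_gap_run_excluded_despite_high_label(self):
        kept, report = filter_training_alignments([_rec("M" + "X" * 11 + "M", 0.9)])
        assert kept == [] and report["long_gap_run"] == 1

    def test_boundary_ten_gap_run_and_label_point_six_retained(self):
        kept, _ = filter_training_alignments([_rec("M" + "X" * 10 + "M", 0.60)])
        assert len(kept) == 1

    def test_low_label_excluded_without_gaps(self):
        kept, report = filter_training_alignments([_rec("MMMM", 0.59)])
        assert kept == [] and report["low_tm"] == 1

    def test_mixed_gap_run_breaks_the_run(self):
        # 6 X then 6 Y: neither single-state run exceeds 10
        kept, _ = filter_training_alignments([_rec("M" + "X" * 6 + "Y" * 6 + "M", 0.8)])
        assert len(kept) == 1

    @given(run=st.integers(1, 20), other=st.sampled_from("XY"))
    @settings(max_examples=40, deadline=None)
    def test_run_length_boundary_property(self, run, other):
        states = "M" + other * run + "M"
        kept, _ = filter_training_alignments([_rec(states, 0.8)])
        assert bool(kept) == (run <= 10)
        assert max_gap_run(states) == run


class TestAlignPair:
    @pytest.fixture(scope="class")
    def model(self):
        return DeepBLASTModel(embedder=ToyEmbedder(d=16, seed=0))

    def test_untrained_model_yields_valid_path(self, model):
        res = align_pair("AAA", "AAA", model)
        assert (res.path.p, res.path.q) == (3, 3)
        assert res.expected.e.shape == (3, 3)
        assert 0.0 <= res.expected.e.min() and res.expected.e.max() <= 1.0 + 1e-9

    def test_rendered_text_has_three_row_blocks(self, model):
        seq = "MKVLATLLLLGAVVA" * 5
        res = align_pair(seq, seq, model)
        blocks = res.text.split("\n\n")
        for block in blocks:
            rows = block.split("\n")
            assert len(rows) == 3
            assert len(rows[0]) <= 60
        assert ">" in res.gapped_fasta

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            align_pair("", "AAA", model)

    def test_low_confidence_flag_reflects_marginals(self, model):
        res = align_pair("ACDEFGHIKL", "ACDEFGHIKL", model)
        assert res.low_confidence == (res.expected.e.max() < 0.5)


class TestTrainDeepblast:
    SEQS = {
        "a": "MKVLATLLLLGAVVAQSTPN",
        "b": "MKVLATLWLLGAVVAQSTPN",
    }

    def test_single_repeated_example_is_memorized(self):
        rec = AlignmentRecord("a", "b", GroundTruthAlignment.from_states("M" * 20, 0.95), 0.95)
        model, log = train_deepblast(
            [rec] * 8,
            self.SEQS,
            ScoringHeadConfig(n_layers=2, width=16, d=16, seed=0),
            lr=5e-3,
            batch_size=4,
            epochs=30,
            val_fraction=0.2,
            patience=30,
            seed=0,
        )
        assert log.train_loss[-1] < 0.01

    def test_training_is_deterministic(self):
        rec = AlignmentRecord("a", "b", GroundTruthAlignment.from_states("M" * 20, 0.95), 0.95)
        kw = dict(
            heads_config=ScoringHeadConfig(n_layers=1, width=16, d=16, seed=1),
            lr=1e-3, batch_size=4, epochs=2, seed=3,
        )
        _, l1 = train_deepblast([rec] * 6, self.SEQS, **kw)
        _, l2 = train_deepblast([rec] * 6, self.SEQS, **kw)
        assert l1.train_loss == l2.train_loss

    def test_everything_filtered_out_is_an_error(self):
        rec = AlignmentRecord("a", "b", GroundTruthAlignment.from_states("M" * 20, 0.2), 0.2)
        with pytest.raises(ValueError, match="filter"):
            train_deepblast([rec], self.SEQS)

    def test_render_alignment_text_marks_matches(self):
        path = AlignmentPath("MMXM")
        text = render_alignment_text("ABCD", "ABD", path)
        rows = text.split("\n")
        assert rows[0] == "ABCD"
        assert rows[1] == "|| |"
        assert rows[2] == "AB-D"
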