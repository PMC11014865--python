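import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastosort import fixtures as fx
from plastosort.targeting import (
    AMINO_ACIDS,
    PSSM,
    SignalPeptideCall,
    alt_positive_ids,
    asafind_classify,
    build_pssm,
    default_thresholds,
    first_met_trim,
    merge_routes,
    parse_flag_table,
    parse_legacy_table,
    parse_signalp5,
    pool_variant_calls,
    uniform_background,
    write_legacy_table,
)

SIGNALP5_DOC = """\
# SignalP-5.0\tOrganism: Euk
# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position
prot1\tSP(Sec/SPI)\t0.97\t0.03\tCS pos: 20-21. Pr: 0.88
prot2\tOTHER\t0.01\t0.99
"""


class TestSignalPParsing:
    def test_positive_and_negative_rows(self):
        calls = {c.sequence_id: c for c in parse_signalp5(SIGNALP5_DOC)}
        assert calls["prot1"].has_sp and calls["prot1"].cleavage_pos == 20
        assert calls["prot1"].sp_probability == pytest.approx(0.97)
        assert not calls["prot2"].has_sp

    def test_sp_row_without_cs_field_raises(self):
        doc = "prot1\tSP(Sec/SPI)\t0.97\t0.03\n"
        with pytest.raises(ValueError, match="prot1"):
            parse_signalp5(doc)

    def test_legacy_round_trip(self):
        calls = parse_signalp5(SIGNALP5_DOC)
        back = parse_legacy_table(write_legacy_table(calls))
        assert [(c.sequence_id, c.has_sp, c.cleavage_pos) for c in back] == [
            (c.sequence_id, c.has_sp, c.cleavage_pos) for c in calls
        ]

    def test_positive_call_requires_cleavage(self):
        with pytest.raises(ValueError):
            SignalPeptideCall(sequence_id="x", has_sp=True)


class TestVariantPooling:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ARMLKV", "MLKV"), ("MKV", "MKV"), ("ARLKV", None)],
    )
    def test_first_met_trim(self, seq, expected):
        assert first_met_trim(seq) == expected

    def test_trimmed_positive_shifts_coordinates(self):
        original = SignalPeptideCall("p", has_sp=False)
        trimmed = SignalPeptideCall("p", has_sp=True, cleavage_pos=18)
        pooled = pool_variant_calls(original, trimmed, trim_offset=4)
        assert pooled.has_sp and pooled.cleavage_pos == 22
        assert pooled.source_variant == "first_met_trimmed"

    def test_both_positive_keeps_original(self):
        original = SignalPeptideCall("p", has_sp=True, cleavage_pos=20)
        trimmed = SignalPeptideCall("p", has_sp=True, cleavage_pos=18)
        assert pool_variant_calls(original, trimmed, 4) is original

    def test_both_negative_stays_negative(self):
        original = SignalPeptideCall("p", has_sp=False)
        trimmed = SignalPeptideCall("p", has_sp=False)
        assert not pool_variant_calls(original, trimmed, 4).has_sp

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError):
            pool_variant_calls(
                SignalPeptideCall("a", has_sp=False),
                SignalPeptideCall("b", has_sp=False),
                0,
            )


class TestBuildPSSM:
    def test_background_equal_training_scores_zero(self):
        # every residue appears equally often at every position
        windows = [a * 3 for a in AMINO_ACIDS]
        matrix = build_pssm(windows, pseudocount=1.0)
        assert np.allclose(matrix.scores, 0.0, atol=1e-12)

    def test_pure_column_closed_form_without_pseudocount(self):
        matrix = build_pssm(["R"] * 10, pseudocount=0.0)
        expected = math.log2(1 / 0.05)
        assert matrix.score_of(-5, "R") == pytest.approx(expected, abs=1e-9)

    def test_pure_column_closed_form_with_pseudocount(self):
        matrix = build_pssm(["R"] * 10, pseudocount=1.0)
        expected = math.log2((10 + 0.05) / 11 / 0.05)
        assert matrix.score_of(-5, "R") == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "windows,background,err",
        [
            (["AA", "AAA"], None, "length"),
            (["AZ"], None, "unknown residue"),
            (["AA"], {"A": 1.0}, "missing letters"),
            ([], None, "at least one"),
        ],
    )
    def test_invalid_inputs_raise(self, windows, background, err):
        with pytest.raises(ValueError, match=err):
            build_pssm(windows, background=background)

    def test_tsv_round_trip(self, tmp_path):
        matrix = fx.sharp_pssm()
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        back = PSSM.from_tsv(path)
        assert back.positions == matrix.positions
        assert np.allclose(back.scores, matrix.scores, atol=1e-6)
        assert np.allclose(back.background, matrix.background, atol=1e-6)

    def test_sampled_windows_recover_generator(self):
        """Windows sampled from a sharp matrix's positional distributions
        give back the per-position consensus, and entries converge."""
        generator = fx.sharp_pssm(concentration=0.9)
        rng = np.random.default_rng(11)
        letters = list(AMINO_ACIDS)
        dists = [generator.positional_distribution(p) for p in generator.positions]

        def sample(n):
            out = []
            for _ in range(n):
                out.append(
                    "".join(
                        letters[int(rng.choice(20, p=d))] for d in dists
                    )
                )
            return out

        learned_small = build_pssm(sample(300), positions=generator.positions)
        assert np.array_equal(
            learned_small.scores.argmax(axis=1), generator.scores.argmax(axis=1)
        )
        learned_big = build_pssm(sample(5000), positions=generator.positions)
        deviation = np.abs(learned_big.scores - generator.scores)
        # rare-residue log-odds carry ~0.3-bit sampling noise at this depth,
        # so convergence is asserted on the entries that dominate window
        # scores: frequency-weighted mean and the consensus entries
        weights = np.vstack(
            [generator.positional_distribution(p) for p in generator.positions]
        )
        assert (deviation * weights).sum() / weights.sum() < 0.2
        consensus_cols = generator.scores.argmax(axis=1)
        assert np.max(deviation[np.arange(len(consensus_cols)), consensus_cols]) < 0.2


class TestScoring:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_window_score_is_sum_of_per_residue_scores(self, seed):
        matrix = fx.sharp_pssm()
        rng = np.random.default_rng(seed)
        length = int(rng.integers(40, 80))
        seq = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
        )
        cleavage = int(rng.integers(10, 30))
        total = matrix.score_window(seq, cleavage)
        manual = 0.0
        for p in matrix.positions:
            idx = cleavage + 1 + p
            if 1 <= idx <= len(seq):
                manual += matrix.score_of(p, seq[idx - 1])
        assert total == pytest.approx(manual, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 15))
    def test_shift_consistency(self, seed, k):
        """Prepending k residues and shifting the cleavage site leaves all
        window scores unchanged."""
        matrix = fx.sharp_pssm()
        rng = np.random.default_rng(seed)
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=70))
        prefix = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=k))
        cleavage = 25
        for offset in range(-2, 3):
            assert matrix.score_window(
                seq, cleavage, offset
            ) == pytest.approx(
                matrix.score_window(prefix + seq, cleavage + k, offset),
                abs=1e-9,
            )

    def test_out_of_sequence_positions_score_zero(self):
        matrix = fx.sharp_pssm()
        short = "M" + "A" * 20  # ends 2 residues after the cleavage site
        full_score = matrix.score_window(short, 19)
        inside = sum(
            matrix.score_of(p, short[19 + p + 1 - 1])
            for p in matrix.positions
            if 1 <= 19 + 1 + p <= len(short)
        )
        assert full_score == pytest.approx(inside, abs=1e-9)


class TestClassification:
    def make_consensus_sequence(self, matrix, cleavage=20, total=60):
        consensus = {
            p: AMINO_ACIDS[int(matrix.scores[i].argmax())]
            for i, p in enumerate(matrix.positions)
        }
        residues = ["A"] * total
        residues[0] = "M"
        for p, aa in consensus.items():
            idx = cleavage + 1 + p
            if 1 <= idx <= total:
                residues[idx - 1] = aa
        return "".join(residues)

    def test_consensus_sequence_is_high_confidence(self):
        matrix = fx.sharp_pssm()
        seq = self.make_consensus_sequence(matrix)
        sp = SignalPeptideCall("x", has_sp=True, cleavage_pos=20)
        call = asafind_classify(seq, sp, matrix)
        assert call.klass == "plastid_high"
        assert call.best_offset == 0
        assert call.at_site_score == pytest.approx(matrix.max_window_score())

    def test_negative_sp_gates_to_no_sp(self):
        matrix = fx.sharp_pssm()
        call = asafind_classify(
            "MAAAA", SignalPeptideCall("x", has_sp=False), matrix
        )
        assert call.klass == "no_sp"
        assert call.at_site_score is None

    def test_low_scoring_site_is_not_plastid(self):
        matrix = fx.sharp_pssm()
        rng = np.random.default_rng(1)
        seq = "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 59))
        sp = SignalPeptideCall("x", has_sp=True, cleavage_pos=20)
        call = asafind_classify(seq, sp, matrix)
        assert call.klass == "not_plastid"

    def test_shifted_optimum_denies_high_confidence(self):
        matrix = fx.sharp_pssm()
        # consensus window planted one residue downstream of the called site
        seq = self.make_consensus_sequence(matrix, cleavage=21)
        sp = SignalPeptideCall("x", has_sp=True, cleavage_pos=20)
        t_high, t_low = default_thresholds(matrix)
        call = asafind_classify(seq, sp, matrix, t_low=-1e9)
        assert call.best_offset == 1
        assert call.best_offset_score > call.at_site_score
        assert call.klass != "plastid_high"

    def test_window_entirely_outside_sequence_raises(self):
        matrix = fx.sharp_pssm()
        sp = SignalPeptideCall("x", has_sp=True, cleavage_pos=500)
        with pytest.raises(ValueError, match="outside"):
            asafind_classify("MAAA", sp, matrix)

    def test_threshold_order_enforced(self):
        matrix = fx.sharp_pssm()
        sp = SignalPeptideCall("x", has_sp=True, cleavage_pos=3)
        with pytest.raises(ValueError, match="t_low"):
            asafind_classify("MAAAAAAA", sp, matrix, t_high=1.0, t_low=2.0)


class TestRoutesMerging:
    def test_flag_table_parsing(self):
        predisi = parse_flag_table("p1 0.9 Y\np2 0.1 N\np3 0.8 Y\n")
        chlorop = parse_flag_table("p1  0.55  Y\np2  0.60  Y\n")
        assert alt_positive_ids(predisi, chlorop) == {"p1"}

    def test_merge_rules(self):
        matrix = fx.flat_pssm()

        def call(sid, klass):
            sp = SignalPeptideCall(sid, has_sp=klass != "no_sp",
                                   cleavage_pos=None if klass == "no_sp" else 10)
            from plastosort.targeting import PresequenceCall

            return PresequenceCall(
                sequence_id=sid, sp=sp,
                at_site_score=0.0, best_offset_score=0.0, best_offset=0,
                klass=klass,
            )

        calls = [
            call("a", "plastid_high"),
            call("b", "not_plastid"),
            call("c", "no_sp"),
            call("d", "plastid_low"),
        ]
        final = merge_routes(calls, alt_positive={"a", "b", "z"})
        assert final == ["a", "d", "SPTP-b", "SPTP-z"]

    def test_merge_has_no_duplicates(self):
        assert merge_routes([], alt_positive={"x"}) == ["SPTP-x"]
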