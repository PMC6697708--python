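import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhprof import (MSA, ColumnSpec, SyntheticMsaSpec, SyntheticStructureSpec,
                    column_occupancy, entropy_profile, entropy_track,
                    make_msa, make_structure_pair, map_to_reference, read_msa,
                    refine_msa, shannon_entropy)
from dhprof.conservation import AMINO_ACIDS
from dhprof.errors import (ArgumentError, EmptyAlignmentError, FormatError,
                           ReferenceMismatchError)

from oracles import column_entropy_bits


def _msa_from_columns(columns):
    n_seq = len(columns[0])
    return MSA(records=[(f"s{i}", "".join(col[i] for col in columns))
                        for i in range(n_seq)])


class TestOccupancy:
    def test_four_gaps_in_ten(self):
        msa = _msa_from_columns(["AAAAAA----"])
        assert column_occupancy(msa)[0] == pytest.approx(0.6)

    def test_all_gap_column_is_zero(self):
        msa = _msa_from_columns(["----", "AAAA"])
        occ = column_occupancy(msa)
        assert occ[0] == 0.0 and occ[1] == 1.0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(FormatError):
            MSA(records=[("a", "ACD"), ("b", "AC")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=30))
                for _ in range(15)]
        msa = MSA(records=[(f"s{i}", row) for i, row in enumerate(rows)])
        occ = column_occupancy(msa)
        for j in range(30):
            expected = sum(row[j] != "-" for row in rows) / 15
            assert occ[j] == pytest.approx(expected)


class TestRefine:
    def test_gapless_msa_fully_retained(self):
        msa = _msa_from_columns(["AAAA", "CCCC", "DDDD"])
        refined, retained = refine_msa(msa, 0.10)
        assert retained == [0, 1, 2]
        assert refined.n_columns == 3

    def test_exact_ten_percent_is_kept(self):
        # 20 sequences, 2 non-gaps: occupancy exactly 0.10 -> inclusive keep
        col_keep = "AA" + "-" * 18
        col_drop = "A" + "-" * 19
        msa = _msa_from_columns([col_keep, col_drop, "A" * 20])
        refined, retained = refine_msa(msa, 0.10)
        assert retained == [0, 2]

    def test_no_columns_left_raises(self):
        msa = _msa_from_columns(["-A", "-C"])
        with pytest.raises(EmptyAlignmentError):
            refine_msa(msa, 1.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True,
              database=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACD--"), size=20)) for _ in range(10)]
        msa = MSA(records=[(f"s{i}", r) for i, r in enumerate(rows)])
        retained = []
        for threshold in (0.1, 0.3, 0.5, 0.8):
            try:
                _, cols = refine_msa(msa, threshold)
            except EmptyAlignmentError:
                cols = []
            retained.append(set(cols))
        for loose, strict in zip(retained, retained[1:]):
            assert strict <= loose


class TestShannonEntropy:
    def test_conserved_column_is_zero(self):
        assert shannon_entropy("A" * 50) == 0.0

    def test_uniform_column_hits_log2_20(self):
        assert shannon_entropy(AMINO_ACIDS) == pytest.approx(math.log2(20), abs=1e-9)

    def test_even_two_letter_split_is_one_bit(self):
        assert shannon_entropy("A" * 10 + "V" * 10) == pytest.approx(1.0, abs=1e-9)

    def test_gaps_and_ambiguous_letters_excluded(self):
        assert shannon_entropy("AAAA----XXBB") == 0.0

    def test_all_gap_column_rejected(self):
        with pytest.raises(ArgumentError):
            shannon_entropy("----")

    def test_natural_log_base(self):
        h_nats = shannon_entropy("A" * 10 + "V" * 10, base=math.e)
        assert h_nats == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_oracle(self, seed):
        rng = np.random.default_rng(seed)
        column = "".join(rng.choice(list(AMINO_ACIDS + "-X"), size=80))
        if not any(c in AMINO_ACIDS for c in column):
            column += "A"
        assert shannon_entropy(column) == pytest.approx(
            column_entropy_bits(column), abs=1e-12)


class TestEntropyProfile:
    def test_fully_conserved_msa_is_all_zero(self):
        msa = _msa_from_columns(["AAAA", "CCCC", "GGGG"])
        profile = entropy_profile(msa)
        assert np.all(profile.entropy == 0.0)

    def test_entropy_bounds_and_frequency_normalization(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=40))
                for _ in range(30)]
        msa = MSA(records=[(f"s{i}", r) for i, r in enumerate(rows)])
        profile = entropy_profile(msa, 0.10)
        assert np.all(profile.entropy >= 0.0)
        assert np.all(profile.entropy <= math.log2(20) + 1e-12)
        sums = profile.frequencies.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)

    def test_sequence_order_irrelevant(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=25))
                for _ in range(12)]
        msa = MSA(records=[(f"s{i}", r) for i, r in enumerate(rows)])
        shuffled = MSA(records=[msa.records[i] for i in rng.permutation(12)])
        p1, p2 = entropy_profile(msa), entropy_profile(shuffled)
        assert np.allclose(p1.entropy, p2.entropy)
        assert np.allclose(p1.occupancy, p2.occupancy)

    def test_empirical_entropy_tracks_generator_truth(self):
        spec = SyntheticMsaSpec(
            n_sequences=500,
            columns=[ColumnSpec(kind="dirichlet", concentration=1.0)
                     for _ in range(40)],
            seed=12)
        msa, truth = make_msa(spec)
        profile = entropy_profile(msa, 0.10)
        assert np.abs(profile.entropy - truth.expected_entropy).max() < 0.15

    def test_planted_variable_blocks_have_highest_entropy(self):
        # two high-entropy blocks among conserved background
        columns = []
        for j in range(60):
            if 10 <= j < 18 or 40 <= j < 48:
                columns.append(ColumnSpec(kind="dirichlet", concentration=20.0))
            else:
                columns.append(ColumnSpec(kind="conserved", letter="L"))
        msa, _ = make_msa(SyntheticMsaSpec(n_sequences=200, columns=columns, seed=13))
        profile = entropy_profile(msa)
        high = set(np.argsort(profile.entropy)[-16:])
        assert high == set(range(10, 18)) | set(range(40, 48))


class TestReadMsa:
    def test_fasta_roundtrip_and_dot_normalization(self, tmp_path):
        path = tmp_path / "m.fasta"
        path.write_text(">a\nAC.E\n>b\nAC-E\n")
        msa = read_msa(path)
        assert msa.records == [("a", "AC-E"), ("b", "AC-E")]


class TestMapToReference:
    def _structure_for(self, sequence, unmodeled=()):
        spec = SyntheticStructureSpec(n_residues=len(sequence), sequence=sequence,
                                      unmodeled=list(unmodeled), seed=1)
        st, _, _ = make_structure_pair(spec)
        return st

    def test_identity_map_when_row_equals_chain(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        st = self._structure_for(seq)
        msa = MSA(records=[("REF", seq), ("other", seq)])
        mapping = map_to_reference(msa, "REF", st, "A")
        assert mapping.pairs == [(j, (j + 1, "")) for j in range(len(seq))]

    def test_leading_gap_columns_shift_map(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        st = self._structure_for(seq)
        msa = MSA(records=[("REF", "-----" + seq), ("other", "AAAAA" + seq)])
        mapping = map_to_reference(msa, "REF", st, "A")
        assert mapping.pairs[0] == (5, (1, ""))

    def test_unmodeled_loop_columns_inferred(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        st = self._structure_for(seq, unmodeled=[(25, 35)])
        msa = MSA(records=[("REF", seq), ("other", seq)])
        mapping = map_to_reference(msa, "REF", st, "A")
        mapped = mapping.residue_for_column()
        # flanks mapped through the alignment, loop assigned by interpolation
        assert mapped[23] == (24, "")
        assert mapped[36] == (37, "")
        for col in range(24, 35):
            assert mapped[col] == (col + 1, "")

    def test_unmodeled_loop_unmapped_without_inference(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        st = self._structure_for(seq, unmodeled=[(25, 35)])
        msa = MSA(records=[("REF", seq), ("other", seq)])
        mapping = map_to_reference(msa, "REF", st, "A", infer_unmodeled=False)
        mapped = mapping.residue_for_column()
        assert all(col not in mapped for col in range(24, 35))

    def test_wrong_reference_rejected(self):
        st = self._structure_for("ACDEFGHIKLMNPQRSTVWY")
        msa = MSA(records=[("REF", "WWWWWWWWWWWWWWWWWWWW")])
        with pytest.raises(ReferenceMismatchError):
            map_to_reference(msa, "REF", st, "A")

    def test_map_injective_both_ways(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        st = self._structure_for(seq, unmodeled=[(10, 14)])
        msa = MSA(records=[("REF", seq)])
        mapping = map_to_reference(msa, "REF", st, "A")
        cols = [c for c, _ in mapping.pairs]
        rids = [r for _, r in mapping.pairs]
        assert len(cols) == len(set(cols)) and len(rids) == len(set(rids))

    def test_entropy_track_pushes_values_onto_residues(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        st = self._structure_for(seq)
        rows = [("REF", seq)] + [(f"s{i}", seq) for i in range(9)]
        msa = MSA(records=rows)
        profile = entropy_profile(msa)
        mapping = map_to_reference(msa, "REF", st, "A")
        track = entropy_track(profile, mapping)
        assert set(track) == {(n, "") for n in range(1, 21)}
        assert all(v == 0.0 for v in track.values())
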