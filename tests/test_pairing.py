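"""Pairing engine: table IO, scoring, enumeration, and the fast scan."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betallps.pairing import (
    AMINO_ACIDS,
    BetaPairing,
    EnergyTable,
    EnergyTableError,
    Orientation,
    average_register_shift,
    best_pairings,
    diagonal_optima,
    enumerate_pairings,
    load_energy_table,
    scan_sequences,
    score_pairing,
    write_energy_table,
)
from conftest import pair_table, random_sequence, random_tables


class TestEnergyTableIO:
    def test_zero_matrix_roundtrip(self, tmp_path):
        path = tmp_path / "zero.tsv"
        write_energy_table(EnergyTable.zeros("parallel"), path)
        table = load_energy_table(path, "parallel")
        assert np.all(table.matrix == 0.0)

    def test_random_roundtrip_cell_for_cell(self, tmp_path):
        par, _ = random_tables(5)
        path = tmp_path / "t.tsv"
        write_energy_table(par, path)
        again = load_energy_table(path, "parallel")
        np.testing.assert_allclose(again.matrix, par.matrix, rtol=1e-5)

    def test_missing_row_names_residue(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = [" ".join(AMINO_ACIDS)]
        for aa in AMINO_ACIDS:
            if aa != "W":
                lines.append(aa + " " + " ".join(["0"] * 20))
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(EnergyTableError, match="W"):
            load_energy_table(path, "parallel")

    def test_non_numeric_cell_reports_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = [" ".join(AMINO_ACIDS)]
        for aa in AMINO_ACIDS:
            row = ["0"] * 20
            if aa == "K":
                row[3] = "oops"
            lines.append(aa + " " + " ".join(row))
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(EnergyTableError, match="oops"):
            load_energy_table(path, "parallel")

    def test_header_must_be_permutation(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A C D\nA 0 0 0\n")
        with pytest.raises(EnergyTableError, match="permutation"):
            load_energy_table(path, "parallel")

    def test_comments_and_ordering(self, tmp_path):
        # scrambled header order must land entries in the right cells
        par, _ = random_tables(11)
        path = tmp_path / "t.tsv"
        order = list(AMINO_ACIDS)[::-1]
        with open(path, "w") as fh:
            fh.write("# a comment\n" + " ".join(order) + "\n")
            for aa in AMINO_ACIDS:
                vals = " ".join(
                    format(par.energy(aa, b), ".8g") for b in order
                )
                fh.write(f"{aa} {vals}\n")
        again = load_energy_table(path, "parallel")
        np.testing.assert_allclose(again.matrix, par.matrix, rtol=1e-6)

    def test_symmetrized(self):
        par, _ = random_tables(3)
        sym = par.symmetrized()
        np.testing.assert_allclose(sym.matrix, sym.matrix.T)


class TestScorePairing:
    def test_zero_table_scores_zero(self, zero_tables):
        p = BetaPairing(1, 2, 3, 4, "parallel", 0.0)
        assert score_pairing("VVVV", p, zero_tables[0]) == 0.0

    def test_parallel_homopair(self, vv_tables):
        p = BetaPairing(1, 2, 3, 4, "parallel", 0.0)
        assert score_pairing("VVVV", p, vv_tables[0]) == -2.0

    def test_antiparallel_hand_summed(self):
        # independently hand-evaluated per-term oracle on an asymmetric table
        anti = pair_table(
            Orientation.ANTIPARALLEL,
            {("A", "I"): -0.7, ("V", "L"): 0.4, ("I", "A"): 5.0, ("L", "V"): 5.0},
        )
        p = BetaPairing(1, 2, 3, 4, "antiparallel", 0.0)
        # pairs: seq[1]=A faces seq[4]=I; seq[2]=V faces seq[3]=L
        assert score_pairing("AVLI", p, anti) == pytest.approx(-0.7 + 0.4)

    def test_out_of_bounds_raises(self, zero_tables):
        p = BetaPairing(1, 3, 3, 5, "parallel", 0.0)
        with pytest.raises(IndexError):
            score_pairing("VVVV", p, zero_tables[0])

    def test_orientation_mismatch_raises(self, zero_tables):
        p = BetaPairing(1, 2, 3, 4, "antiparallel", 0.0)
        with pytest.raises(ValueError, match="orientation"):
            score_pairing("VVVV", p, zero_tables[0])

    def test_noncanonical_pairing_rejected(self):
        with pytest.raises(ValueError, match="m >= k"):
            BetaPairing(3, 4, 1, 2, "parallel", 0.0)


class TestEnumerate:
    def test_counts_n5(self, zero_tables):
        allp = enumerate_pairings("AVLIC", zero_tables, min_lp=2)
        assert len(allp) == 40  # 20 per orientation
        par = [p for p in allp if p.orientation is Orientation.PARALLEL]
        assert len(par) == 20

    def test_n_equals_min_lp(self, zero_tables):
        allp = enumerate_pairings("AVLI", zero_tables, min_lp=4)
        assert len(allp) == 2  # one full-length self-pairing per orientation
        assert {p.orientation for p in allp} == set(Orientation)

    def test_empty_sequence_errors(self, zero_tables):
        with pytest.raises(ValueError):
            enumerate_pairings("", zero_tables, min_lp=2)

    def test_every_entry_scored(self, zero_tables):
        par = pair_table(Orientation.PARALLEL, {}, base=1.0)
        allp = enumerate_pairings("AVLIC", (par, zero_tables[1]), min_lp=3)
        for p in allp:
            if p.orientation is Orientation.PARALLEL:
                assert p.energy == p.lp


class TestBestPairings:
    def test_homopolymer_v8(self, vv_tables):
        s = best_pairings("VVVVVVVV", vv_tables, min_lp=4)
        assert s.E == -8.0
        assert s.lp == 8
        assert s.best.shift == 0
        assert s.best.orientation is Orientation.PARALLEL
        assert sorted(p.shift for p in s.top_pairings) == [0, 1, 2, 3, 4]
        assert s.S == 2.0

    def test_zero_tables_tiebreak(self, zero_tables):
        s = best_pairings("AVLICAVLIC", zero_tables, min_lp=4)
        assert s.E == 0.0
        b = s.best
        # longest, in-register-first, leftmost, parallel before antiparallel
        assert (b.k, b.l, b.m, b.n) == (1, 10, 1, 10)
        assert b.orientation is Orientation.PARALLEL

    def test_k_best_one(self, vv_tables):
        s = best_pairings("VVVVVVVV", vv_tables, k_best=1, min_lp=4)
        assert s.S == s.best.shift == 0

    def test_too_short_errors(self, zero_tables):
        with pytest.raises(ValueError):
            best_pairings("AVL", zero_tables, min_lp=4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_random(self, seed):
        """Fast diagonal scan finds the brute-force global minimum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 22))
        seq = random_sequence(rng, n)
        tables = random_tables(seed + 1)
        brute = min(enumerate_pairings(seq, tables, min_lp=4), key=BetaPairing.sort_key)
        s = best_pairings(seq, tables, min_lp=4)
        assert s.E == pytest.approx(brute.energy, abs=1e-9)
        assert (s.best.k, s.best.l, s.best.m, s.best.n, s.best.orientation) == (
            brute.k, brute.l, brute.m, brute.n, brute.orientation,
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_diagonal_decomposition(self, seed):
        """Each diagonal optimum is the brute-force minimum on its diagonal."""
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, int(rng.integers(6, 16)))
        tables = random_tables(seed)
        optima = diagonal_optima(seq, tables, min_lp=4)
        allp = enumerate_pairings(seq, tables, min_lp=4)
        for opt in optima:
            if opt.orientation is Orientation.PARALLEL:
                rivals = [
                    p for p in allp
                    if p.orientation is Orientation.PARALLEL and p.shift == opt.shift
                ]
            else:
                rivals = [
                    p for p in allp
                    if p.orientation is Orientation.ANTIPARALLEL
                    and p.k + p.n == opt.k + opt.n
                ]
            assert opt.energy == pytest.approx(min(p.energy for p in rivals), abs=1e-9)

    def test_translation_invariance(self, vv_tables):
        # prepend residues whose pairings are all strictly destabilizing
        par = pair_table(Orientation.PARALLEL, {("V", "V"): -1.0}, base=0.0)
        m = par.matrix.copy()
        from betallps.pairing import _AA_INDEX

        g = _AA_INDEX["G"]
        m[g, :] = 2.0
        m[:, g] = 2.0
        par = EnergyTable(Orientation.PARALLEL, m)
        anti = EnergyTable(Orientation.ANTIPARALLEL, np.abs(m) + 0.5)
        base = best_pairings("VVVVVV", (par, anti), min_lp=4)
        shifted = best_pairings("GGG" + "VVVVVV", (par, anti), min_lp=4)
        assert shifted.E == base.E
        assert (shifted.best.k, shifted.best.l) == (base.best.k + 3, base.best.l + 3)

    def test_energy_offset_monotonicity(self):
        """Subtracting c from every entry lowers each pairing by c*lp and the
        new global best matches the brute-force oracle on the shifted table."""
        rng = np.random.default_rng(42)
        seq = random_sequence(rng, 12)
        par, anti = random_tables(7)
        c = 0.75
        par2 = EnergyTable(Orientation.PARALLEL, par.matrix - c)
        anti2 = EnergyTable(Orientation.ANTIPARALLEL, anti.matrix - c)
        before = {
            (p.k, p.l, p.m, p.n, p.orientation): p.energy
            for p in enumerate_pairings(seq, (par, anti), min_lp=4)
        }
        after = enumerate_pairings(seq, (par2, anti2), min_lp=4)
        for p in after:
            key = (p.k, p.l, p.m, p.n, p.orientation)
            assert p.energy == pytest.approx(before[key] - c * p.lp, abs=1e-9)
        s = best_pairings(seq, (par2, anti2), min_lp=4)
        assert s.E == pytest.approx(min(p.energy for p in after), abs=1e-9)


class TestAverageShift:
    def test_examples(self, vv_tables):
        mk = lambda shift: BetaPairing(1, 4, 1 + shift, 4 + shift, "parallel", 0.0)
        assert average_register_shift([mk(s) for s in (0, 1, 2, 3, 4)]) == 2.0
        assert average_register_shift([mk(0), mk(0)]) == 0.0
        assert average_register_shift([mk(3)]) == 3.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_register_shift([])


class TestScanBatch:
    def test_schema_and_values(self, vv_tables):
        df = scan_sequences([("a", "VVVVVVVV"), ("b", "AVLICAVLIC")], vv_tables)
        assert list(df.columns) == [
            "id", "N", "E", "lp", "S",
            "best_k", "best_l", "best_m", "best_n", "best_orientation",
        ]
        row = df.set_index("id").loc["a"]
        assert row.E == -8.0 and row.lp == 8 and row.S == 2.0

    def test_invariants_hold_on_summary(self, vv_tables):
        s = best_pairings("VVVVAVVV", vv_tables, min_lp=4)
        assert s.E == s.top_pairings[0].energy
        energies = [p.energy for p in s.top_pairings]
        assert energies == sorted(energies)
        assert s.S >= 0
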