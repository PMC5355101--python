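import numpy as np
import pytest

from conftest import random_sequence
from oracles import oracle_pse_vector, oracle_tau, oracle_theta

from psekit import (
    BioSequence,
    Molecule,
    PropertyTable,
    PseParams,
    default_property_index,
    extract_features,
    kmer_composition,
    parallel_correlation,
    pse_vector,
    read_property_table,
    series_correlation,
    standardize_properties,
)
from psekit.pseudo_components import PseError, unit_alphabet
from psekit.sequence_io import ALPHABETS, LabeledDataset


class TestStandardization:
    def test_exact_values_for_mean1_sd1_raw_table(self, toy_residue_index):
        # raw {A:0, C:2, G:2, T:0}: mu=1, population sigma=1 by direct computation
        assert toy_residue_index.value("toy", "A") == -1.0
        assert toy_residue_index.value("toy", "C") == 1.0
        assert toy_residue_index.value("toy", "G") == 1.0
        assert toy_residue_index.value("toy", "T") == -1.0

    def test_idempotence(self, toy_residue_index):
        symbols = unit_alphabet(Molecule.DNA, "residue")
        again = standardize_properties(
            PropertyTable(
                Molecule.DNA,
                "residue",
                ("toy",),
                {"toy": {s: toy_residue_index.value("toy", s) for s in symbols}},
            )
        )
        assert np.allclose(again.matrix, toy_residue_index.matrix, atol=1e-12)

    def test_constant_property_is_an_error(self):
        table = PropertyTable(
            Molecule.DNA,
            "residue",
            ("flat",),
            {"flat": {s: 5.0 for s in "ACGT"}},
        )
        with pytest.raises(PseError, match="flat"):
            standardize_properties(table)

    @pytest.mark.parametrize("molecule", list(Molecule))
    def test_shipped_sets_are_mean0_sd1(self, molecule):
        index = default_property_index(molecule)
        assert np.abs(index.matrix.mean(axis=1)).max() <= 1e-10
        assert np.abs(index.matrix.std(axis=1) - 1).max() <= 1e-10

    def test_scale_invariance_of_features(self, toy_residue_index):
        """Rescaling one raw property leaves all feature vectors unchanged."""
        scaled = standardize_properties(
            PropertyTable(
                Molecule.DNA,
                "residue",
                ("toy",),
                {"toy": {"A": 0.0, "C": 74.0, "G": 74.0, "T": 0.0}},
            )
        )
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = random_sequence(rng, Molecule.DNA, int(rng.integers(10, 60)))
            params = PseParams(k=2, lam=3, w=0.5, mode="series")
            a = pse_vector(seq, params, toy_residue_index).values
            b = pse_vector(seq, params, scaled).values
            assert np.allclose(a, b, atol=1e-9)


class TestKmerComposition:
    @pytest.mark.parametrize(
        "residues,k,expected",
        [
            ("ACGA", 1, [0.5, 0.25, 0.25, 0.0]),
            ("AAAAA", 2, [1.0] + [0.0] * 15),
        ],
    )
    def test_counting(self, residues, k, expected):
        seq = BioSequence("x", residues, Molecule.DNA)
        assert np.allclose(kmer_composition(seq, k), expected)

    def test_dimer_counting(self):
        v = kmer_composition(BioSequence("x", "ACGA", Molecule.DNA), 2)
        dimers = unit_alphabet(Molecule.DNA, "dinucleotide")
        nonzero = {d: x for d, x in zip(dimers, v) if x > 0}
        assert nonzero == {"AC": pytest.approx(1 / 3), "CG": pytest.approx(1 / 3),
                           "GA": pytest.approx(1 / 3)}

    def test_too_short_is_an_error(self):
        with pytest.raises(PseError, match="shorter than k"):
            kmer_composition(BioSequence("x", "AC", Molecule.DNA), 3)


class TestCorrelations:
    def test_homopolymer_parallel_factors_are_zero(self, dna_index):
        seq = BioSequence("h", "AAAAAA", Molecule.DNA)
        assert np.allclose(parallel_correlation(seq, dna_index, 3), 0.0)

    def test_parallel_hand_example(self, toy_residue_index):
        # one property, A=-1, G=+1: theta_1 for "AG" = (1-(-1))^2 = 4
        seq = BioSequence("x", "AG", Molecule.DNA)
        assert parallel_correlation(seq, toy_residue_index, 1) == pytest.approx([4.0])

    def test_series_hand_examples(self, toy_residue_index):
        ag = BioSequence("x", "AG", Molecule.DNA)
        gggg = BioSequence("y", "GGGG", Molecule.DNA)
        assert series_correlation(ag, toy_residue_index, 1) == pytest.approx([-1.0])
        assert series_correlation(gggg, toy_residue_index, 1) == pytest.approx([1.0])

    def test_lambda_zero_is_empty(self, dna_index):
        seq = BioSequence("x", "ACGT", Molecule.DNA)
        assert len(parallel_correlation(seq, dna_index, 0)) == 0

    def test_inadmissible_lambda_names_sequence_and_maximum(self, dna_index):
        seq = BioSequence("shorty", "ACGT", Molecule.DNA)  # 3 dinucleotides
        with pytest.raises(PseError, match="shorty") as err:
            parallel_correlation(seq, dna_index, 3)
        assert "maximum lambda is 2" in str(err.value)

    @pytest.mark.parametrize("molecule", list(Molecule))
    @pytest.mark.parametrize("mode", ["parallel", "series"])
    def test_oracle_equivalence(self, molecule, mode):
        """Vectorized factors match a naive double-loop oracle to 1e-10."""
        index = default_property_index(molecule)
        rng = np.random.default_rng(hash((molecule.value, mode)) % 2**31)
        fn = parallel_correlation if mode == "parallel" else series_correlation
        oracle = oracle_theta if mode == "parallel" else oracle_tau
        for case in range(40):
            L = int(rng.integers(10, 50))
            lam = int(rng.integers(1, 6))
            seq = random_sequence(rng, molecule, L, seq_id=f"r{case}")
            got = fn(seq, index, lam)
            want = oracle(seq, index, lam)
            assert np.max(np.abs(got - want)) < 1e-10


class TestPseVector:
    def test_homopolymer_protein_reduces_to_pure_composition(self, protein_index):
        seq = BioSequence("p", "AAAAA", Molecule.PROTEIN)
        v = pse_vector(seq, PseParams(k=1, lam=2, w=0.5), protein_index)
        assert v.dim == 22
        assert v.values[0] == pytest.approx(1.0)
        assert np.allclose(v.values[1:], 0.0)

    def test_lambda_zero_equals_kmer_composition_exactly(self, dna_index):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_sequence(rng, Molecule.DNA, 30)
            v = pse_vector(seq, PseParams(k=2, lam=0, w=0.3), dna_index)
            assert np.array_equal(v.values, kmer_composition(seq, 2))

    @pytest.mark.parametrize("mode", ["parallel", "series"])
    @pytest.mark.parametrize("molecule", list(Molecule))
    def test_sum_to_one_fuzz(self, molecule, mode):
        index = default_property_index(molecule)
        rng = np.random.default_rng(17)
        for _ in range(25):
            L = int(rng.integers(12, 80))
            seq = random_sequence(rng, molecule, L)
            params = PseParams(
                k=int(rng.integers(1, 3)),
                lam=int(rng.integers(0, 6)),
                w=float(rng.uniform(0.05, 1.0)),
                mode=mode,
            )
            try:
                v = pse_vector(seq, params, index)
            except PseError as exc:
                # sum-to-one only applies while 1 + wT > 0; series mode can
                # legitimately fall outside that
                assert mode == "series" and "degenerate" in str(exc)
                continue
            assert abs(v.values.sum() - 1.0) <= 1e-9
            M = len(ALPHABETS[molecule]) ** params.k
            assert (v.values[:M] >= 0).all()

    def test_full_assembly_matches_oracle(self, dna_index):
        seq = BioSequence("x", "ACGTACGT", Molecule.DNA)
        params = PseParams(k=2, lam=2, w=0.1)
        got = pse_vector(seq, params, dna_index).values
        want = oracle_pse_vector(seq, params, dna_index, "ACGT")
        assert got.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_degenerate_series_normalization_is_an_error(self, toy_residue_index):
        # alternating A/G: tau_1 = -1 so 1 + w*T <= 0 for w >= 1
        seq = BioSequence("alt", "AGAGAGAGAG", Molecule.DNA)
        with pytest.raises(PseError, match="degenerate normalization"):
            pse_vector(seq, PseParams(k=1, lam=1, w=2.0, mode="series"),
                       toy_residue_index)


class TestExtractFeatures:
    def _dataset(self, residues_list):
        seqs = [BioSequence(f"s{i}", r, Molecule.DNA)
                for i, r in enumerate(residues_list)]
        labels = [1] * (len(seqs) // 2) + [-1] * (len(seqs) - len(seqs) // 2)
        return LabeledDataset(seqs, np.array(labels), Molecule.DNA)

    def test_rows_follow_dataset_order_and_sum_to_one(self, dna_index):
        ds = self._dataset(["ACGTACGTAC", "CCCCCCCCCC", "ACGTTGCAAG",
                            "GGGGAAAATT", "TTTACGTTTA"])
        X, y = extract_features(ds, PseParams(k=2, lam=2, w=0.5), dna_index)
        assert X.shape == (5, 18)
        assert np.allclose(X.sum(axis=1), 1.0, atol=1e-9)
        assert y.tolist() == ds.labels.tolist()

    def test_order_equivariance(self, dna_index):
        ds = self._dataset(["ACGTACGTAC", "CCCCCCCCCC", "ACGTTGCAAG",
                            "GGGGAAAATT"])
        perm = [2, 0, 3, 1]
        X, _ = extract_features(ds, PseParams(k=1, lam=1, w=0.5), dna_index)
        Xp, _ = extract_features(ds.subset(perm), PseParams(k=1, lam=1, w=0.5),
                                 dna_index)
        assert np.array_equal(Xp, X[perm])

    def test_all_offending_ids_listed(self, dna_index):
        ds = self._dataset(["ACG", "ACGTACGTAC", "ACT", "GGGGAAAATT"])
        with pytest.raises(PseError) as err:
            extract_features(ds, PseParams(k=2, lam=5, w=0.5), dna_index)
        assert "s0" in str(err.value) and "s2" in str(err.value)


class TestPropertyTableFile:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "props.tsv"
        lines = ["symbol\talpha\tbeta"]
        for i, s in enumerate(unit_alphabet(Molecule.DNA, "dinucleotide")):
            lines.append(f"{s}\t{float(i)}\t{float(i % 4)}")
        path.write_text("\n".join(lines) + "\n")
        table = read_property_table(path, Molecule.DNA)
        assert table.names == ("alpha", "beta")
        index = standardize_properties(table)
        assert index.n_properties == 2
        assert np.abs(index.matrix.mean(axis=1)).max() <= 1e-10

    def test_series_dimension_is_lambda_times_Lambda(self, tmp_path, dna_index):
        seq = BioSequence("x", "ACGTACGTACGT", Molecule.DNA)
        tau = series_correlation(seq, dna_index, 3)
        assert len(tau) == 3 * dna_index.n_properties
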