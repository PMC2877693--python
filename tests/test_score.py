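"""Sequence scoring, window scanning, estimability and the gene transform."""

import numpy as np
import pytest

import nnnfit as nf
from nnnfit.score import ParameterTable

# Published inhibition parameters (%) for the 49 independent circular
# 12-mers, reconstructable by circular triplet summation over the reference
# table (printed two-decimal triplet values propagate <= 0.15 rounding).
INDEPENDENT_P = {
    "(ACU)4": 72.1, "(UUG)4": 68.2, "(CG)6": 68.0, "(AACU)3": 61.7,
    "(GGUC)3": 61.0, "(UGC)4": 57.3, "(UUAG)3": 53.6, "(AACG)3": 50.3,
    "(AUC)4": 46.2, "(GGUA)3": 44.7, "(UCC)4": 44.2, "(UUGC)3": 41.2,
    "(AAGC)3": 39.2, "(AGC)4": 37.1, "(CCUG)3": 37.0, "(CCG)4": 36.8,
    "(A)12": 35.7, "(GGAC)3": 34.5, "(ACG)4": 33.3, "(UUCG)3": 30.5,
    "(AAG)4": 29.1, "(UUCA)3": 28.5, "(CGG)4": 27.6, "(G)12": 24.8,
    "(GGCA)3": 22.7, "(AGG)4": 22.4, "(GGAU)3": 19.0, "(AAC)4": 16.0,
    "(AAUC)3": 12.2, "(UGG)4": 11.8, "(U)12": 9.7, "(ACC)4": 8.5,
    "(GGCU)3": 7.3, "(AG)6": 6.2, "(UUAC)3": 5.8, "(UCG)4": 5.6,
    "(AUG)4": 4.2, "(AUU)4": 3.2, "(CCAG)3": 0.4, "(UG)6": -9.9,
    "(AU)6": -10.6, "(AAUG)3": -11.3, "(AGU)4": -11.8, "(UC)6": -19.4,
    "(AAU)4": -22.8, "(AC)6": -31.8, "(UUC)4": -36.1, "(C)12": -44.8,
    "(AAGU)3": -46.0,
}


def circ(s, id=""):
    return nf.NucleotideSequence(s, topology="circular", id=id)


def zero_table():
    return ParameterTable(triplet_params={t: 0.0 for t in nf.TRIPLETS})


class TestScoreSequence:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ACUACUACUACU", 72.1), ("GGGAGGGAGGGA", 23.0), ("GGGAUCGGGAUC", 46.8)],
    )
    def test_worked_examples(self, ref_table, seq, expected):
        assert nf.score_sequence(ref_table, circ(seq)).P == pytest.approx(
            expected, abs=0.15)

    def test_reconstructs_all_49_independent_parameters(self, ref_table, independent_seqs):
        for seq in independent_seqs:
            got = nf.score_sequence(ref_table, seq).P
            assert got == pytest.approx(INDEPENDENT_P[seq.id], abs=0.15), seq.id

    def test_zero_table_scores_zero(self):
        assert nf.score_sequence(zero_table(), circ("ACGUACGUACGU")).P == 0.0

    def test_covariate_offsets_added_when_labels_given(self, ref_table):
        base = nf.score_sequence(ref_table, circ("ACUACUACUACU")).P
        with_cov = nf.score_sequence(ref_table, circ("ACUACUACUACU"),
                                     cell="A549", gene="BCL2").P
        assert with_cov == pytest.approx(base + 10.59 - 3.10)
        with pytest.raises(KeyError):
            nf.score_sequence(ref_table, circ("ACU"), cell="HELA")

    def test_rotation_invariance(self, ref_table):
        s = "GGGAUCCAUGCA"
        scores = {nf.score_sequence(ref_table, circ(s[i:] + s[:i])).P
                  for i in range(len(s))}
        assert len({round(v, 9) for v in scores}) == 1

    def test_linearity_in_the_parameter_table(self, ref_table):
        rng = np.random.default_rng(3)
        other = ParameterTable(
            triplet_params={t: float(v) for t, v in
                            zip(nf.TRIPLETS, rng.normal(size=64))})
        summed = ParameterTable(
            triplet_params={t: ref_table.triplet_params[t] + other.triplet_params[t]
                            for t in nf.TRIPLETS})
        seq = circ("CAUGGAUCCAUG")
        assert nf.score_sequence(summed, seq).P == pytest.approx(
            nf.score_sequence(ref_table, seq).P + nf.score_sequence(other, seq).P)

    def test_dependent_sequence_equals_its_linear_combination(self, ref_table):
        # (GGGA)3 = 1/4 (G)12 + 3/4 (AGG)4 in triplet count space
        p_dep = nf.score_sequence(ref_table, circ("GGGAGGGAGGGA")).P
        p_g12 = nf.score_sequence(ref_table, circ("G" * 12)).P
        p_agg = nf.score_sequence(ref_table, circ("AGGAGGAGGAGG")).P
        assert p_dep == pytest.approx(0.25 * p_g12 + 0.75 * p_agg, abs=1e-9)

    def test_naive_se_is_root_sum_of_squares(self, ref_table):
        res = nf.score_sequence(ref_table, circ("ACUACUACUACU"), naive_se=True)
        expected = np.sqrt(sum((4 * ref_table.triplet_se[t]) ** 2
                               for t in ("ACU", "CUA", "UAC")))
        assert res.se_kind == "naive"
        assert res.SE == pytest.approx(expected)

    def test_covariance_se_used_when_available(self, sim_fit):
        table = ParameterTable.from_fit(sim_fit)
        res = nf.score_sequence(table, circ("A" * 12))
        assert res.se_kind == "covariance"
        w = np.zeros(len(sim_fit.column_names))
        w[sim_fit.column_names.index("AAA")] = 12.0
        assert res.SE == pytest.approx(nf.propagate_error(sim_fit, w))


class TestScanWindows:
    def test_top_window_is_the_high_scoring_block(self, ref_table):
        mrna = nf.NucleotideSequence("ACU" * 4 + "C" * 12, topology="linear", id="m")
        ranked = nf.scan_windows(ref_table, mrna, window=12)
        start, sub, res = ranked[0]
        assert (start, sub.residues) == (0, "ACUACUACUACU")
        assert res.P == pytest.approx(72.1, abs=0.15)
        # exhaustive oracle: every window scored directly, same ranking
        oracle = sorted(
            ((-nf.score_sequence(ref_table, circ(mrna.residues[i:i + 12])).P, i)
             for i in range(len(mrna) - 11)))
        assert [i for _, i in oracle] == [s for s, _, _ in ranked]

    def test_window_equal_to_length_matches_direct_score(self, ref_table):
        mrna = nf.NucleotideSequence("GGGAUCCAUGCA", topology="linear")
        ((start, sub, res),) = nf.scan_windows(ref_table, mrna, window=12)
        assert start == 0
        assert res.P == pytest.approx(
            nf.score_sequence(ref_table, circ(mrna.residues)).P)

    def test_ties_broken_by_start_coordinate(self):
        mrna = nf.NucleotideSequence("AAAAAAAA", topology="linear")
        ranked = nf.scan_windows(zero_table(), mrna, window=4)
        assert [s for s, _, _ in ranked] == [0, 1, 2, 3, 4]

    def test_window_longer_than_sequence_rejected(self, ref_table):
        with pytest.raises(ValueError):
            nf.scan_windows(ref_table, nf.NucleotideSequence("ACGU", topology="linear"),
                            window=12)


class TestIndependence:
    def test_published_49_sequence_set_is_independent(self, independent_seqs):
        report = nf.check_independence(independent_seqs)
        assert report.rank == 49 and report.independent
        assert report.n_rows == 64

    def test_adding_dependent_sequence_is_detected_with_dependency(self, independent_seqs):
        report = nf.check_independence(
            independent_seqs + [circ("GGGAGGGAGGGA", id="(GGGA)3")])
        assert report.rank == 49 and not report.independent
        dep = report.dependency
        scale = -dep["(GGGA)3"]
        assert dep["(G)12"] / scale == pytest.approx(0.25, abs=1e-8)
        assert dep["(AGG)4"] / scale == pytest.approx(0.75, abs=1e-8)
        assert set(dep) == {"(GGGA)3", "(G)12", "(AGG)4"}

    def test_single_sequence_is_independent(self):
        assert nf.check_independence([circ("ACGUACGUACGU")]).independent


class TestEstimability:
    def test_homotriplets_estimable_without_gene_block(self, sim_experiments):
        # with triplet counts + cell column only, the null space is exactly
        # the 15 flow-balance constraints, so homotriplets and cell are
        # uniquely determined while generic triplets are not
        dm = nf.build_design(sim_experiments, gene_covariate=False)
        k = dm.shape[1]

        def unit(name):
            w = np.zeros(k)
            w[dm.column_names.index(name)] = 1.0
            return w

        for name in ("AAA", "CCC", "GGG", "UUU", "cell:A549"):
            assert nf.is_estimable(dm, unit(name)), name
        assert not nf.is_estimable(dm, unit("ACU"))
        assert nf.is_estimable(dm, np.zeros(k))

    def test_gene_block_adds_constant_shift_ambiguity(self, sim_experiments):
        # gene indicators sum to 1 while 20-mer counts sum to 20: the design
        # gains one more dependency, so single triplets (even homotriplets)
        # and single gene indicators lose estimability; gene differences and
        # the cell column keep it
        dm = nf.build_design(sim_experiments)
        k = dm.shape[1]

        def unit(name):
            w = np.zeros(k)
            w[dm.column_names.index(name)] = 1.0
            return w

        assert nf.is_estimable(dm, unit("cell:A549"))
        assert not nf.is_estimable(dm, unit("AAA"))
        assert not nf.is_estimable(dm, unit("gene:BCL2"))
        assert nf.is_estimable(dm, unit("gene:BCL2") - unit("gene:CRAF1"))
        # gene-minus-average is estimable, matching the published transform
        gene_cols = [n for n in dm.column_names if n.startswith("gene:")]
        w = unit("gene:BCL2") - sum(unit(g) for g in gene_cols) / len(gene_cols)
        assert nf.is_estimable(dm, w)
        # the ambiguity direction itself: +1 on every triplet, -L on genes
        ambig = np.zeros(k)
        ambig[:64] = 1.0
        for g in gene_cols:
            ambig[dm.column_names.index(g)] = -20.0
        assert not nf.is_estimable(dm, ambig)
        np.testing.assert_allclose(dm.unweighted() @ ambig, 0.0, atol=1e-9)

    def test_count_space_estimability_matches_constraint_null_space(self):
        space = nf.circular_count_space("triplet")
        e_aaa = np.zeros(64)
        e_aaa[nf.TRIPLETS.index("AAA")] = 1.0
        assert nf.is_estimable(space, e_aaa)
        e_acu = np.zeros(64)
        e_acu[nf.TRIPLETS.index("ACU")] = 1.0
        assert not nf.is_estimable(space, e_acu)

    def test_dimension_mismatch_rejected(self, sim_experiments):
        dm = nf.build_design(sim_experiments)
        with pytest.raises(ValueError):
            nf.is_estimable(dm, np.zeros(5))


class TestGeneMinusAverage:
    def test_reference_gene_offsets(self, ref_table):
        offsets = nf.gene_minus_average(ref_table)
        assert offsets["BCL2"][0] == pytest.approx(-4.54, abs=0.01)
        assert offsets["CRAF1"][0] == pytest.approx(2.20, abs=0.01)
        assert offsets["AKT2"][0] == pytest.approx(7.53, abs=0.01)
        assert offsets["PKCA"][0] == pytest.approx(-5.20, abs=0.01)
        assert sum(v for v, _ in offsets.values()) == pytest.approx(0.0, abs=1e-10)

    def test_equal_parameters_give_zero_offsets(self):
        table = ParameterTable(
            triplet_params={t: 0.0 for t in nf.TRIPLETS},
            covariate_params={"gene:X": 5.0, "gene:Y": 5.0})
        assert all(v == pytest.approx(0.0) for v, _ in
                   nf.gene_minus_average(table).values())

    def test_offsets_center_random_inputs(self):
        rng = np.random.default_rng(9)
        table = ParameterTable(
            triplet_params={t: 0.0 for t in nf.TRIPLETS},
            covariate_params={f"gene:G{i}": float(v)
                              for i, v in enumerate(rng.normal(size=5))})
        assert sum(v for v, _ in nf.gene_minus_average(table).values()) == \
            pytest.approx(0.0, abs=1e-10)

    def test_ses_propagated_when_covariance_present(self, sim_fit):
        table = ParameterTable.from_fit(sim_fit)
        offsets = nf.gene_minus_average(table)
        assert all(se is not None and se > 0 for _, se in offsets.values())

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            nf.gene_minus_average(zero_table())


class TestNNFreeEnergy:
    def test_uniform_table_counts_length(self):
        table = {d: -1.0 for d in nf.DOUBLETS}
        assert nf.nn_free_energy(circ("ACGU" * 5), table) == pytest.approx(-20.0)
        assert nf.nn_free_energy(circ("ACGU" * 5), {d: 0.0 for d in nf.DOUBLETS}) == 0.0

    def test_matches_positional_oracle_on_random_sequences(self):
        rng = np.random.default_rng(21)
        table = {d: float(v) for d, v in zip(nf.DOUBLETS, rng.normal(size=16))}
        for _ in range(20):
            s = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 30))))
            brute = sum(table[(s + s[0])[i:i + 2]] for i in range(len(s)))
            assert nf.nn_free_energy(circ(s), table) == pytest.approx(brute)

    def test_incomplete_table_rejected(self):
        table = {d: -1.0 for d in nf.DOUBLETS if d != "GU"}
        with pytest.raises(KeyError, match="GU"):
            nf.nn_free_energy(circ("ACGU"), table)


class TestParameterTableIO:
    def test_table_requires_all_64_triplets(self):
        with pytest.raises(ValueError):
            ParameterTable(triplet_params={"AAA": 1.0})

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            ParameterTable(triplet_params={t: 0.0 for t in nf.TRIPLETS},
                           triplet_se={"AAA": -1.0})

    def test_save_load_round_trip_with_covariance(self, tmp_path, sim_fit):
        table = ParameterTable.from_fit(sim_fit, provenance="sim fit")
        path = tmp_path / "table.params"
        nf.save_parameter_table(table, path)
        again = nf.load_parameter_table(path)
        for t in nf.TRIPLETS:
            assert again.triplet_params[t] == pytest.approx(
                table.triplet_params[t], rel=1e-11)
        assert again.covariate_params.keys() == table.covariate_params.keys()
        np.testing.assert_allclose(again.covariance, table.covariance,
                                   rtol=1e-9, atol=1e-15)
        seq = circ("GGGAUCCAUGCA")
        assert nf.score_sequence(again, seq).SE == pytest.approx(
            nf.score_sequence(table, seq).SE, rel=1e-9)
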