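import numpy as np
import pytest
from hypothesis import given, strategies as st

from famqls import (
    Individual,
    KinshipNumericalError,
    Pedigree,
    PedigreeParseError,
    PedigreeValidationError,
    Sex,
    compute_kinship,
    read_pedigree,
    three_generation_pedigree,
    write_fam,
)


def _write(tmp_path, text, name="ped.fam"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPedigree:
    def test_minimal_trio(self, tmp_path):
        ped = read_pedigree(
            _write(tmp_path, "F1 A 0 0 1\nF1 B 0 0 2\nF1 C A B 1\n")
        )
        assert len(ped) == 3
        assert [i.person_id for i in ped.founders()] == ["A", "B"]
        assert not ped[ped.row("F1", "C")].is_founder

    def test_unknown_parent_is_validation_error(self, tmp_path):
        with pytest.raises(PedigreeValidationError, match="unknown parent X"):
            read_pedigree(_write(tmp_path, "F1 A 0 0 1\nF1 B 0 0 2\nF1 C A X 1\n"))

    def test_children_may_precede_parents(self, tmp_path):
        ped = read_pedigree(
            _write(tmp_path, "F1 C A B 1\nF1 A 0 0 1\nF1 B 0 0 2\n")
        )
        assert [i.person_id for i in ped] == ["C", "A", "B"]  # file order kept

    def test_duplicate_individual_names_line(self, tmp_path):
        with pytest.raises(PedigreeParseError, match="line 1"):
            read_pedigree(_write(tmp_path, "F1 A 0 0 1\nF1 A 0 0 2\n"))

    def test_short_line_rejected(self, tmp_path):
        with pytest.raises(PedigreeParseError, match="5 columns"):
            read_pedigree(_write(tmp_path, "F1 A 0 0\n"))

    def test_single_recorded_parent_rejected(self, tmp_path):
        with pytest.raises(PedigreeValidationError, match="exactly one"):
            read_pedigree(_write(tmp_path, "F1 B 0 0 2\nF1 C 0 B 1\n"))

    def test_cycle_detected(self):
        with pytest.raises(PedigreeValidationError, match="cycle"):
            Pedigree(
                [
                    Individual("F1", "M", sex=Sex.FEMALE),
                    Individual("F1", "A", "B", "M"),
                    Individual("F1", "B", "A", "M"),
                ]
            )

    def test_fam_round_trip(self, tmp_path, trio):
        out = tmp_path / "out.fam"
        write_fam(trio, out)
        again = read_pedigree(out)
        assert [i.key for i in again] == [i.key for i in trio]
        assert [i.sex for i in again] == [i.sex for i in trio]


def _pedigree_with_relations() -> Pedigree:
    # founders A,B; full sibs C,D; E marries C (founder), their child F;
    # G marries D, child H; F x H are first cousins, their child I is inbred.
    # Half sibs: J shares father A with C (different mother K).
    return Pedigree(
        [
            Individual("F1", "A", sex=Sex.MALE),
            Individual("F1", "B", sex=Sex.FEMALE),
            Individual("F1", "K", sex=Sex.FEMALE),
            Individual("F1", "C", "A", "B", Sex.MALE),
            Individual("F1", "D", "A", "B", Sex.FEMALE),
            Individual("F1", "J", "A", "K", Sex.MALE),
            Individual("F1", "E", sex=Sex.FEMALE),
            Individual("F1", "G", sex=Sex.MALE),
            Individual("F1", "F", "C", "E", Sex.MALE),
            Individual("F1", "H", "G", "D", Sex.FEMALE),
            Individual("F1", "I", "F", "H", Sex.MALE),
        ]
    )


class TestKinship:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("A", "C"), 0.25),   # parent-offspring
            (("C", "D"), 0.25),   # full siblings
            (("C", "J"), 0.125),  # half siblings
            (("F", "H"), 0.0625), # first cousins
            (("A", "E"), 0.0),    # unrelated founders
            (("A", "I"), 0.125),  # great-grandparent via two lines
        ],
    )
    def test_classic_coefficients(self, pair, expected):
        ped = _pedigree_with_relations()
        kin = compute_kinship(ped)
        d = kin.dense()
        i, j = (ped.row("F1", p) for p in pair)
        assert d[i, j] == pytest.approx(expected, abs=1e-15)

    def test_full_sib_mating_offspring_diagonal(self):
        ped = Pedigree(
            [
                Individual("F1", "A", sex=Sex.MALE),
                Individual("F1", "B", sex=Sex.FEMALE),
                Individual("F1", "C", "A", "B", Sex.MALE),
                Individual("F1", "D", "A", "B", Sex.FEMALE),
                Individual("F1", "X", "C", "D"),
            ]
        )
        kin = compute_kinship(ped)
        x = ped.row("F1", "X")
        assert kin.dense()[x, x] == pytest.approx(0.625)
        assert kin.inbreeding()[x] == pytest.approx(0.25)

    def test_row_order_invariance(self):
        ped = _pedigree_with_relations()
        base = compute_kinship(ped).dense()
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(ped.individuals))
            shuffled = Pedigree([ped.individuals[i] for i in perm])
            d = compute_kinship(shuffled).dense()
            assert np.allclose(d, base[np.ix_(perm, perm)])

    def test_cross_family_kinship_is_zero_and_blocks_factor(self):
        ped = three_generation_pedigree(3, 3)
        kin = compute_kinship(ped)
        kin.assert_positive_definite()
        d = kin.dense()
        for fid_a in ped.family_ids:
            for fid_b in ped.family_ids:
                if fid_a == fid_b:
                    continue
                block = d[np.ix_(ped.family_rows(fid_a), ped.family_rows(fid_b))]
                assert not block.any()

    def test_pairwise_bounds(self):
        kin = compute_kinship(three_generation_pedigree(2, 4))
        d = kin.dense()
        diag = np.diag(d)
        assert (diag >= 0.5).all()
        off = d - np.diag(diag)
        assert (off >= 0).all()
        assert (off <= np.maximum.outer(diag, diag)).all()

    def test_singular_matrix_names_family(self):
        from famqls import KinshipMatrix

        bad = KinshipMatrix.from_dense(np.zeros((2, 2)), family_id="FBAD")
        with pytest.raises(KinshipNumericalError, match="FBAD"):
            bad.assert_positive_definite()

    @given(st.permutations(list(range(11))))
    def test_permutation_property(self, perm):
        ped = _pedigree_with_relations()
        base = compute_kinship(ped).dense()
        shuffled = Pedigree([ped.individuals[i] for i in perm])
        d = compute_kinship(shuffled).dense()
        assert np.allclose(d, base[np.ix_(perm, perm)])


class TestFounders:
    def test_trio(self, trio):
        assert [i.person_id for i in trio.founders()] == ["A", "B"]

    def test_all_founders(self):
        ped = Pedigree([Individual("F1", str(i)) for i in range(5)])
        assert len(ped.founders()) == 5

    def test_empty(self):
        assert Pedigree([]).founders() == []


def _mc_kinship(ped: Pedigree, n_drops: int, rng) -> np.ndarray:
    """Independent brute-force oracle: estimate every pairwise kinship as the
    probability that one randomly drawn allele from each individual is IBD,
    by dropping uniquely labelled founder alleles through the pedigree."""
    n = len(ped.individuals)
    labels = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_label = 1
    for row, ind in enumerate(ped.individuals):
        if ind.is_founder:
            labels[:, row, 0] = next_label
            labels[:, row, 1] = next_label + 1
            next_label += 2
    for row in ped.topological_order():
        parents = ped.parent_rows(row)
        if parents is None:
            continue
        fa, mo = parents
        pick_f = rng.integers(0, 2, n_drops)
        pick_m = rng.integers(0, 2, n_drops)
        labels[:, row, 0] = labels[np.arange(n_drops), fa, pick_f]
        labels[:, row, 1] = labels[np.arange(n_drops), mo, pick_m]
    # kinship = average over the 4 allele pairings of P(IBD)
    est = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eq = labels[:, i, :, None] == labels[:, j, None, :]
            est[i, j] = eq.mean()
    return est


def test_kinship_matches_gene_drop_oracle():
    """Monte-Carlo IBD sharing over 1e5 drops agrees with the recursion."""
    ped = _pedigree_with_relations()
    kin = compute_kinship(ped).dense()
    n_drops = 100_000
    est = _mc_kinship(ped, n_drops, np.random.default_rng(2024))
    # binomial SE per pairing average; conservative bound with phi(1-phi)
    for i in range(len(ped.individuals)):
        for j in range(len(ped.individuals)):
            if i == j:
                continue
            phi = kin[i, j]
            se = np.sqrt(max(phi * (1 - phi), 1e-4) / n_drops) * 2
            assert abs(est[i, j] - phi) < 3 * se + 1e-3, (i, j)
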