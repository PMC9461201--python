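"""Paired-TCR pairing, clonotype calling and clonality statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fimbria import tcr
from fimbria.io import TcrChainRecord
from fimbria.qc import lognormalize
from fimbria.synthetic import CohortConfig, generate_cohort

from conftest import small_cohort_config, toy_matrix


def _chain(barcode, chain="TRA", cdr3="CAVF", cdr3_nt="TGTGCA", umis=5,
           productive=True, full_length=True, is_cell=True, v="TRAV1", j="TRAJ1"):
    return TcrChainRecord(barcode, chain, v, j, cdr3, cdr3_nt, umis, productive,
                          full_length, is_cell)


class TestSelectPairedCells:
    def test_basic_pair(self):
        chains = [_chain("bc1", "TRA"), _chain("bc1", "TRB", cdr3="CASF")]
        out = tcr.select_paired_cells(chains)
        assert len(out) == 1
        assert out.loc[0, "tra_cdr3_aa"] == "CAVF"
        assert out.loc[0, "trb_cdr3_aa"] == "CASF"

    def test_highest_umi_chain_kept(self):
        """Two TRA chains with UMIs 7 and 3: the 7-UMI chain wins."""
        chains = [
            _chain("bc1", "TRA", cdr3="CLOW", umis=3),
            _chain("bc1", "TRA", cdr3="CHIGH", umis=7),
            _chain("bc1", "TRB", cdr3="CASF"),
        ]
        out = tcr.select_paired_cells(chains)
        assert out.loc[0, "tra_cdr3_aa"] == "CHIGH"
        assert out.loc[0, "tra_umis"] == 7

    def test_umi_tie_broken_by_cdr3_nt(self):
        chains = [
            _chain("bc1", "TRA", cdr3="CB", cdr3_nt="TGTB", umis=5),
            _chain("bc1", "TRA", cdr3="CA", cdr3_nt="TGTA", umis=5),
            _chain("bc1", "TRB"),
        ]
        out = tcr.select_paired_cells(chains)
        assert out.loc[0, "tra_cdr3_nt"] == "TGTA"

    @pytest.mark.parametrize(
        "kwargs", [{"productive": False}, {"full_length": False}, {"is_cell": False}]
    )
    def test_filtered_chain_breaks_pair(self, kwargs):
        chains = [_chain("bc1", "TRA", **kwargs), _chain("bc1", "TRB")]
        assert tcr.select_paired_cells(chains).empty

    def test_other_chain_ignored(self):
        chains = [_chain("bc1", "other"), _chain("bc1", "TRB")]
        assert tcr.select_paired_cells(chains).empty

    def test_single_locus_cell_excluded(self):
        chains = [_chain("bc1", "TRA"), _chain("bc2", "TRA"), _chain("bc2", "TRB")]
        out = tcr.select_paired_cells(chains)
        assert out["barcode"].tolist() == ["bc2"]

    def test_output_order_independent_of_input_order(self):
        chains = [
            _chain("bcB", "TRA"), _chain("bcB", "TRB"),
            _chain("bcA", "TRA"), _chain("bcA", "TRB"),
        ]
        for perm in itertools.permutations(range(4)):
            out = tcr.select_paired_cells([chains[i] for i in perm])
            assert out["barcode"].tolist() == ["bcA", "bcB"]


def _paired_frame(keys):
    """Paired-cell frame with given (tra_aa, trb_aa) identities."""
    rows = []
    for i, (a, b) in enumerate(keys):
        rows.append(
            {
                "barcode": f"bc{i}",
                "tra_v": "TRAV1", "tra_j": "TRAJ1",
                "tra_cdr3_aa": a, "tra_cdr3_nt": "TGT" + a, "tra_umis": 5,
                "trb_v": "TRBV1", "trb_j": "TRBJ1",
                "trb_cdr3_aa": b, "trb_cdr3_nt": "TGT" + b, "trb_umis": 5,
            }
        )
    return pd.DataFrame(rows)


class TestAssignClonotypes:
    def test_sizes_and_flags(self):
        out = tcr.assign_clonotypes(_paired_frame([("A", "X"), ("A", "X"), ("B", "Y")]))
        assert out["clone_size"].tolist() == [2, 2, 1]
        assert out["clonal"].tolist() == [True, True, False]
        assert out.loc[0, "clonotype_id"] == out.loc[1, "clonotype_id"]
        assert out.loc[0, "clonotype_id"] != out.loc[2, "clonotype_id"]

    def test_same_tra_different_trb_distinct(self):
        out = tcr.assign_clonotypes(_paired_frame([("A", "X"), ("A", "Y")]))
        assert not out["clonal"].any()

    def test_row_order_invariance(self):
        frame = _paired_frame([("A", "X"), ("B", "Y"), ("A", "X"), ("C", "Z")])
        base = tcr.assign_clonotypes(frame).set_index("barcode")
        perm = tcr.assign_clonotypes(frame.iloc[[3, 1, 0, 2]].reset_index(drop=True))
        perm = perm.set_index("barcode")
        for bc in base.index:
            assert base.loc[bc, "clonotype_id"] == perm.loc[bc, "clonotype_id"]
            assert base.loc[bc, "clone_size"] == perm.loc[bc, "clone_size"]

    def test_nt_key_splits_synonymous(self):
        frame = _paired_frame([("A", "X"), ("A", "X")])
        frame.loc[1, "tra_cdr3_nt"] = "TGCA"  # same aa, different nt
        aa = tcr.assign_clonotypes(frame, key="cdr3_aa")
        nt = tcr.assign_clonotypes(frame, key="cdr3_nt")
        assert aa["clonal"].all()
        assert not nt["clonal"].any()

    def test_v_gene_key_splits(self):
        frame = _paired_frame([("A", "X"), ("A", "X")])
        frame.loc[1, "tra_v"] = "TRAV9"
        out = tcr.assign_clonotypes(frame, key="v_cdr3_aa")
        assert not out["clonal"].any()

    def test_unknown_key(self):
        with pytest.raises(ValueError, match="unknown"):
            tcr.assign_clonotypes(_paired_frame([("A", "X")]), key="nope")


class TestClonalityContingency:
    def test_hand_counts_and_percentages(self):
        """672/242 clonal/non-clonal carriers vs 337/210 controls."""
        flags = np.array([True] * 672 + [False] * 242 + [True] * 337 + [False] * 210)
        groups = np.array(["carrier"] * 914 + ["control"] * 547, dtype=object)
        out = tcr.clonality_contingency(flags, groups)
        assert out["table"].tolist() == [[672, 337], [242, 210]]
        assert out["clonal_percent"]["carrier"] == pytest.approx(73.5, abs=0.05)
        assert out["clonal_percent"]["control"] == pytest.approx(61.6, abs=0.05)

    def test_p_matches_yates_formula(self):
        flags = np.array([True] * 30 + [False] * 20 + [True] * 10 + [False] * 40)
        groups = np.array(["carrier"] * 50 + ["control"] * 50, dtype=object)
        out = tcr.clonality_contingency(flags, groups)
        table = np.array([[30, 10], [20, 40]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((np.abs(table - expected) - 0.5) ** 2 / expected).sum()
        assert out["chi2"] == pytest.approx(chi2, abs=1e-10)
        assert out["p"] == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tcr.clonality_contingency(
                np.array([True, False]), np.array(["carrier", "carrier"], dtype=object)
            )

    def test_percent_helper(self):
        assert tcr.clonal_percentages(672, 242) == pytest.approx(100 * 672 / 914)


class TestWilcoxon:
    def _matrix(self, values):
        import scipy.sparse as sp

        return sp.csr_matrix(np.array([values], dtype=float)), ["M"]

    def test_exact_small_sample(self):
        """x={1,2} all below y={3,4}: exact two-sided p = 2/C(4,2) = 1/3."""
        norm, syms = self._matrix([1.0, 2.0, 3.0, 4.0])
        p = tcr.wilcoxon_marker(norm, syms, np.array([0, 1]), np.array([2, 3]), "M")
        assert p == pytest.approx(1 / 3)

    def test_matches_enumeration_oracle(self):
        """Exact p agrees with brute-force enumeration of group assignments."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=9)
        a_idx, b_idx = np.arange(4), np.arange(4, 9)
        norm, syms = self._matrix(values)
        p = tcr.wilcoxon_marker(norm, syms, a_idx, b_idx, "M")
        ranks = stats.rankdata(values)
        u_obs = ranks[a_idx].sum() - 4 * 5 / 2
        n_extreme = 0
        combos = list(itertools.combinations(range(9), 4))
        for combo in combos:
            u = ranks[list(combo)].sum() - 4 * 5 / 2
            if abs(u - 10) >= abs(u_obs - 10) - 1e-12:  # |U - n1*n2/2| two-sided
                n_extreme += 1
        assert p == pytest.approx(n_extreme / len(combos), abs=1e-12)

    def test_identical_distributions_large_p(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=200)
        norm, syms = self._matrix(values)
        p = tcr.wilcoxon_marker(norm, syms, np.arange(100), np.arange(100, 200), "M")
        assert p > 0.01

    def test_boolean_masks_accepted(self):
        norm, syms = self._matrix([1.0, 2.0, 3.0, 4.0])
        a = np.array([True, True, False, False])
        p1 = tcr.wilcoxon_marker(norm, syms, a, ~a, "M")
        p2 = tcr.wilcoxon_marker(norm, syms, np.array([0, 1]), np.array([2, 3]), "M")
        assert p1 == p2

    def test_missing_marker(self):
        norm, syms = self._matrix([1.0, 2.0])
        with pytest.raises(KeyError, match="NOPE"):
            tcr.wilcoxon_marker(norm, syms, np.array([0]), np.array([1]), "NOPE")

    def test_empty_set_rejected(self):
        norm, syms = self._matrix([1.0, 2.0])
        with pytest.raises(ValueError, match="non-empty"):
            tcr.wilcoxon_marker(norm, syms, np.array([], dtype=int), np.array([1]), "M")


class TestCd8Mask:
    def test_gating_rule(self):
        m = toy_matrix(
            [[1, 0, 1, 0], [0, 0, 1, 0]], symbols=["CD8A", "CD4"]
        )
        t_mask = np.array([True, True, True, False])
        out = tcr.cd8_mask(m, t_mask)
        # cell0: CD8A+, CD4- -> CD8; cell2: double positive -> excluded;
        # cell3: not a T cell
        assert out.tolist() == [True, False, False, False]

    def test_missing_gene(self):
        m = toy_matrix([[1]], symbols=["CD8A"])
        with pytest.raises(ValueError, match="CD4"):
            tcr.cd8_mask(m, np.array([True]))


@pytest.fixture(scope="module")
def cohort():
    matrix, contigs, truth = generate_cohort(small_cohort_config(cells_per_sample=400), seed=17)
    paired = tcr.select_paired_cells(contigs)
    clonotypes = tcr.assign_clonotypes(paired)
    return matrix, contigs, truth, clonotypes


class TestEndToEndOnSyntheticCohort:
    def test_conservation_invariants(self, cohort):
        matrix, contigs, truth, clonotypes = cohort
        # clone sizes sum to the number of paired cells
        per_clone = clonotypes.drop_duplicates("clonotype_id")
        assert per_clone["clone_size"].sum() == len(clonotypes)
        # every paired barcode exists in the cohort and is a T cell
        t_barcodes = set(truth[truth["major_type"] == "T"]["barcode"])
        assert set(clonotypes["barcode"]) <= t_barcodes

    def test_planted_clonality_recovered(self, cohort):
        matrix, contigs, truth, clonotypes = cohort
        planted = truth.set_index("barcode")["planted_clonal"]
        called = clonotypes.set_index("barcode")["clonal"]
        joined = pd.concat([planted[called.index], called], axis=1)
        assert (joined["planted_clonal"] == joined["clonal"]).mean() == 1.0

    def test_group_difference_detected(self, cohort):
        matrix, contigs, truth, clonotypes = cohort
        group = truth.set_index("barcode")["group"]
        cd8 = truth.set_index("barcode")["is_cd8"]
        sub = clonotypes[cd8[clonotypes["barcode"]].to_numpy()]
        out = tcr.clonality_contingency(
            sub["clonal"].to_numpy(), group[sub["barcode"]].to_numpy()
        )
        assert out["clonal_percent"]["carrier"] > out["clonal_percent"]["control"]

    def test_exhaustion_pd1_signal(self, cohort):
        """PDCD1 is planted higher in clonal cells: the Wilcoxon column
        flags it while preserving one row per present marker."""
        matrix, contigs, truth, clonotypes = cohort
        norm = lognormalize(matrix)
        t_mask = np.isin(matrix.barcodes, list(clonotypes["barcode"]))
        cd8 = tcr.cd8_mask(matrix, t_mask)
        out = tcr.exhaustion_analysis(matrix, norm, clonotypes, cell_mask=cd8)
        out = out.set_index("marker")
        assert out.loc["PDCD1", "p_clonal_vs_nonclonal"] < 0.01
        assert set(out.index) == {"PDCD1", "HAVCR2", "LAG3", "CTLA4", "TOX", "ENTPD1"}
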