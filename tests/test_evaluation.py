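"""Evaluation metrics against brute-force and library oracles."""

import itertools

import numpy as np
import pytest

from rawrphylo.evaluation import (
    aggregate_pr_auc,
    anhd,
    confusion_at_threshold,
    gappiness,
    nrf_distance,
    pr_curve,
    sp_errors,
)
from rawrphylo.io_formats import Alignment, parse_newick
from rawrphylo.support import SupportMap, nontrivial_bipartitions


def _sixtree(newick="((a,b),(c,d),(e,f));"):
    return parse_newick(newick)


def _support_for(tree, values):
    """Assign given support values to the tree's bipartitions, ordered by
    sorted canonical side for determinism."""
    bips = sorted(nontrivial_bipartitions(tree), key=lambda b: sorted(b))
    assert len(bips) == len(values)
    return SupportMap(dict(zip(bips, values)), n_replicates=100)


class TestConfusion:
    def test_direct_classification(self):
        est = _sixtree()  # canonical splits, sorted: cd | cdef (=ab|rest) | ef
        ref = _sixtree("((a,b),(c,e),(d,f));")  # shares only ab|cdef
        bips = sorted(nontrivial_bipartitions(est), key=lambda b: sorted(b))
        sup = SupportMap(
            {b: v for b, v in zip(bips, [0.4, 0.9, 0.4])}, 10
        )  # the in-ref split gets 0.9; the two absent ones get 0.4
        c = confusion_at_threshold(est, sup, ref, 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 2)

    def test_threshold_zero_all_positive(self):
        est, ref = _sixtree(), _sixtree("((a,b),(c,e),(d,f));")
        sup = _support_for(est, [0.2, 0.6, 0.9])
        c = confusion_at_threshold(est, sup, ref, 0.0)
        assert c.fn == 0 and c.tn == 0

    def test_est_equals_ref_no_negative_truth(self):
        est = _sixtree()
        sup = _support_for(est, [0.1, 0.5, 0.9])
        for thr in (0.0, 0.5, 1.1):
            c = confusion_at_threshold(est, sup, est, thr)
            assert c.fp == 0 and c.tn == 0

    def test_counts_sum_to_bipartition_count(self):
        est, ref = _sixtree(), _sixtree("((a,c),(b,d),(e,f));")
        sup = _support_for(est, [0.3, 0.7, 1.0])
        for thr in np.linspace(0, 1.2, 13):
            assert confusion_at_threshold(est, sup, ref, thr).total == 3


class TestPRCurve:
    def test_perfect_separation_auc_one(self):
        est = _sixtree()
        ref = _sixtree()
        sup = _support_for(est, [0.9, 0.8, 0.7])
        assert pr_curve(est, sup, ref).auc == pytest.approx(1.0)

    def test_all_supports_equal_half_in_ref(self):
        est = parse_newick("((a,b),((c,d),(e,f)));")  # ab, cd, ef, cdef
        ref = parse_newick("((a,c),((b,d),(e,f)));")  # shares ef ... check below
        est_bips = nontrivial_bipartitions(est)
        ref_bips = nontrivial_bipartitions(ref)
        n_shared = len(est_bips & ref_bips)
        sup = SupportMap({b: 0.5 for b in est_bips}, 10)
        curve = pr_curve(est, sup, ref)
        # one effective threshold plus the sentinel
        assert len(curve.points) == 2
        rec, prec, _ = curve.points[-1]
        assert rec == 1.0
        assert prec == pytest.approx(n_shared / len(est_bips))

    def test_monotone_transform_invariance(self):
        est = parse_newick("((a,b),((c,d),(e,f)));")  # 3 non-trivial splits
        ref = parse_newick("((a,b),((c,e),(d,f)));")
        vals = [0.2, 0.4, 0.8]
        sup1 = _support_for(est, vals)
        sup2 = _support_for(est, [v**3 for v in vals])
        assert pr_curve(est, sup1, ref).auc == pytest.approx(
            pr_curve(est, sup2, ref).auc
        )

    def test_no_reference_positive_is_error(self):
        est = _sixtree()
        ref = _sixtree("((a,c),(b,e),(d,f));")
        if nontrivial_bipartitions(est) & nontrivial_bipartitions(ref):
            pytest.skip("fixture unexpectedly shares a split")
        sup = _support_for(est, [0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            pr_curve(est, sup, ref)

    def test_matches_sklearn(self):
        """Dual-route check: our threshold sweep + trapezoid equals
        scikit-learn's precision_recall_curve + auc."""
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import precision_recall_curve

        from rawrphylo.evaluation import _curve_from_scores

        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            scores = rng.integers(0, 11, n) / 10
            pos = rng.random(n) < 0.5
            if not pos.any():
                continue
            mine = _curve_from_scores(list(zip(scores.tolist(), pos.tolist()))).auc
            p, r, _ = precision_recall_curve(pos.astype(int), scores)
            assert mine == pytest.approx(sk_auc(r, p), abs=1e-12)


class TestAggregate:
    def _case(self, vals, ref_newick):
        est = parse_newick("((a,b),((c,d),(e,f)));")
        return est, _support_for(est, vals), parse_newick(ref_newick)

    def test_single_case_equals_pr_curve(self):
        case = self._case([0.1, 0.5, 0.9], "((a,b),((c,e),(d,f)));")
        assert aggregate_pr_auc([case]) == pytest.approx(pr_curve(*case).auc)

    def test_pooling_homogeneous(self):
        case = self._case([0.1, 0.5, 0.9], "((a,b),((c,e),(d,f)));")
        assert aggregate_pr_auc([case, case]) == pytest.approx(pr_curve(*case).auc)

    def test_pooled_differs_from_mean_on_heterogeneous_cases(self):
        # each case is perfectly separated on its own scale (AUC 1), but
        # the score ranges interleave, so the pooled curve drops below 1
        ref = "((a,c),((b,d),(e,f)));"  # shares only the ef split with est
        c1 = self._case([0.2, 0.2, 0.6], ref)
        c2 = self._case([0.7, 0.7, 0.9], ref)
        pooled = aggregate_pr_auc([c1, c2])
        mean = aggregate_pr_auc([c1, c2], mean_auc=True)
        assert mean == pytest.approx(1.0)
        assert pooled < 1.0
        assert pooled != pytest.approx(mean)


class TestNRF:
    def test_identical_zero(self, five_taxon_trees):
        t1, _ = five_taxon_trees
        assert nrf_distance(t1, t1) == 0.0

    def test_half_shared(self, five_taxon_trees):
        t1, t2 = five_taxon_trees
        assert nrf_distance(t1, t2) == pytest.approx(0.5)

    def test_disjoint_one(self):
        t1 = parse_newick("((a,b),(c,d),(e,f));")
        t2 = parse_newick("((a,c),(b,e),(d,f));")
        assert nrf_distance(t1, t2) == 1.0

    def test_symmetry_and_dendropy_agreement(self):
        """Cross-check against dendropy's (unnormalized) RF distance on
        random binary topologies."""
        import dendropy
        from rawrphylo.simulation import sample_model_tree

        for s in range(10):
            t1 = sample_model_tree(8, 1.0, seed=s)
            t2 = sample_model_tree(8, 1.0, seed=100 + s)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert nrf_distance(t1, t2) == pytest.approx(rf / (2 * (8 - 3)))
            assert nrf_distance(t1, t2) == nrf_distance(t2, t1)

    def test_taxon_mismatch(self):
        with pytest.raises(ValueError):
            nrf_distance(parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));"))


def _brute_pairs(aln):
    """Independent oracle: enumerate residue-pair homologies column by
    column with explicit counters."""
    pairs = set()
    counters = [0] * len(aln)
    for col in range(aln.n_cols):
        present = [
            (i, counters[i]) for i, row in enumerate(aln.rows) if row[col] != "-"
        ]
        for (i, ri), (j, rj) in itertools.combinations(present, 2):
            pairs.add((i, ri, j, rj))
        for i, row in enumerate(aln.rows):
            counters[i] += row[col] != "-"
    return pairs


class TestSPErrors:
    def test_identity(self, toy_alignment):
        assert sp_errors(toy_alignment, toy_alignment) == (0.0, 0.0)

    def test_disjoint(self):
        # true pairs the C of a with the A of b; est pairs A-A and C-C
        true = Alignment((("a", "AC-"), ("b", "-AC")))
        est = Alignment((("a", "AC"), ("b", "AC")))
        assert sp_errors(true, est) == (1.0, 1.0)

    def test_direct_set_arithmetic(self):
        true = Alignment((("a", "ACG"), ("b", "ACG")))  # pairs (0,0),(1,1),(2,2)
        est = Alignment((("a", "AC-G"), ("b", "A-CG")))  # pairs (0,0),(2,2)
        sp_fn, sp_fp = sp_errors(true, est)
        assert sp_fn == pytest.approx(1 / 3)
        assert sp_fp == 0.0

    def test_column_shuffle_invariance(self):
        """Homology pairs depend on which residues share a column, not on
        column order: permuting the columns of a gapless alignment leaves
        the homology-pair set unchanged (so the implied SP errors against
        the original are zero)."""
        from rawrphylo.evaluation import _homology_pairs

        rng = np.random.default_rng(0)
        rows = ["ACGGTCA", "ATCGTTA", "ACCATGA"]
        true = Alignment(tuple((f"t{i}", r) for i, r in enumerate(rows)))
        perm = rng.permutation(7)
        shuffled = Alignment(
            tuple(
                (f"t{i}", "".join(r[p] for p in perm))
                for i, r in enumerate(rows)
            )
        )
        assert _homology_pairs(true) == _homology_pairs(shuffled)

    def test_against_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cols = int(rng.integers(4, 10))
            rows = [
                "".join(rng.choice(list("ACGT-"), cols)) for _ in range(3)
            ]
            rows = [r if r.strip("-") else "A" * cols for r in rows]
            a1 = Alignment(tuple((f"t{i}", r) for i, r in enumerate(rows)))
            from rawrphylo.evaluation import _homology_pairs

            assert _homology_pairs(a1) == _brute_pairs(a1)

    def test_unalign_mismatch_error(self):
        with pytest.raises(ValueError):
            sp_errors(
                Alignment((("a", "AC"), ("b", "AC"))),
                Alignment((("a", "AG"), ("b", "AC"))),
            )


class TestANHDGappiness:
    def test_identical_rows(self):
        assert anhd(Alignment((("a", "ACGT"), ("b", "ACGT")))) == 0.0

    def test_all_different(self):
        assert anhd(Alignment((("a", "AAAA"), ("b", "TTTT")))) == 1.0

    def test_gap_exclusion(self):
        assert anhd(Alignment((("a", "AAAA"), ("b", "AAT-")))) == pytest.approx(1 / 3)

    def test_pairwise_mean_brute_force(self):
        rows = ["ACGT-A", "AC-TTA", "TCGTAA"]
        a = Alignment(tuple((f"t{i}", r) for i, r in enumerate(rows)))
        vals = []
        for r1, r2 in itertools.combinations(rows, 2):
            comp = [(x, y) for x, y in zip(r1, r2) if x != "-" and y != "-"]
            vals.append(sum(x != y for x, y in comp) / len(comp))
        assert anhd(a) == pytest.approx(np.mean(vals))

    @pytest.mark.parametrize(
        "rows,expected",
        [
            (("ACGT", "ACGT"), 0.0),
            (("AC--", "ACGT"), 0.25),
            (("----", "ACGT"), 0.5),
        ],
    )
    def test_gappiness(self, rows, expected):
        a = Alignment(tuple((f"t{i}", r) for i, r in enumerate(rows)))
        assert gappiness(a) == pytest.approx(expected)
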