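import numpy as np
import pandas as pd
import pytest
import scipy.stats

import ulmnet as u


def calls_from(compositions):
    active = {f"bc{i}": frozenset(c.split("_")) if c else frozenset()
              for i, c in enumerate(compositions)}
    return u.classify_barcodes(active)


def matrix_from_values(values, genes, barcodes):
    """ExpressionMatrix whose lognorm layer is set to the given dense values."""
    arr = np.asarray(values, dtype=float)
    m = u.ExpressionMatrix(np.ceil(arr).astype(int), genes, barcodes)
    import scipy.sparse as sp
    m.lognorm = sp.csr_matrix(arr)
    return m


class TestSelectPairDoublets:
    def test_named_group_selection(self):
        calls = calls_from(["Bcell_Tcell", "Plasmablast_Tcell", "CAF_Tcell"])
        picked = u.select_pair_doublets(
            calls, {"Bcell", "Plasmablast"}, {"Tcell"})
        assert picked == ["bc0", "bc1"]

    def test_empty_groups_empty_selection(self):
        calls = calls_from(["Bcell_Tcell"])
        assert u.select_pair_doublets(calls, set(), {"Tcell"}) == []

    def test_triplets_excluded(self):
        calls = calls_from(["Bcell_CAF_Tcell"])
        assert u.select_pair_doublets(calls, {"Bcell"}, {"Tcell"}) == []

    def test_overlapping_groups_rejected(self):
        with pytest.raises(u.ValidationError, match="disjoint"):
            u.select_pair_doublets([], {"T"}, {"T", "B"})


class TestLrpCoexpression:
    def test_strict_mean_rule_hand_example(self):
        # ligand [2,0,1] (mean 1) expressed in unit 0; receptor [0,3,3]
        # (mean 2) expressed in units 1,2 -> intersection empty
        m = matrix_from_values([[2, 0, 1], [0, 3, 3]], ["LIG", "REC"],
                               ["u0", "u1", "u2"])
        pairs = pd.DataFrame({"ligand": ["LIG"], "receptor": ["REC"]})
        out = u.lrp_coexpression(m, ["u0", "u1", "u2"], pairs, min_units=0)
        assert len(out) == 1
        assert out.loc[0, "n_units"] == 0

    def test_constant_gene_never_expressed(self):
        m = matrix_from_values([[5, 5, 5], [0, 9, 0]], ["FLAT", "REC"],
                               ["u0", "u1", "u2"])
        pairs = pd.DataFrame({"ligand": ["FLAT"], "receptor": ["REC"]})
        out = u.lrp_coexpression(m, ["u0", "u1", "u2"], pairs, min_units=0)
        assert out.loc[0, "n_units"] == 0

    def test_min_units_retention(self):
        vals = np.zeros((2, 6))
        vals[:, 0] = 9  # both genes high only in unit 0
        m = matrix_from_values(vals + 0.5, ["L", "R"],
                               [f"u{i}" for i in range(6)])
        pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        units = [f"u{i}" for i in range(6)]
        assert len(u.lrp_coexpression(m, units, pairs, min_units=1)) == 1
        assert len(u.lrp_coexpression(m, units, pairs, min_units=5)) == 0

    def test_positive_scaling_invariance(self, rng):
        vals = rng.uniform(0, 4, size=(2, 10))
        genes, units = ["L", "R"], [f"u{i}" for i in range(10)]
        pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        base = u.lrp_coexpression(matrix_from_values(vals, genes, units),
                                  units, pairs, min_units=0)
        scaled = vals * np.array([[3.0], [0.5]])
        again = u.lrp_coexpression(matrix_from_values(scaled, genes, units),
                                   units, pairs, min_units=0)
        assert base.loc[0, "n_units"] == again.loc[0, "n_units"]

    def test_fraction_consistency_and_bounds(self, rng):
        vals = rng.uniform(0, 4, size=(4, 12))
        genes = ["L1", "R1", "L2", "R2"]
        units = [f"u{i}" for i in range(12)]
        pairs = pd.DataFrame({"ligand": ["L1", "L2"], "receptor": ["R1", "R2"]})
        out = u.lrp_coexpression(matrix_from_values(vals, genes, units),
                                 units, pairs, min_units=1)
        assert (out["n_units"] >= 1).all()
        assert np.allclose(out["fraction"], out["n_units"] / 12)
        assert ((out["fraction"] > 0) & (out["fraction"] <= 1)).all()

    def test_absent_genes_dropped_with_warning(self, rng):
        m = matrix_from_values(rng.uniform(0, 2, (2, 5)), ["L", "R"],
                               [f"u{i}" for i in range(5)])
        pairs = pd.DataFrame({"ligand": ["L", "GHOST"],
                              "receptor": ["R", "R"]})
        with pytest.warns(UserWarning, match="absent"):
            out = u.lrp_coexpression(m, [f"u{i}" for i in range(5)], pairs,
                                     min_units=0)
        assert len(out) == 1

    def test_unknown_unit_rejected(self, rng):
        m = matrix_from_values(rng.uniform(0, 2, (2, 5)), ["L", "R"],
                               [f"u{i}" for i in range(5)])
        pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        with pytest.raises(u.ValidationError, match="absent"):
            u.lrp_coexpression(m, ["u0", "nope"], pairs)


class TestColocalizedSpots:
    def deconv(self, rows, types=("T", "B", "Other")):
        spots = [f"s{i}" for i in range(len(rows))]
        return u.SpotDeconvolution(spots, list(types), np.asarray(rows))

    def test_inclusive_boundary(self):
        d = self.deconv([[0.06, 0.05, 0.89]])
        assert u.colocalized_spots(d, {"T"}, {"B"}, min_prop=0.05) == ["s0"]

    def test_below_threshold_excluded(self):
        d = self.deconv([[0.30, 0.049, 0.651]])
        assert u.colocalized_spots(d, {"T"}, {"B"}, min_prop=0.05) == []

    def test_zero_threshold_keeps_all(self):
        d = self.deconv([[0.3, 0.2, 0.5], [0.0, 0.1, 0.9]])
        assert len(u.colocalized_spots(d, {"T"}, {"B"}, min_prop=0.0)) == 2

    def test_group_proportions_are_sums(self):
        # B + plasma together reach 5% even though neither does alone
        d = self.deconv([[0.10, 0.03, 0.02, 0.85]],
                        types=("T", "B", "Plasmablast", "Other"))
        out = u.colocalized_spots(d, {"T"}, {"B", "Plasmablast"}, min_prop=0.05)
        assert out == ["s0"]

    def test_monotone_in_min_prop(self, rng):
        props = rng.dirichlet([1, 1, 1], size=60)
        d = self.deconv(list(props))
        prev = None
        for mp in (0.0, 0.02, 0.05, 0.2, 0.5):
            spots = set(u.colocalized_spots(d, {"T"}, {"B"}, min_prop=mp))
            if prev is not None:
                assert spots <= prev
            prev = spots

    def test_rows_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalized"):
            d = u.SpotDeconvolution(["s0"], ["T", "B"],
                                    np.array([[0.5, 0.4]]))
        assert d.proportions.sum() == pytest.approx(1.0)


class TestColocalizationCorrelation:
    def deconv(self, X, types):
        X = np.asarray(X, dtype=float)
        X = X / X.sum(axis=1, keepdims=True)
        return u.SpotDeconvolution([f"s{i}" for i in range(len(X))],
                                   types, X)

    def test_monotone_transform_gives_rho_one(self):
        a = np.linspace(0.1, 0.4, 20)
        b = np.sqrt(a)  # monotone transform, different values
        other = np.ones(20)
        d = self.deconv(np.stack([a, b, other], axis=1), ["A", "B", "C"])
        rho, _ = u.colocalization_correlation(d)
        assert rho.loc["A", "B"] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        a = np.linspace(0.1, 0.4, 15)
        d = self.deconv(np.stack([a, a[::-1], np.ones(15)], axis=1),
                        ["A", "B", "C"])
        rho, _ = u.colocalization_correlation(d)
        assert rho.loc["A", "B"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(77)
        # independent small fractions; a remainder column absorbs the rest so
        # rows sum to 1 without renormalization-induced dependence
        X = rng.uniform(0.0, 0.05, size=(5000, 2))
        rest = 1.0 - X.sum(axis=1)
        d = u.SpotDeconvolution([f"s{i}" for i in range(5000)],
                                ["A", "B", "C"],
                                np.column_stack([X, rest]))
        rho, _ = u.colocalization_correlation(d)
        assert abs(rho.loc["A", "B"]) < 0.05

    def test_agrees_with_rank_then_pearson_oracle(self, rng):
        X = rng.uniform(size=(40, 3))
        d = self.deconv(X, ["A", "B", "C"])
        rho, _ = u.colocalization_correlation(d)
        ranks = np.apply_along_axis(scipy.stats.rankdata, 0, d.proportions)
        oracle = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(rho.to_numpy(), oracle, atol=1e-10)

    def test_constant_column_reported_missing(self):
        # renormalized rows: column C constant share
        X = np.column_stack([np.linspace(0.1, 0.3, 10),
                             np.linspace(0.3, 0.1, 10),
                             np.full(10, 0.6)])
        d = u.SpotDeconvolution([f"s{i}" for i in range(10)],
                                ["A", "B", "C"], X / X.sum(1, keepdims=True))
        with pytest.warns(UserWarning, match="constant"):
            rho, p = u.colocalization_correlation(d)
        assert np.isnan(rho.loc["C", "A"]) and np.isnan(p.loc["A", "C"])

    def test_too_few_spots_rejected(self):
        d = u.SpotDeconvolution(["s0", "s1"], ["A", "B"],
                                np.array([[0.5, 0.5], [0.4, 0.6]]))
        with pytest.raises(u.ValidationError, match="spots"):
            u.colocalization_correlation(d)


class TestLrPairsReader:
    def test_duplicates_dropped_and_counts_logged(self, tmp_path, caplog):
        p = tmp_path / "lr.tsv"
        p.write_text("ligand\treceptor\nL1\tR1\nL1\tR1\nL2\tR2\n")
        import logging
        with pytest.warns(UserWarning, match="duplicate"), \
                caplog.at_level(logging.INFO, logger="ulmnet.crosstalk"):
            pairs = u.read_lr_pairs(p)
        assert len(pairs) == 2
        assert "2 unique ligands" in caplog.text

    def test_bundled_demo_list_is_valid(self):
        pairs = u.crosstalk.demo_lr_pairs()
        assert {"ligand", "receptor"} == set(pairs.columns)
        assert len(pairs) == len(pairs.drop_duplicates())
        assert len(pairs) >= 10
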