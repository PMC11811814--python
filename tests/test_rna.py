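"""Transcriptomic gating: NOX_mRNA split, subsets, DEGs, pathways."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropsecr.rna import (
    HOUSEKEEPING_GENES,
    NOX_GENE_SET,
    assign_subset,
    classify_nox_mrna,
    composition_report,
    default_marker_config,
    deg_test,
    default_pathways,
    housekeeping_check,
    pathway_modulation,
)
from dropsecr.synthgen import generate_rna_matrix


def cell(**vals):
    s = pd.Series(0.0, index=list(NOX_GENE_SET))
    for k, v in vals.items():
        s[k] = v
    return s


class TestNoxMrna:
    def test_all_nonpositive_is_negative(self):
        assert classify_nox_mrna(cell() - 0.1) == "neg"

    def test_zero_exactly_is_negative(self):
        assert classify_nox_mrna(cell()) == "neg"

    def test_single_positive_gene_suffices(self):
        assert classify_nox_mrna(cell(NOX2=0.5)) == "pos"

    def test_one_up_one_down_is_positive(self):
        assert classify_nox_mrna(cell(NOX1=0.4, NOX2=-0.2)) == "pos"

    def test_mean_mode_aggregates(self):
        c = cell(NOX1=0.4, NOX2=-0.2)  # mean over 15 genes is positive but small
        assert classify_nox_mrna(c, mode="mean") == "pos"
        assert classify_nox_mrna(cell(NOX1=0.1, NOX2=-0.5), mode="mean") == "neg"

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            classify_nox_mrna(cell(), gene_set=())

    def test_missing_genes_warn_and_count_as_zero(self):
        df = pd.DataFrame({"NOX1": [0.5, -0.5]})
        with pytest.warns(UserWarning, match="missing"):
            labels = classify_nox_mrna(df)
        assert list(labels) == ["pos", "neg"]

    @given(
        base=st.lists(st.floats(-2, 2), min_size=15, max_size=15),
        idx=st.integers(0, 14),
        bump=st.floats(0.0, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_raising_never_flips_pos_to_neg(self, base, idx, bump):
        c = pd.Series(base, index=list(NOX_GENE_SET))
        before = classify_nox_mrna(c)
        c2 = c.copy()
        c2.iloc[idx] += bump
        after = classify_nox_mrna(c2)
        assert not (before == "pos" and after == "neg")


class TestSubsets:
    def test_planted_markers_recovered(self):
        cfg = default_marker_config()
        genes = sorted({g for gl in cfg["subsets"].values() for g in gl})
        mat = pd.DataFrame(0.0, index=["c0"], columns=genes)
        mat.loc["c0", cfg["subsets"]["gcbc"]] = 2.0
        assert assign_subset(mat, cfg).iloc[0] == "gcbc"

    def test_all_zero_unassigned(self):
        cfg = default_marker_config()
        genes = sorted({g for gl in cfg["subsets"].values() for g in gl})
        mat = pd.DataFrame(0.0, index=["c0"], columns=genes)
        assert assign_subset(mat, cfg).iloc[0] == "unassigned"

    def test_exact_tie_unassigned(self):
        cfg = {"subsets": {"a": ["G1"], "b": ["G2"]}}
        mat = pd.DataFrame({"G1": [1.0], "G2": [1.0]})
        assert assign_subset(mat, cfg).iloc[0] == "unassigned"

    def test_noise_free_labels_fully_recovered(self):
        mat, truth = generate_rna_matrix(
            nox_positive_fraction=0.3, n_cells=1000, seed=17, noise_sd=0.0
        )
        labels = assign_subset(mat, default_marker_config())
        nox = classify_nox_mrna(mat)
        assert (labels.to_numpy() == truth["subset"].to_numpy()).all()
        assert (nox.to_numpy() == truth["nox_mrna"].to_numpy()).all()

    def test_gating_deterministic(self):
        mat, _ = generate_rna_matrix(nox_positive_fraction=0.2, n_cells=200, seed=4)
        a = assign_subset(mat, default_marker_config())
        b = assign_subset(mat, default_marker_config())
        pd.testing.assert_series_equal(a, b)


class TestDeg:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        n_genes = 1000
        cols = [f"G{i}" for i in range(n_genes)]
        group = pd.DataFrame(rng.normal(0, 1, (150, n_genes)), columns=cols)
        ref = pd.DataFrame(rng.normal(0, 1, (400, n_genes)), columns=cols)
        deg = deg_test(group, ref)
        frac = (deg["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) <= 3 * se
        assert deg["log2fc"].abs().mean() < 0.1

    def test_planted_shift_power(self):
        rng = np.random.default_rng(13)
        cols = [f"G{i}" for i in range(200)]
        group = pd.DataFrame(rng.normal(0, 0.5, (200, 200)), columns=cols)
        ref = pd.DataFrame(rng.normal(0, 0.5, (200, 200)), columns=cols)
        planted = cols[:50]
        group[planted] += 1.0
        deg = deg_test(group, ref).set_index("gene")
        assert (deg.loc[planted, "p"] < 0.05).mean() >= 0.9

    def test_constant_gene_p_one(self):
        group = pd.DataFrame({"G": [1.0] * 5})
        ref = pd.DataFrame({"G": [1.0] * 8})
        assert deg_test(group, ref)["p"].iloc[0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            deg_test(pd.DataFrame(), pd.DataFrame({"G": [1.0]}))


class TestPathways:
    def _deg(self, genes, fcs, ps=None):
        return pd.DataFrame(
            {"gene": genes, "log2fc": fcs, "p": ps if ps is not None else [0.01] * len(genes)}
        )

    def test_uniform_up_scores_plus_one(self):
        score, direction = pathway_modulation(self._deg(["A", "B"], [1.0, 1.0]), ["A", "B"])
        assert score == 1.0 and direction == "positive"

    def test_balanced_mix_no_direction(self):
        score, direction = pathway_modulation(self._deg(["A", "B"], [1.0, -1.0]), ["A", "B"])
        assert score == 0.0 and direction == "none"

    def test_empty_intersection_no_call(self):
        score, direction = pathway_modulation(self._deg(["A"], [1.0]), ["ZZZ"])
        assert np.isnan(score) and direction == "no call"

    def test_nonsignificant_genes_excluded(self):
        deg = self._deg(["A", "B"], [1.0, -5.0], ps=[0.01, 0.5])
        score, direction = pathway_modulation(deg, ["A", "B"])
        assert score == 1.0 and direction == "positive"

    def test_planted_pathway_shift_recovered(self):
        rng = np.random.default_rng(14)
        pathways = default_pathways()
        genes = pathways["glycolysis"] + [f"G{i}" for i in range(200)]
        group = pd.DataFrame(rng.normal(0, 0.3, (150, len(genes))), columns=genes)
        ref = pd.DataFrame(rng.normal(0, 0.3, (400, len(genes))), columns=genes)
        group[pathways["glycolysis"]] += 0.5
        deg = deg_test(group, ref)
        score, direction = pathway_modulation(deg, pathways["glycolysis"])
        assert direction == "positive"
        assert score == pytest.approx(0.5, abs=0.15)


class TestCompositionAndControls:
    def test_planted_composition_recovered(self):
        comp = {"gcbc": 0.34, "plasma_cell": 0.26, "naive_b": 0.40}
        mat, truth = generate_rna_matrix(composition=comp, n_cells=4000, seed=6)
        labels = assign_subset(mat, default_marker_config())
        ann = truth.assign(subset=labels.to_numpy())
        rep = composition_report(ann)
        sub = rep["subsets"].set_index("subset")
        for name, frac in comp.items():
            sd = np.sqrt(frac * (1 - frac) / 4000)
            assert abs(sub.loc[name, "fraction"] - frac) <= 3 * sd

    def test_no_positives_planted_all_fractions_zero(self):
        mat, truth = generate_rna_matrix(nox_positive_fraction=0.0, n_cells=500, seed=7)
        labels = classify_nox_mrna(mat)
        ann = truth.assign(nox_mrna=labels.to_numpy())
        rep = composition_report(ann)
        assert (rep["nox_by_subset"]["fraction_pos"] == 0.0).all()

    def test_housekeeping_pass_on_null(self):
        mat, _ = generate_rna_matrix(n_cells=2000, seed=8)
        ok, table = housekeeping_check(mat)
        assert ok

    def test_housekeeping_fails_on_planted_shift_naming_gene(self):
        mat, _ = generate_rna_matrix(n_cells=2000, seed=9)
        mat["HPRT"] += 1.0
        ok, table = housekeeping_check(mat)
        assert not ok
        bad = table[~table["ok"]]["gene"].tolist()
        assert bad == ["HPRT"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            housekeeping_check(pd.DataFrame())
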