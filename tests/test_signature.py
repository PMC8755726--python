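"""Sign-concordance signature derivation, scoring and set crossing."""

import numpy as np
import pandas as pd
import pytest

from oracles import venn_brute_force
from xenosig.expression import HUMAN_THRESHOLDS, annotate_de, de_test
from xenosig.signature import (
    GeneSignature,
    build_annotation_signature,
    correlate_with_anchor,
    cross_sets,
    derive_signature,
    score_signature,
)
from xenosig.synthetic_data import generate_cohort, generate_xenograft


@pytest.fixture
def tiny_cohort(rng):
    n = 50
    anchor = rng.standard_normal(n)
    expr = pd.DataFrame(
        {
            "ANCHOR": anchor,
            "POS": anchor * 2 + 3,  # perfectly correlated
            "NEG": -anchor,  # perfectly anti-correlated
            "NOISE": rng.standard_normal(n),
        }
    ).T
    expr.columns = [f"s{i}" for i in range(n)]
    return expr


class TestCorrelation:
    def test_anchor_self_correlation(self, tiny_cohort):
        corr = correlate_with_anchor(tiny_cohort, "ANCHOR")
        assert corr.loc["ANCHOR", "R"] == pytest.approx(1.0)
        assert corr.loc["ANCHOR", "passes"]

    def test_perfect_anticorrelation(self, tiny_cohort):
        corr = correlate_with_anchor(tiny_cohort, "ANCHOR")
        assert corr.loc["NEG", "R"] == pytest.approx(-1.0)
        assert corr.loc["POS", "R"] == pytest.approx(1.0)

    def test_threshold_is_strict(self, tiny_cohort):
        r_noise = correlate_with_anchor(tiny_cohort, "ANCHOR").loc["NOISE", "R"]
        corr = correlate_with_anchor(tiny_cohort, "ANCHOR", threshold=abs(r_noise))
        assert not corr.loc["NOISE", "passes"]  # |R| == threshold fails

    def test_zero_variance_gene_excluded(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.loc["FLAT"] = 3.0
        corr = correlate_with_anchor(cohort, "ANCHOR")
        assert "FLAT" not in corr.index

    def test_missing_anchor_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            correlate_with_anchor(tiny_cohort, "TWIST1")


def _de_frame(rows):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "is_de"]).set_index("gene")
    return df


class TestDeriveSignature:
    @pytest.fixture
    def corr(self):
        return pd.DataFrame(
            {"R": [0.3, 0.3, -0.4, 0.1, -0.3], "passes": [True, True, True, False, True]},
            index=["up1", "disc1", "down1", "weak", "down2"],
        )

    def test_sign_concordant_partition(self, corr):
        de = _de_frame(
            [
                ("up1", 1.5, True),
                ("disc1", -1.2, True),
                ("down1", -2.0, True),
                ("weak", 3.0, True),
                ("down2", 1.0, False),
            ]
        )
        sig = derive_signature(corr, de, "test")
        assert sig.up == ("up1",)
        assert sig.down == ("down1",)
        assert sig.discordant == ("disc1",)  # opposite R and FC signs
        assert "weak" not in sig.genes  # failed the R threshold
        assert "down2" not in sig.genes  # not DE

    def test_gene_order_irrelevant(self, corr):
        de = _de_frame([("up1", 1.5, True), ("down1", -2.0, True), ("disc1", -1.2, True)])
        sig1 = derive_signature(corr, de, "t")
        sig2 = derive_signature(corr.iloc[::-1], de.iloc[::-1], "t")
        assert sig1.up == sig2.up and sig1.down == sig2.down

    def test_empty_intersection_warns_not_raises(self, corr):
        de = _de_frame([("other", 2.0, True)])
        sig = derive_signature(corr, de, "t")
        assert sig.genes == ()


class TestScoreSignature:
    def test_definition_on_two_sample_cohort(self):
        # sample s0 sits +1 population SD on every up gene and -1 on every
        # down gene, so its weighted score is exactly 1
        expr = pd.DataFrame(
            {"s0": [1.0, 1.0, 0.0], "s1": [0.0, 0.0, 1.0]},
            index=["u1", "u2", "d1"],
        )
        sig = GeneSignature("t", "a", up=("u1", "u2"), down=("d1",))
        scores = score_signature(expr, sig)
        assert scores["s0"] == pytest.approx(1.0)
        assert scores["s1"] == pytest.approx(-1.0)

    def test_empty_down_list_degenerates_to_mean_up_z(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 10)), index=["a", "b", "c"])
        sig = GeneSignature("t", "", up=("a", "b", "c"), down=())
        scores = score_signature(expr, sig)
        from xenosig.stats_core import zscore

        expected = np.mean([zscore(expr.loc[g]) for g in "abc"], axis=0)
        assert scores.to_numpy() == pytest.approx(expected)

    def test_affine_rescaling_of_one_gene_is_invisible(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 20)), index=list("abcd"))
        sig = GeneSignature("t", "", up=("a", "b"), down=("c",))
        base = score_signature(expr, sig)
        expr2 = expr.copy()
        expr2.loc["a"] *= 10
        assert score_signature(expr2, sig).to_numpy() == pytest.approx(base.to_numpy())

    def test_weighted_vs_unweighted_variants(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 15)), index=list("abcde"))
        sig = GeneSignature("t", "", up=("a", "b", "c", "d"), down=("e",))
        w = score_signature(expr, sig, weighted=True)
        u = score_signature(expr, sig, weighted=False)
        assert not np.allclose(w, u)  # sub-list sizes differ, so variants differ

    def test_no_gene_present_raises(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 5)), index=["x", "y"])
        sig = GeneSignature("t", "", up=("a",), down=("b",))
        with pytest.raises(ValueError):
            score_signature(expr, sig)

    def test_recovers_planted_latent_score(self, small_cfg):
        cohort, truth = generate_cohort(small_cfg)
        sig = GeneSignature(
            "planted",
            cohort["anchor"],
            up=tuple(truth.planted_signature_up),
            down=tuple(truth.planted_signature_down),
        )
        scores = score_signature(cohort["expression"], sig)
        latent = pd.Series(truth.latent_score).reindex(scores.index)
        assert np.corrcoef(scores, latent)[0, 1] >= 0.9


class TestAnnotationSignature:
    def test_only_annotated_de_genes_enter(self):
        de = _de_frame([("g1", 2.0, True), ("g2", -1.5, True), ("g3", 1.2, False)])
        ann = pd.DataFrame(
            {"categories": ["growth_factor", "integrin;cytokine"]}, index=["g1", "g3"]
        )
        out = build_annotation_signature(de, ann)
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "direction"] == "up"
        assert out.loc["g1", "group"] == "growth factors"

    def test_empty_result_is_warning_not_error(self):
        de = _de_frame([("g1", 2.0, True)])
        ann = pd.DataFrame({"categories": []}, index=pd.Index([], name="gene"))
        assert build_annotation_signature(de, ann).empty


class TestCrossSets:
    def test_identical_sets(self):
        regions = cross_sets({"A": {1, 2}, "B": {1, 2}})
        assert regions["A&B"] == {1, 2}
        assert regions["A"] == set() and regions["B"] == set()

    def test_disjoint_sets(self):
        regions = cross_sets({"A": {1}, "B": {2}, "C": {3}})
        assert all(not v for k, v in regions.items() if "&" in k)

    def test_three_set_partition_matches_brute_force(self):
        sets = {
            "A": set(range(1, 11)),
            "B": set(range(6, 16)),
            "C": set(range(8, 13)),
        }
        regions = cross_sets(sets)
        expected = venn_brute_force(sets)
        for key, members in regions.items():
            assert len(members) == expected.get(key, 0)
        assert sum(len(v) for v in regions.values()) == 15

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            cross_sets({"A": {1}})


def test_end_to_end_signature_recovery(small_cfg):
    """Planted concordant genes are recovered by the full derive chain."""
    cohort, truth = generate_cohort(small_cfg)
    counts, groups, _, _ = generate_xenograft(
        small_cfg,
        planted_up=truth.planted_signature_up,
        planted_down=truth.planted_signature_down,
        gene_names=list(cohort["expression"].index),
    )
    de = annotate_de(de_test(counts, groups, reference="knockout"), HUMAN_THRESHOLDS)
    corr = correlate_with_anchor(cohort["expression"], cohort["anchor"])
    sig = derive_signature(corr, de, "recovered", anchor=cohort["anchor"])
    planted = set(truth.planted_signature_up) | set(truth.planted_signature_down)
    found = set(sig.genes)
    sensitivity = len(found & planted) / len(planted)
    fdr = len(found - planted) / max(len(found), 1)
    assert sensitivity >= 0.9
    assert fdr <= 0.1
    assert set(sig.up) <= set(truth.planted_signature_up) | (found - planted)
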