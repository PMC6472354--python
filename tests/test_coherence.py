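import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigcoherence.coherence import (
    SignatureVector, coherence_test, control_factor_scan,
    correlate_signatures, directed_pvalue, immune_set_shift, permutation_p,
    read_signature, write_signature,
)
from sigcoherence.differential_expression import fit_all_genes
from sigcoherence.formats_io import ImmuneAnnotation
from sigcoherence.synthetic_data import (
    SimulationConfig, draw_ground_truth, simulate_casecontrol,
)


class TestDirectedPvalue:
    @pytest.mark.parametrize("p,stat,expected", [
        (0.01, 3.2, 2.0),
        (0.1, -1.5, -1.0),
        (1.0, 42.0, 0.0),
        (0.5, 0.0, 0.0),
    ])
    def test_values(self, p, stat, expected):
        assert directed_pvalue(p, stat) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            directed_pvalue(0.0, 1.0)
        with pytest.raises(ValueError):
            directed_pvalue(1.5, 1.0)


class TestCorrelateSignatures:
    def _sig(self, ids, vals, level="gene", name="f"):
        return SignatureVector(ids, np.asarray(vals, float), level, name)

    def test_identity_and_negation(self):
        a = self._sig(["a", "b", "c"], [1.0, 2.0, 4.0])
        rho, n = correlate_signatures(a, a)
        assert rho == pytest.approx(1.0)
        b = self._sig(["a", "b", "c"], [-1.0, -2.0, -4.0])
        rho, _ = correlate_signatures(a, b)
        assert rho == pytest.approx(-1.0)

    def test_closed_form_oracle_five_points(self):
        va = np.array([0.3, -1.2, 2.0, 0.7, -0.5])
        vb = np.array([1.1, -0.4, 1.5, -0.2, 0.9])
        a = self._sig(list("abcde"), va)
        b = self._sig(list("abcde"), vb)
        num = np.sum((va - va.mean()) * (vb - vb.mean()))
        den = np.sqrt(np.sum((va - va.mean()) ** 2)
                      * np.sum((vb - vb.mean()) ** 2))
        rho, n = correlate_signatures(a, b)
        assert rho == pytest.approx(num / den, abs=1e-12)
        assert n == 5

    def test_intersection_only(self):
        a = self._sig(["a", "b", "c", "x"], [1, 2, 3, 99])
        b = self._sig(["c", "b", "a", "y"], [3, 2, 1, -99])
        rho, n = correlate_signatures(a, b)
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_errors(self):
        a = self._sig(["a", "b", "c"], [1, 2, 3])
        with pytest.raises(ValueError, match="common"):
            correlate_signatures(a, self._sig(["x", "y", "z"], [1, 2, 3]))
        with pytest.raises(ValueError, match="levels"):
            correlate_signatures(
                a, self._sig(["a", "b", "c"], [1, 2, 3], level="pathway"))
        with pytest.raises(ValueError, match="zero variance"):
            correlate_signatures(a, self._sig(["a", "b", "c"], [1, 1, 1],
                                              name="flat"))


class TestPermutationP:
    def test_no_exceedances(self):
        assert permutation_p([0.1, 0.2, -0.25], 0.3) == 0.0

    def test_counting_example(self):
        assert permutation_p([0.1, -0.5, 0.2, 0.05], 0.3) == 0.25

    def test_headline_scale_consistency(self):
        # 31 exceedances out of 5000 permutations -> 0.0062
        rng = np.random.default_rng(0)
        null = 0.3 * rng.random(5000 - 31)
        null = np.concatenate([null, 0.62 + 0.2 * rng.random(31)])
        assert permutation_p(null, 0.606) == pytest.approx(0.0062)

    def test_invariance_under_null_ordering(self):
        rng = np.random.default_rng(1)
        null = rng.normal(0, 0.3, 400)
        p1 = permutation_p(null, 0.25)
        p2 = permutation_p(rng.permutation(null), 0.25)
        assert p1 == p2

    def test_ties_do_not_count(self):
        assert permutation_p([0.3, -0.3, 0.3], 0.3) == 0.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_p([], 0.5)


@pytest.fixture(scope="module")
def ab_setup():
    cfg = SimulationConfig(n_genes=400, n_pathways=10,
                           pathway_size_range=(15, 25),
                           frac_active_pathways=0.4, effect_sd=0.5,
                           cross_factor_correlation=0.6, seed=31)
    truth = draw_ground_truth(cfg)
    study, _ = simulate_casecontrol(cfg, 15, 60, truth=truth)
    fits = fit_all_genes(study, "ab", model="linear")
    obs_sig = SignatureVector(fits["gene_id"].tolist(),
                              fits["t"].to_numpy(), "gene", "ab")
    return cfg, truth, study, obs_sig


class TestCoherenceTest:
    def test_self_signature_has_unit_correlation(self, ab_setup):
        _, _, study, obs_sig = ab_setup
        res = coherence_test(study, obs_sig, "ab", "gene", "linear",
                             B=100, seed=2)
        assert res.rho_obs == pytest.approx(1.0)
        assert res.n_common_ids == study.n_genes

    def test_sign_equivariance(self, ab_setup):
        _, truth, study, _ = ab_setup
        rng = np.random.default_rng(3)
        fixed = SignatureVector(truth.gene_ids,
                                truth.beta_cs / 0.1 + rng.normal(size=400),
                                "gene", "cs")
        neg = SignatureVector(truth.gene_ids, -fixed.values, "gene", "cs")
        r1 = coherence_test(study, fixed, "ab", "gene", "linear",
                            B=100, seed=4)
        r2 = coherence_test(study, neg, "ab", "gene", "linear",
                            B=100, seed=4)
        assert r2.rho_obs == pytest.approx(-r1.rho_obs)
        assert r2.p_perm == r1.p_perm

    def test_detects_planted_cross_factor_correlation(self, ab_setup):
        _, truth, study, _ = ab_setup
        rng = np.random.default_rng(5)
        # a CS-like signature: standardized true effects plus unit noise
        fixed = SignatureVector(truth.gene_ids,
                                truth.beta_cs / 0.08 + rng.normal(size=400),
                                "gene", "cs")
        res = coherence_test(study, fixed, "ab", "gene", "linear",
                             B=200, seed=6)
        assert res.rho_obs > 0.3
        assert res.p_perm <= 0.05
        assert len(res.null_rhos) == 200

    def test_pathway_level_runs_and_correlates(self, ab_setup):
        cfg, truth, study, _ = ab_setup
        from sigcoherence.safe_enrichment import safe_test
        pw = safe_test(study, "ab", truth.gene_set_collection(),
                       model="linear", B=150, seed=7)
        fixed = SignatureVector(pw["name"].tolist(),
                                pw["directed_p"].to_numpy(), "pathway", "cs")
        res = coherence_test(study, fixed, "ab", "pathway", "linear",
                             gene_sets=truth.gene_set_collection(),
                             B=100, inner_B=150, seed=8)
        assert res.level == "pathway"
        assert res.rho_obs > 0.5  # self-derived signature, same labels
        assert res.p_perm <= 0.1

    def test_missing_gene_sets_rejected_for_pathway_level(self, ab_setup):
        _, _, study, obs_sig = ab_setup
        pw_sig = SignatureVector(["P1", "P2", "P3"], [1.0, 2.0, 3.0],
                                 "pathway", "cs")
        with pytest.raises(ValueError, match="gene_sets"):
            coherence_test(study, pw_sig, "ab", "pathway", "linear",
                           B=100, seed=0)


class TestControlScan:
    def test_duplicated_factor_gives_identical_rows(self, ab_setup):
        _, truth, study, _ = ab_setup
        fixed = SignatureVector(truth.gene_ids, truth.beta_cs / 0.1
                                + np.random.default_rng(0).normal(size=400),
                                "gene", "cs")
        out = control_factor_scan(study, fixed, ["gender", "gender"],
                                  B=100, seed=9)
        assert len(out) == 2
        assert out.iloc[0]["rho_obs"] == out.iloc[1]["rho_obs"]

    def test_empty_factor_list_gives_empty_table(self, ab_setup):
        _, _, study, obs_sig = ab_setup
        out = control_factor_scan(study, obs_sig, [], B=100, seed=0)
        assert len(out) == 0

    def test_unknown_factor_skipped(self, ab_setup):
        _, _, study, obs_sig = ab_setup
        out = control_factor_scan(study, obs_sig, ["not_a_factor"],
                                  B=100, seed=0)
        assert len(out) == 0

    def test_adjustment_removes_case_label_leakage(self, ab_setup):
        # make a null factor that strongly co-occurs with the case label:
        # unadjusted, its signature borrows the ab signal and correlates
        # with the CS-like fixed signature; adjusted for ab it does not
        _, truth, study, _ = ab_setup
        rng = np.random.default_rng(13)
        ab = study.metadata["ab"].to_numpy(float)
        confounded = ab.copy()
        flip = rng.random(len(ab)) < 0.15
        confounded[flip] = 1 - confounded[flip]
        study.metadata["gender"] = confounded
        fixed = SignatureVector(truth.gene_ids,
                                truth.beta_cs / 0.08 + rng.normal(size=400),
                                "gene", "cs")
        raw = coherence_test(study, fixed, "gender", "gene", "linear",
                             B=50, seed=1)
        adj = coherence_test(study, fixed, "gender", "gene", "linear",
                             B=50, seed=1, adjust_for="ab")
        assert abs(raw.rho_obs) > 0.3
        assert abs(adj.rho_obs) < 0.25

    def test_adjustment_limited_to_gene_linear(self, ab_setup):
        _, _, study, obs_sig = ab_setup
        with pytest.raises(ValueError, match="adjust_for"):
            coherence_test(study, obs_sig, "ab", "gene", "gamm",
                           B=100, seed=0, adjust_for="gender")


class TestImmuneShift:
    def _fits(self, t_immune, t_other):
        genes = [f"I{i}" for i in range(len(t_immune))] + \
                [f"N{i}" for i in range(len(t_other))]
        return (pd.DataFrame({"gene_id": genes,
                              "t": list(t_immune) + list(t_other)}),
                ImmuneAnnotation({f"I{i}" for i in range(len(t_immune))}))

    def test_identical_multisets_give_p_one(self):
        fits, ann = self._fits([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        _, p = immune_set_shift(fits, ann)
        assert p == 1.0

    def test_exact_path_matches_mannwhitney(self):
        rng = np.random.default_rng(10)
        t1 = rng.normal(1.0, 0.5, 6)
        t0 = rng.normal(0.0, 0.5, 8)
        fits, ann = self._fits(t1, t0)
        _, p = immune_set_shift(fits, ann)
        oracle = stats.mannwhitneyu(np.abs(t1), np.abs(t0),
                                    alternative="two-sided",
                                    method="exact").pvalue
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_three_vs_three_enumeration_count(self):
        # every distinct assignment is equally likely: p is a multiple of
        # 1/C(6,3) = 1/20
        fits, ann = self._fits([0.1, 0.5, 0.9], [0.2, 0.4, 0.6])
        _, p = immune_set_shift(fits, ann)
        assert (p * 20) == pytest.approx(round(p * 20))

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(11)
        t1 = rng.normal(0, 1, 200) + 2.0
        t0 = rng.normal(0, 1, 1800)
        fits, ann = self._fits(t1, t0)
        _, p = immune_set_shift(fits, ann)
        assert p < 1e-6

    def test_empty_stratum_rejected(self):
        fits, _ = self._fits([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            immune_set_shift(fits, ImmuneAnnotation({"ZZZ"}))


def test_signature_io_round_trip(tmp_path):
    sig = SignatureVector(["g1", "g2", "g3"], [0.5, -1.25, 3.0],
                          "gene", "cs")
    write_signature(sig, tmp_path / "sig.tsv")
    back = read_signature(tmp_path / "sig.tsv")
    assert back.ids == sig.ids
    np.testing.assert_allclose(back.values, sig.values, rtol=1e-6)
    assert back.level == "gene" and back.factor_name == "cs"
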