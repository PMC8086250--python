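"""Carrier collapse, crude/adjusted burden tests, AML mixture test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rvburden as rv
from conftest import missense_matrix
from rvburden.errors import ConfigError, DataError


class TestCrudeOr:
    @pytest.mark.parametrize(
        "table, printed, tol",
        [
            ((29, 5492, 9, 5174), 3.04, 0.005),   # deep-sequencing carrier table
            ((6, 818, 7, 903), 0.946, 0.0005),    # exome carrier table (printed 0.94 adjusted)
        ],
    )
    def test_reproduces_published_carrier_tables(self, table, printed, tol):
        assert rv.crude_or(*table).or_hat == pytest.approx(printed, abs=tol)

    def test_zero_cells_get_haldane_correction_symmetrically(self):
        res = rv.crude_or(0, 10, 0, 10)
        assert res.or_hat == 1.0

    def test_diagonal_zero_cells_flagged_non_estimable(self):
        assert rv.crude_or(0, 10, 5, 0).non_estimable
        assert rv.crude_or(5, 0, 0, 10).non_estimable
        assert not rv.crude_or(0, 10, 5, 5).non_estimable

    def test_wald_ci_and_p_are_consistent(self):
        res = rv.crude_or(29, 5492, 9, 5174)
        assert res.ci_low < res.or_hat < res.ci_high
        # the published interval (1.43, 6.43) is country-adjusted; the crude
        # table reproduces it to within ~1%
        assert res.ci_low == pytest.approx(1.43, rel=0.01)
        assert res.ci_high == pytest.approx(6.43, rel=0.01)
        assert res.p == pytest.approx(0.0037, abs=3e-4)
        assert 0 < res.p_score < 1

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.integers(0, 500), b=st.integers(1, 5000),
        c=st.integers(0, 500), d=st.integers(1, 5000),
    )
    def test_transposing_groups_inverts_the_odds_ratio(self, a, b, c, d):
        assert rv.crude_or(a, b, c, d).or_hat * rv.crude_or(c, d, a, b).or_hat == pytest.approx(
            1.0, rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            rv.crude_or(-1, 5, 5, 5)


def toy_cohort():
    manifest = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "status": ["case"] * 4 + ["control"] * 4,
            "histotype": ["HGSOC", "HGSOC", "other-EOC", "HGSOC"] + ["NA"] * 4,
            "stratum": ["A"] * 8,
            "platform": ["TS"] * 8,
        }
    )
    classified = pd.DataFrame(
        {
            "variant_id": ["g1_v1", "g1_v2", "g2_v1", "g1_v3"],
            "gene": ["G1", "G1", "G2", "G1"],
            "class": ["deleterious", "deleterious", "deleterious", "not_deleterious"],
        }
    )
    genotypes = pd.DataFrame(
        {
            # s0 carries two deleterious G1 variants; s1 carries G1 and G2;
            # s4 (control) carries G1; s2 carries only a non-deleterious variant
            "sample_id": ["s0", "s0", "s1", "s1", "s4", "s2"],
            "variant_id": ["g1_v1", "g1_v2", "g1_v1", "g2_v1", "g1_v2", "g1_v3"],
            "gt": [1, 1, 1, 1, 1, 1],
        }
    )
    return manifest, classified, genotypes


class TestCollapseCarriers:
    def test_subject_with_two_variants_counts_once(self):
        manifest, classified, genotypes = toy_cohort()
        a, b, c, d = rv.collapse_carriers(classified, genotypes, manifest, "G1")
        assert (a, b, c, d) == (2, 2, 1, 3)

    def test_multi_gene_carrier_appears_in_both_genes(self):
        manifest, classified, genotypes = toy_cohort()
        a2, *_ = rv.collapse_carriers(classified, genotypes, manifest, "G2")
        assert a2 == 1  # s1 counted for G2 as well as G1

    def test_histotype_subset_shrinks_cases_only(self):
        manifest, classified, genotypes = toy_cohort()
        overall = rv.collapse_carriers(classified, genotypes, manifest, "G1")
        hgsoc = rv.collapse_carriers(classified, genotypes, manifest, "G1", histotype="HGSOC")
        assert (hgsoc[2], hgsoc[3]) == (overall[2], overall[3])  # controls shared
        assert hgsoc[0] + hgsoc[1] < overall[0] + overall[1]

    def test_non_deleterious_variants_never_make_carriers(self):
        manifest, classified, genotypes = toy_cohort()
        a, b, c, d = rv.collapse_carriers(classified, genotypes, manifest, "G1")
        assert a + c == 3  # s2's not_deleterious call does not count

    def test_absent_gene_warns_and_returns_empty_margin(self):
        manifest, classified, genotypes = toy_cohort()
        with pytest.warns(UserWarning, match="absent"):
            a, b, c, d = rv.collapse_carriers(classified, genotypes, manifest, "NOPE")
        assert (a, c) == (0, 0) and b + d == len(manifest)


def grid_search_logistic_oracle(carrier, is_case, stratum):
    """Direct maximisation of the stratified logistic likelihood on a grid.

    Independent of any regression library: profiles the exact binomial
    log-likelihood over (intercept per stratum, carrier lnOR) by nested grid
    refinement and returns the lnOR at the maximum.
    """
    carrier = np.asarray(carrier, bool)
    is_case = np.asarray(is_case, bool)
    stratum = np.asarray(stratum)
    labels = np.unique(stratum)
    # sufficient statistics: cases and totals per (stratum, carrier) cell
    y = np.array([[ (is_case & (stratum == s) & (carrier == x)).sum() for x in (0, 1)]
                  for s in labels], float)
    n = np.array([[ ((stratum == s) & (carrier == x)).sum() for x in (0, 1)]
                  for s in labels], float)

    def loglik(b, beta):  # b: (S, G) intercept grid, beta: (G2,) carrier grid
        ll = np.zeros((b.shape[1], beta.size))
        for si in range(len(labels)):
            for x in (0, 1):
                eta = b[si][:, None] + beta[None, :] * x
                logp = -np.log1p(np.exp(-eta))
                log1mp = -np.log1p(np.exp(eta))
                ll += y[si, x] * logp + (n[si, x] - y[si, x]) * log1mp
        return ll

    b_centre = np.log(y.sum(1) / (n.sum(1) - y.sum(1)))  # crude per-stratum logit
    beta_centre, half = 0.0, 2.0
    for _ in range(4):  # nested refinement: resolution 4/40 -> ~1e-3
        bg = np.linspace(-half, half, 41)
        beta_g = beta_centre + np.linspace(-half, half, 41)
        # profile intercepts jointly via outer product of per-stratum grids is
        # costly; exploit separability: optimise each stratum's intercept on a
        # grid for each beta
        best = None
        grids = [bc + bg for bc in b_centre]
        # evaluate over the cartesian product lazily, stratum by stratum:
        # for fixed beta, the likelihood separates across strata
        ll_total = np.zeros(beta_g.size)
        b_best = np.zeros(len(labels))
        for si in range(len(labels)):
            eta0 = grids[si][:, None]
            eta1 = grids[si][:, None] + beta_g[None, :]
            ll_s = (
                y[si, 0] * -np.log1p(np.exp(-eta0))
                + (n[si, 0] - y[si, 0]) * -np.log1p(np.exp(eta0))
                + y[si, 1] * -np.log1p(np.exp(-eta1))
                + (n[si, 1] - y[si, 1]) * -np.log1p(np.exp(eta1))
            )  # (B, T)
            ll_total = ll_total + ll_s.max(axis=0)
        ti = int(ll_total.argmax())
        beta_centre = float(beta_g[ti])
        half /= 10.0
    return beta_centre


class TestLogisticBurden:
    def test_unstratified_fit_equals_crude_odds_ratio(self):
        rng = np.random.default_rng(7)
        carrier = rng.random(2000) < 0.02
        is_case = rng.random(2000) < 0.5
        if not (carrier & is_case).any():
            carrier[0] = is_case[0] = True
        a = int((carrier & is_case).sum()); b = int((~carrier & is_case).sum())
        c = int((carrier & ~is_case).sum()); d = int((~carrier & ~is_case).sum())
        res = rv.logistic_burden(carrier, is_case)
        crude = rv.crude_or(a, b, c, d)
        assert res.or_hat == pytest.approx(crude.or_hat, abs=1e-8)

    def test_confounded_cohort_adjustment_matches_grid_oracle(self, classified_bundle):
        bundle, manifest, genotypes, classified = classified_bundle
        from rvburden.burden import carrier_flags

        flags = carrier_flags(genotypes, classified, manifest, ["NULLG"])
        m = manifest.set_index("sample_id")
        carrier = flags.reindex(m.index).fillna(False).to_numpy()
        is_case = (m["status"] == "case").to_numpy()
        stratum = m["stratum"].to_numpy()

        adjusted = rv.logistic_burden(
            carrier, is_case, pd.DataFrame({"stratum": stratum})
        )
        crude = rv.crude_or(
            int((carrier & is_case).sum()), int((~carrier & is_case).sum()),
            int((carrier & ~is_case).sum()), int((~carrier & ~is_case).sum()),
        )
        oracle_beta = grid_search_logistic_oracle(carrier, is_case, stratum)
        assert np.log(adjusted.or_hat) == pytest.approx(oracle_beta, abs=5e-3)
        # the confounding design pushes the crude OR well away from the
        # adjusted one for this null gene
        assert abs(np.log(crude.or_hat) - np.log(adjusted.or_hat)) > 0.15

    def test_no_carriers_is_a_data_error(self):
        with pytest.raises(DataError):
            rv.logistic_burden(np.zeros(10), np.ones(10))

    def test_complete_separation_falls_back_to_crude(self):
        carrier = np.array([True] * 5 + [False] * 5)
        is_case = carrier.copy()
        with pytest.warns(UserWarning, match="separation|fallback|fit failure"):
            res = rv.logistic_burden(carrier, is_case)
        assert res.separation_fallback
        assert res.non_estimable


class TestGeneSetBurden:
    def test_single_gene_set_equals_gene_burden(self):
        manifest, classified, genotypes = toy_cohort()
        single = rv.gene_burden("G1", classified, genotypes, manifest)
        as_set = rv.gene_set_burden(["G1"], classified, genotypes, manifest)
        assert (single.a, single.b, single.c, single.d) == (
            as_set.a, as_set.b, as_set.c, as_set.d,
        )

    def test_union_respects_inclusion_exclusion(self):
        manifest, classified, genotypes = toy_cohort()
        g1 = rv.gene_burden("G1", classified, genotypes, manifest)
        g2 = rv.gene_burden("G2", classified, genotypes, manifest)
        both = rv.gene_set_burden(["G1", "G2"], classified, genotypes, manifest)
        n_multi = 1  # s1 carries deleterious variants in both genes
        assert both.a == g1.a + g2.a - n_multi

    def test_empty_gene_set_rejected(self):
        manifest, classified, genotypes = toy_cohort()
        with pytest.raises(ConfigError):
            rv.gene_set_burden([], classified, genotypes, manifest)

    def test_carrier_frequencies_render_like_published_summary(self):
        res = rv.crude_or(96, 6088, 85, 6004, gene="FA-set")
        assert f"{100 * res.case_carrier_freq:.2g}" == "1.6"
        assert f"{100 * res.control_carrier_freq:.2g}" == "1.4"


class TestAmlMissense:
    def _matrix(self, classified_bundle):
        bundle, manifest, genotypes, classified = classified_bundle
        return missense_matrix(bundle, manifest), manifest

    def test_alpha_constrained_to_zero_nullifies_the_statistic(self, classified_bundle):
        wide, manifest = self._matrix(classified_bundle)
        res = rv.aml_missense_test(
            wide, manifest, n_perm=99, seed=1, alpha_grid=np.array([0.0])
        )
        assert res.statistic == 0.0
        assert res.p_perm == 1.0

    def test_permutation_p_is_within_valid_bounds(self, classified_bundle):
        wide, manifest = self._matrix(classified_bundle)
        res = rv.aml_missense_test(wide, manifest, n_perm=199, seed=2)
        assert 1 / 200 <= res.p_perm <= 1.0
        assert res.statistic >= 0.0
        assert 0.0 <= res.alpha_hat <= 1.0

    def test_enriched_variants_shift_p_below_null(self):
        """Median permutation p is smaller when 30% of variants carry OR=3."""
        def run(missense_or, assoc_frac, seed):
            cfg = rv.SimConfig(
                strata=[rv.StratumSpec("S", 800, 800)],
                genes=[rv.GeneSpec("G", 0.0)],
                n_missense_per_gene=20,
                missense_or=missense_or,
                missense_assoc_fraction=assoc_frac,
                seed=seed,
            )
            bundle = rv.simulate_cohort(cfg)
            wide = missense_matrix(bundle, bundle.manifest)
            return rv.aml_missense_test(wide, bundle.manifest, n_perm=199, seed=seed).p_perm

        null_ps = [run(1.0, 0.0, s) for s in range(30, 42)]
        alt_ps = [run(3.0, 0.3, s) for s in range(60, 72)]
        assert np.median(alt_ps) < np.median(null_ps)

    def test_empty_variant_set_is_undefined_not_p_one(self, classified_bundle):
        _, manifest, *_ = classified_bundle[0], classified_bundle[1]
        manifest = classified_bundle[1]
        empty = pd.DataFrame(
            0.0, index=manifest["sample_id"], columns=["v1", "v2"]
        )
        with pytest.raises(DataError):
            rv.aml_missense_test(empty, manifest, n_perm=99, seed=0)
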