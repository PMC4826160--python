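import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctc_origin import (
    CellPhenotype,
    ConfigurationError,
    FrequencyTable,
    INDETERMINATE,
    SceneConfig,
    binomial_log_likelihood,
    cell_log_likelihood,
    classify,
    generate_scene,
    population_posterior,
    sample_marker_states,
)

FEMALE_PANEL = ("CK7", "CK20", "TTF-1", "ER")
MALE_PANEL = ("CK7", "CK20", "TTF-1", "PSA")


def _cells(panel, call_rows):
    return [
        CellPhenotype(roi_label=i, nuclear_positive=True,
                      marker_calls=dict(zip(panel, calls)), is_ctc=True)
        for i, calls in enumerate(call_rows)
    ]


def brute_force_posterior(cells, table, prior=None):
    """Independent oracle: plain-float product of per-marker probabilities,
    normalised directly (safe at these tiny sizes)."""
    tissues = list(table.tissues)
    prior = prior or {t: 1.0 / len(tissues) for t in tissues}
    weights = []
    for t in tissues:
        like = 1.0
        for cell in cells:
            for m, call in cell.marker_calls.items():
                p = table.p[t][m]
                like *= p if call else (1.0 - p)
        weights.append(prior[t] * like)
    z = sum(weights)
    return {t: w / z for t, w in zip(tissues, weights)}


def _random_instances(rng, n_instances, panel, max_cells=5):
    for _ in range(n_instances):
        n = int(rng.integers(1, max_cells + 1))
        rows = rng.random((n, len(panel))) < 0.5
        yield _cells(panel, [tuple(map(bool, r)) for r in rows])


class TestCellLogLikelihood:
    def test_half_probability_marker_is_call_independent(self):
        table = FrequencyTable(tissues=("breast", "lung"), markers=("CK7",),
                               raw={"breast": {"CK7": 0.5}, "lung": {"CK7": 0.5}})
        pos = _cells(("CK7",), [(True,)])[0]
        neg = _cells(("CK7",), [(False,)])[0]
        for tissue in ("breast", "lung"):
            assert cell_log_likelihood(pos, tissue, table) == pytest.approx(math.log(0.5))
            assert cell_log_likelihood(neg, tissue, table) == pytest.approx(math.log(0.5))

    def test_psa_positive_profile_is_maximised_by_prostate(self, table):
        """PSA+/TTF-1-/CK7+ can only be prostate among the four tissues."""
        cell = CellPhenotype(roi_label=0, nuclear_positive=True,
                             marker_calls={"CK7": True, "TTF-1": False, "PSA": True},
                             is_ctc=True)
        scores = {t: cell_log_likelihood(cell, t, table) for t in table.tissues}
        assert max(scores, key=scores.get) == "prostate"

    def test_ck7_only_female_profile_favours_breast_over_colon_and_lung(self, table):
        cell = _cells(FEMALE_PANEL, [(True, False, False, False)])[0]
        scores = {t: cell_log_likelihood(cell, t, table) for t in table.tissues}
        assert scores["breast"] > scores["colon"]
        assert scores["breast"] > scores["lung"]

    def test_marker_absent_from_table_raises(self, table):
        cell = CellPhenotype(roi_label=0, nuclear_positive=True,
                             marker_calls={"AFP": True}, is_ctc=True)
        with pytest.raises(ConfigurationError, match="AFP"):
            cell_log_likelihood(cell, "lung", table)

    def test_mixed_sex_panel_rejected(self, table):
        cell = CellPhenotype(roi_label=0, nuclear_positive=True,
                             marker_calls={"ER": True, "PSA": True}, is_ctc=True)
        with pytest.raises(ConfigurationError):
            cell_log_likelihood(cell, "breast", table)

    def test_sex_context_mismatch_rejected(self, table):
        cells = _cells(MALE_PANEL, [(True, False, False, True)])
        with pytest.raises(ConfigurationError, match="PSA"):
            population_posterior(cells, table, sex="female")


class TestLikelihoodForms:
    def test_per_cell_sum_equals_binomial_count_form(self, table):
        """Positive counts are sufficient statistics: the per-cell-product
        and binomial-kernel forms agree to 1e-9 on random phenotype sets."""
        rng = np.random.default_rng(77)
        for cells in _random_instances(rng, 100, FEMALE_PANEL, max_cells=8):
            counts = {m: sum(c.marker_calls[m] for c in cells) for m in FEMALE_PANEL}
            for t in table.tissues:
                per_cell = sum(cell_log_likelihood(c, t, table) for c in cells)
                binom = binomial_log_likelihood(counts, len(cells), t, table)
                assert per_cell == pytest.approx(binom, abs=1e-9)


class TestPopulationPosterior:
    def test_constant_table_gives_uniform_posterior(self):
        table = FrequencyTable(
            tissues=("breast", "lung", "colon"), markers=("CK7", "CK20"),
            raw={t: {"CK7": 0.4, "CK20": 0.6} for t in ("breast", "lung", "colon")},
        )
        cells = _cells(("CK7", "CK20"), [(True, False)])
        result = population_posterior(cells, table)
        for v in result.posterior.values():
            assert v == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert result.call == INDETERMINATE

    def test_matches_brute_force_oracle_on_small_instances(self, table):
        rng = np.random.default_rng(123)
        for cells in _random_instances(rng, 100, FEMALE_PANEL):
            expected = brute_force_posterior(cells, table)
            result = population_posterior(cells, table)
            for t in table.tissues:
                assert result.posterior[t] == pytest.approx(expected[t], abs=1e-9)

    def test_posterior_normalisation_property(self, table):
        rng = np.random.default_rng(5)
        for cells in _random_instances(rng, 50, MALE_PANEL, max_cells=20):
            result = population_posterior(cells, table)
            assert abs(sum(result.posterior.values()) - 1.0) <= 1e-9

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.tuples(*[st.booleans()] * 4), min_size=1, max_size=12),
        st.sampled_from(["uniform", "weighted"]),
    )
    def test_posterior_sums_to_one_for_any_input(self, table, rows, prior_kind):
        cells = _cells(FEMALE_PANEL, rows)
        prior = (
            "uniform" if prior_kind == "uniform"
            else {"prostate": 0.1, "breast": 0.4, "colon": 0.2, "lung": 0.3}
        )
        result = population_posterior(cells, table, prior=prior)
        assert abs(sum(result.posterior.values()) - 1.0) <= 1e-9

    def test_empty_input_is_indeterminate_with_reason(self, table):
        result = population_posterior([], table)
        assert result.call == INDETERMINATE
        assert result.n_cells_used == 0
        assert result.reason

    def test_ctc_filter_excludes_non_ctcs(self, table):
        ctc = _cells(FEMALE_PANEL, [(True, False, False, False)])[0]
        bystander = CellPhenotype(roi_label=9, nuclear_positive=True,
                                  marker_calls=dict(zip(FEMALE_PANEL, (False,) * 4)),
                                  is_ctc=False)
        result = population_posterior([ctc, bystander], table)
        assert result.n_cells_used == 1
        both = population_posterior([ctc, bystander], table, use_ctc_only=False)
        assert both.n_cells_used == 2

    def test_prostate_posterior_monotone_in_psa_positive_count(self, table):
        """Adding PSA-positive cells (others fixed) never lowers the
        prostate posterior when PSA peaks in prostate."""
        base_rows = [(True, False, False, False)] * 3
        last = None
        for k in range(0, 12):
            rows = base_rows + [(False, False, False, True)] * k
            result = population_posterior(_cells(MALE_PANEL, rows), table)
            p = result.posterior["prostate"]
            if last is not None:
                assert p >= last - 1e-12
            last = p

    def test_simulated_prostate_profiles_call_prostate_confidently(self, table):
        """100 prostate-frequency cells give a >0.99 prostate posterior,
        across many seeds."""
        for seed in range(100):
            states = sample_marker_states("prostate", table, n=100, seed=seed,
                                          markers=MALE_PANEL)
            rows = [tuple(bool(v) for v in r) for r in states.to_numpy()]
            result = population_posterior(_cells(MALE_PANEL, rows), table)
            assert result.call == "prostate"
            assert result.posterior["prostate"] > 0.99

    def test_invalid_prior_rejected(self, table):
        cells = _cells(FEMALE_PANEL, [(True, False, False, False)])
        with pytest.raises(ConfigurationError):
            population_posterior(cells, table, prior={"breast": 1.0})
        with pytest.raises(ConfigurationError):
            population_posterior(
                cells, table,
                prior={"prostate": 0.5, "breast": 0.5, "colon": 0.5, "lung": 0.5},
            )


class TestClassify:
    def test_clear_winner_is_called(self):
        call, margin, tie = classify({"a": 0.97, "b": 0.01, "c": 0.01, "d": 0.01},
                                     call_margin=0.1)
        assert call == "a" and margin == pytest.approx(0.96) and not tie

    def test_uniform_posterior_is_indeterminate(self):
        call, margin, tie = classify({t: 0.25 for t in "abcd"}, call_margin=1e-6)
        assert call == INDETERMINATE and margin == 0.0

    def test_exact_tie_breaks_by_canonical_order_and_flags(self):
        call, margin, tie = classify({"b": 0.45, "a": 0.45, "c": 0.05, "d": 0.05},
                                     call_margin=0.1, tissue_order=["a", "b", "c", "d"])
        assert call == "a" and tie and margin == pytest.approx(0.40)


class TestLabelRecoveryFromSampledProfiles:
    @pytest.mark.parametrize("tissue,sex", [
        ("prostate", "male"), ("breast", "female"), ("colon", "female"), ("lung", "male"),
    ])
    def test_sampled_populations_recover_their_tissue(self, table, tissue, sex):
        panel = MALE_PANEL if sex == "male" else FEMALE_PANEL
        hits = 0
        for seed in range(20):
            states = sample_marker_states(tissue, table, n=50, seed=1000 + seed,
                                          markers=panel)
            rows = [tuple(bool(v) for v in r) for r in states.to_numpy()]
            result = population_posterior(_cells(panel, rows), table)
            hits += result.call == tissue
        assert hits == 20


def test_er_heterogeneous_breast_scene_still_called_breast(table):
    """A breast population with only 21.7% ER-positive cells (dynamic ER
    heterogeneity) is still classified as breast through the full image
    pipeline."""
    from ctc_origin import ThresholdPolicy, assemble_phenotypes, measure_scene, segment_nuclei

    cfg = SceneConfig(tissue_type="breast", sex="female", seed=77,
                      n_tumor_cells=60, n_leukocytes=15,
                      frequency_overrides={"ER": 0.217})
    images, _ = generate_scene(cfg, table)
    rois = segment_nuclei(images["nuclear"])
    meas = measure_scene(images, rois, ThresholdPolicy.kfold(1.0), channels=list(images))
    phenotypes = assemble_phenotypes(meas, list(cfg.panel))
    result = population_posterior(phenotypes, table, sex="female")
    assert result.call == "breast"
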