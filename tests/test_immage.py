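"""IMM-AGE scorer: trimmed standardization, diffusion map, pseudotime."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immflow.immage import (
    DegenerateFeatureError,
    IMMAGE_FEATURES,
    ImmAgeScorer,
    InsufficientSamplesError,
    build_diffusion_map,
    compute_immage,
    pseudotime_scores,
    select_root,
    trimmed_standardize,
)
from immflow.synthetic import SimConfig, cohort_frames


def collinear_points(n=10, dim=8):
    direction = np.ones(dim) / np.sqrt(dim)
    return np.outer(np.arange(float(n)), direction)


class TestTrimmedStandardize:
    def test_one_to_ten_with_ten_percent_trim(self):
        """k = floor(0.1*10) = 1 value trimmed per tail, leaving 2..9."""
        z, mean, sd = trimmed_standardize(np.arange(1.0, 11.0), 0.10)
        assert mean == pytest.approx(5.5, abs=1e-12)
        assert sd == pytest.approx(np.sqrt(6.0), abs=1e-12)
        assert z[0] == pytest.approx((1 - 5.5) / np.sqrt(6.0), abs=1e-12)

    def test_brute_force_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=37)
        z, mean, sd = trimmed_standardize(x, 0.10)
        k = int(np.floor(0.10 * x.size))
        core = np.sort(x)[k: x.size - k]
        assert mean == pytest.approx(core.mean(), abs=1e-12)
        assert sd == pytest.approx(core.std(ddof=1), abs=1e-12)
        np.testing.assert_allclose(z, (x - core.mean()) / core.std(ddof=1), atol=1e-12)

    def test_zero_trim_reduces_to_zscore(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 3.0, size=50)
        z, mean, sd = trimmed_standardize(x, 0.0)
        np.testing.assert_allclose(z, (x - x.mean()) / x.std(ddof=1), atol=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            trimmed_standardize(np.full(10, 3.0), 0.10)

    @pytest.mark.parametrize("bad", [-0.1, 0.5, 0.7])
    def test_invalid_trim_fraction(self, bad):
        with pytest.raises(ValueError):
            trimmed_standardize(np.arange(10.0), bad)


class TestDiffusionMap:
    def test_markov_spectrum(self):
        rng = np.random.default_rng(1)
        lam, _ = build_diffusion_map(rng.normal(size=(30, 8)))
        assert np.all(lam <= 1.0 + 1e-12)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_identical_samples_coincide_in_embedding(self):
        X = np.vstack([collinear_points(9), collinear_points(9)[4]])
        _, emb = build_diffusion_map(X)
        np.testing.assert_allclose(emb[4], emb[-1], atol=1e-9)

    def test_first_component_monotone_for_collinear_points(self):
        _, emb = build_diffusion_map(collinear_points())
        diffs = np.diff(emb[:, 0])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSamplesError):
            build_diffusion_map(np.zeros((5, 8)))

    def test_non_finite_input(self):
        X = np.zeros((10, 8))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            build_diffusion_map(X)


class TestPseudotime:
    def test_root_scores_zero_and_ranks_match_line_position(self):
        _, emb = build_diffusion_map(collinear_points())
        raw = pseudotime_scores(emb, 0)
        assert raw[0] == 0.0
        assert np.array_equal(np.argsort(raw), np.arange(10))

    def test_far_endpoint_root_reverses_order(self):
        _, emb = build_diffusion_map(collinear_points())
        raw = pseudotime_scores(emb, 9)
        assert np.array_equal(np.argsort(raw), np.arange(9, -1, -1))


class TestSelectRoot:
    def test_argmin(self):
        v = pd.Series({"a": 40.0, "b": 5.0, "c": 60.0})
        assert select_root(v) == "b"

    def test_tie_breaks_lexicographically(self):
        v = pd.Series({"b": 5.0, "a": 5.0, "c": 60.0})
        assert select_root(v) == "a"

    def test_explicit_rule(self):
        v = pd.Series({"a": 40.0, "b": 5.0})
        assert select_root(v, "explicit:a") == "a"
        with pytest.raises(KeyError):
            select_root(v, "explicit:zz")


class TestScorerPipeline:
    def test_scores_span_unit_interval_and_root_is_zero(self, default_cohort):
        _, _, panels = default_cohort
        result = compute_immage(panels)
        assert result.scores.min() == 0.0
        assert result.scores.max() == 1.0
        assert result.scores.loc[result.root_id] == 0.0
        assert ((result.scores >= 0) & (result.scores <= 1)).all()

    def test_missing_required_feature_excludes_sample(self, default_cohort):
        _, _, panels = default_cohort
        panels = panels.copy()
        victim = panels.subject_id.iloc[3]
        panels.loc[panels.subject_id == victim, "treg_of_cd4"] = np.nan
        result = compute_immage(panels)
        assert victim in result.excluded_ids
        assert victim not in result.scores.index

    def test_scores_invariant_under_row_permutation(self, default_cohort):
        _, _, panels = default_cohort
        r1 = compute_immage(panels)
        shuffled = panels.sample(frac=1.0, random_state=3)
        r2 = compute_immage(shuffled)
        pd.testing.assert_series_equal(
            r1.scores.sort_index(), r2.scores.sort_index(),
            atol=1e-9, check_exact=False,
        )

    def test_orientation_follows_senescence_gradient(self, default_cohort):
        _, _, panels = default_cohort
        result = compute_immage(panels)
        cd28neg = panels.set_index("subject_id").loc[
            result.scores.index, "cd8_cd28neg"
        ]
        assert sps.spearmanr(result.scores, cd28neg).statistic >= 0.0

    def test_deterministic_given_inputs(self, default_cohort):
        _, _, panels = default_cohort
        s1 = compute_immage(panels).scores
        s2 = compute_immage(panels).scores
        assert (s1.to_numpy() == s2.to_numpy()).all()

    def test_hc_only_cohort_score_tracks_age(self):
        cfg = SimConfig(n_controls=200, n_trauma=1, seed=12)
        subjects, panels = cohort_frames(cfg)
        hc_panels = panels[panels.subject_id.str.startswith("HC")]
        result = compute_immage(hc_panels)
        ages = subjects.set_index("subject_id").loc[result.scores.index, "age_years"]
        assert np.corrcoef(result.scores, ages)[0, 1] > 0

    def test_sklearn_estimator_contract(self, default_cohort):
        _, _, panels = default_cohort
        scorer = ImmAgeScorer(n_components=2)
        assert scorer.get_params()["n_components"] == 2
        out = scorer.set_params(n_components=3).fit_transform(panels)
        assert out.shape[0] == len(scorer.scores_)
        assert scorer.embedding_.shape[1] == 3

    def test_missing_feature_column_raises(self, default_cohort):
        _, _, panels = default_cohort
        with pytest.raises(KeyError, match="treg_of_cd4"):
            ImmAgeScorer().fit(panels.drop(columns=["treg_of_cd4"]))

    def test_degenerate_feature_named_in_error(self, default_cohort):
        _, _, panels = default_cohort
        panels = panels.copy()
        panels["cd8_emra"] = 50.0
        with pytest.raises(DegenerateFeatureError, match="cd8_emra"):
            compute_immage(panels)

    def test_insufficient_complete_samples(self, default_cohort):
        _, _, panels = default_cohort
        with pytest.raises(InsufficientSamplesError):
            compute_immage(panels.head(5))
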