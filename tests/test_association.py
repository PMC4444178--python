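import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvcc.association import (
    AssociationConfig,
    SegmentAssociationModel,
    build_design,
    firth_logistic,
    genomewide_permutation,
    segment_statistic,
    stratified_analysis,
)
from cnvcc.qc import apply_qc
from cnvcc.segmentation import Segment, SegmentMatrix, build_matrix, build_segments
from cnvcc.simulate import PlantedEffect, SimulationConfig, simulate_cohort
from cnvcc.types import Group, SubjectRecord


def _subjects(n_cases, n_controls, batches=1, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cases + n_controls):
        out.append(
            SubjectRecord(
                f"s{i}", Group.SUICIDE if i < n_cases else Group.CONTROL,
                batch=f"B{rng.integers(batches) + 1}",
            )
        )
    return out


def _matrix(carrier: np.ndarray) -> SegmentMatrix:
    n, m = carrier.shape
    segs = [Segment("1", 1000 + 10_000 * j, 6000 + 10_000 * j) for j in range(m)]
    state = np.where(carrier, 1, 2).astype(np.int16)
    return SegmentMatrix(segments=segs, sample_ids=[f"s{i}" for i in range(n)], copy_state=state)


def test_null_segment_statistic_near_zero():
    """Equal carrier frequency in both groups gives p ~ 1."""
    carrier = np.zeros(200)
    carrier[:5] = 1  # 5/100 cases
    carrier[100:105] = 1  # 5/100 controls
    y = np.concatenate([np.ones(100), np.zeros(100)])
    cfg = AssociationConfig(statistic="fisher_exact", covariates=())
    stat, p = segment_statistic(carrier, y, None, cfg)
    assert p == 1.0 and stat == 0.0


def test_fisher_matches_hypergeometric_enumeration():
    """Case-only carriers (8/475 vs 0/1133) against a direct enumeration oracle."""
    n_case, n_ctrl, a = 475, 1133, 8
    carrier = np.concatenate([np.ones(a), np.zeros(n_case - a + n_ctrl)])
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    cfg = AssociationConfig(statistic="fisher_exact", covariates=())
    _, p = segment_statistic(carrier, y, None, cfg)
    # oracle: two-sided hypergeometric sum over tables with pmf <= pmf(obs)
    n = n_case + n_ctrl
    pmf = [stats.hypergeom.pmf(k, n, n_case, a) for k in range(a + 1)]
    expected = sum(q for q in pmf if q <= pmf[a] * (1 + 1e-7))
    assert p == pytest.approx(expected, rel=1e-9)


def test_zero_carriers_untestable_and_constant_labels_error():
    y = np.concatenate([np.ones(5), np.zeros(5)])
    cfg = AssociationConfig(statistic="fisher_exact", covariates=())
    assert segment_statistic(np.zeros(10), y, None, cfg) == (0.0, 1.0)
    with pytest.raises(ValueError, match="constant"):
        segment_statistic(np.ones(10), np.ones(10), None, cfg)


def test_independent_batch_covariate_leaves_estimate_unchanged():
    """A batch orthogonal to carrier and status barely moves the Firth estimate."""
    rng = np.random.default_rng(4)
    n = 1000
    y = (rng.random(n) < 0.3).astype(float)
    carrier = (rng.random(n) < 0.15 + 0.1 * y).astype(float)
    subjects = [
        SubjectRecord(f"s{i}", Group.SUICIDE if y[i] else Group.CONTROL,
                      batch=f"B{rng.integers(2) + 1}")
        for i in range(n)
    ]
    X_unadj = np.column_stack([np.ones(n), carrier])
    beta_u, _, _ = firth_logistic(X_unadj, y)
    X_adj = np.column_stack([build_design(subjects, ("batch",)), carrier])
    beta_a, _, _ = firth_logistic(X_adj, y)
    assert beta_a[-1] == pytest.approx(beta_u[-1], abs=0.05)


def test_firth_finite_under_complete_separation():
    """Case-only carriers give a finite penalised estimate with finite SE."""
    y = np.concatenate([np.ones(50), np.zeros(100)])
    carrier = np.concatenate([np.ones(8), np.zeros(142)])
    X = np.column_stack([np.ones(150), carrier])
    beta, se, converged = firth_logistic(X, y)
    assert converged and np.isfinite(beta).all() and np.isfinite(se).all()
    assert beta[-1] > 1.0  # strong positive effect


def test_firth_agrees_with_mle_away_from_separation():
    rng = np.random.default_rng(7)
    n = 4000
    x = (rng.random(n) < 0.3).astype(float)
    p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
    y = (rng.random(n) < p).astype(float)
    import statsmodels.api as sm

    X = np.column_stack([np.ones(n), x])
    mle = sm.Logit(y, X).fit(disp=0)
    beta, se, _ = firth_logistic(X, y)
    assert beta[1] == pytest.approx(mle.params[1], abs=0.02)
    assert se[1] == pytest.approx(mle.bse[1], rel=0.05)


def _exhaustive_oracle_fisher(carrier_mat, y):
    """Brute-force genome-wide p over all case/control assignments."""
    n = len(y)
    k = int(y.sum())
    m = carrier_mat.shape[1]
    n_carr = carrier_mat.sum(axis=0)

    def pointwise(yv):
        ps = []
        for j in range(m):
            c = carrier_mat[:, j]
            if c.sum() in (0, n):
                ps.append(1.0)
                continue
            a = int(c[yv == 1].sum())
            tab = [[a, k - a], [int(c.sum()) - a, n - k - int(c.sum()) + a]]
            ps.append(stats.fisher_exact(tab)[1])
        return np.array(ps)

    p_obs = pointwise(y)
    mins = []
    points = []
    for combo in itertools.combinations(range(n), k):
        yv = np.zeros(n)
        yv[list(combo)] = 1
        ps = pointwise(yv)
        mins.append(ps.min())
        points.append(ps)
    mins = np.array(mins)
    points = np.array(points)
    gw = [(mins <= p_obs[j] * (1 + 1e-12)).mean() for j in range(m)]
    pw = [(points[:, j] <= p_obs[j] * (1 + 1e-12)).mean() for j in range(m)]
    return np.array(gw), np.array(pw)


def test_exhaustive_permutation_equals_enumeration_oracle():
    """6 subjects, 3 cases, 3 segments: all 20 assignments enumerated exactly."""
    carrier = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
            [1, 0, 0],
        ],
        dtype=bool,
    )
    y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
    subjects = _subjects(3, 3)
    cfg = AssociationConfig(statistic="fisher_exact", covariates=(), seed=5)
    res = genomewide_permutation(_matrix(carrier), subjects, cfg, exhaustive=True)
    gw_oracle, pw_oracle = _exhaustive_oracle_fisher(carrier.astype(float), y)
    assert np.allclose(res["p_genomewide"].to_numpy(), gw_oracle)
    assert np.allclose(res["p_pointwise"].to_numpy(), pw_oracle)


def test_constant_carrier_all_genomewide_p_one():
    carrier = np.ones((10, 4), dtype=bool)
    subjects = _subjects(5, 5)
    cfg = AssociationConfig(n_permutations=200, statistic="score_test", covariates=(), seed=1)
    res = genomewide_permutation(_matrix(carrier), subjects, cfg)
    assert (res["p_genomewide"] == 1.0).all()
    assert (res["p_pointwise"] == 1.0).all()


def test_genomewide_p_at_least_pointwise_and_order_invariant():
    rng = np.random.default_rng(12)
    carrier = rng.random((60, 15)) < 0.1
    subjects = _subjects(20, 40, batches=2, seed=3)
    cfg = AssociationConfig(n_permutations=300, statistic="score_test", seed=9)
    res = genomewide_permutation(_matrix(carrier), subjects, cfg)
    assert (res["p_genomewide"] >= res["p_pointwise"] - 1e-12).all()
    # permute segment order: p-values follow their segments
    perm = rng.permutation(15)
    res2 = genomewide_permutation(_matrix(carrier[:, perm]), subjects, cfg)
    assert np.allclose(res2["p_genomewide"].to_numpy(), res["p_genomewide"].to_numpy()[perm])
    # identical seed -> identical output
    res3 = genomewide_permutation(_matrix(carrier), subjects, cfg)
    pd.testing.assert_frame_equal(res, res3)


def test_null_pointwise_pvalues_superuniform():
    """On a null cohort, P(p <= a) <= a + tolerance for testable segments."""
    rng = np.random.default_rng(77)
    carrier = rng.random((200, 60)) < 0.08
    subjects = _subjects(66, 134, batches=2, seed=5)
    cfg = AssociationConfig(n_permutations=1000, statistic="score_test", seed=2)
    res = genomewide_permutation(_matrix(carrier), subjects, cfg)
    testable = res["p_pointwise"] < 1.0
    p = res.loc[testable, "p_pointwise"].to_numpy()
    for a in (0.1, 0.25, 0.5):
        frac = (p <= a).mean()
        se = math.sqrt(a * (1 - a) / len(p))
        assert frac <= a + 4 * se + 0.05


def test_batch_stratified_permutation_preserves_batch_totals():
    from cnvcc.association import _permuted_labels, _strata

    subjects = _subjects(30, 70, batches=3, seed=8)
    y = np.array([float(s.is_case) for s in subjects])
    strata = _strata(subjects, ("batch",))
    Y = _permuted_labels(y, strata, 50, np.random.default_rng(0))
    for s in np.unique(strata):
        assert np.allclose(Y[:, strata == s].sum(axis=1), y[strata == s].sum())


def test_stratified_analysis_recovers_group_specific_effect():
    """An effect planted only in suicides is flagged there, not in attempters."""
    cfg = SimulationConfig(
        n_cases=200, n_controls=400, suicide_fraction_of_cases=0.5,
        n_loci=40, freq_range=(0.01, 0.05), n_batches=2,
        planted_effects=(PlantedEffect(locus=0, odds_ratio=10.0, target_group="suicide"),),
        seed=42,
    )
    cohort, truth = simulate_cohort(cfg)
    cohort, _ = apply_qc(cohort)
    acfg = AssociationConfig(n_permutations=500, seed=3, statistic="score_test")
    results = stratified_analysis(cohort, acfg)
    loc = truth.loci[0]
    for name, frame in results.items():
        hit = frame[(frame["chrom"] == loc.chrom) & (frame["start"] == loc.start)]
        assert len(hit) == 1
        p = float(hit["p_genomewide"].iloc[0])
        if name == "suicides_vs_controls":
            assert p < 0.05
        elif name == "attempters_vs_controls":
            assert p > 0.05


def test_stratified_analysis_errors_on_empty_stratum():
    cfg = SimulationConfig(n_cases=20, n_controls=40, suicide_fraction_of_cases=1.0,
                           n_loci=10, freq_range=(0.05, 0.2), seed=6)
    cohort, _ = simulate_cohort(cfg)
    with pytest.raises(ValueError, match="attempters"):
        stratified_analysis(cohort, AssociationConfig(n_permutations=100, seed=1))


def test_model_fit_reports_firth_or_and_detects_planted_locus(planted_cohort):
    cohort, truth = planted_cohort
    cohort, _ = apply_qc(cohort)
    cfg = AssociationConfig(n_permutations=1000, seed=17)
    results = SegmentAssociationModel.from_cohort(cohort, cfg).fit()
    loc = truth.loci[0]
    hit = results.frame[
        (results.frame["chrom"] == loc.chrom) & (results.frame["start"] == loc.start)
    ]
    assert len(hit) == 1
    assert float(hit["p_genomewide"].iloc[0]) < 0.05
    assert float(hit["odds_ratio"].iloc[0]) > 2.0
    assert "genome-wide hits" in results.summary()


def test_config_validation():
    with pytest.raises(ValueError):
        AssociationConfig(n_permutations=50)
    with pytest.raises(ValueError):
        AssociationConfig(statistic="t_test")
    with pytest.raises(ValueError):
        AssociationConfig(covariates=("ancestry",))
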