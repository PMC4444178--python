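import numpy as np
import pandas as pd
import pytest

from cnvcc.burden import (
    BurdenModel,
    DEFAULT_RULES,
    RarityRule,
    burden_regression,
    mean_burden_ratio,
    per_subject_burden,
    rare_mask,
)
from cnvcc.qc import apply_qc
from cnvcc.segmentation import Segment, SegmentMap, SegmentMatrix, build_matrix, build_segments, frequency_table
from cnvcc.simulate import SimulationConfig, simulate_cohort
from cnvcc.types import Group, SubjectRecord


def _matrix(carrier, spans=None):
    n, m = carrier.shape
    spans = spans if spans is not None else [50_000] * m
    pos = 1000
    segs = []
    for sp in spans:
        segs.append(Segment("1", pos, pos + sp))
        pos += sp + 10_000
    state = np.where(carrier, 1, 2).astype(np.int16)
    return SegmentMatrix(segments=segs, sample_ids=[f"s{i}" for i in range(n)], copy_state=state)


def _subjects(n_cases, n_controls, batches=1, seed=0):
    rng = np.random.default_rng(seed)
    return [
        SubjectRecord(f"s{i}", Group.SUICIDE if i < n_cases else Group.CONTROL,
                      batch=f"B{rng.integers(batches) + 1}")
        for i in range(n_cases + n_controls)
    ]


def test_rarity_rule_validation_and_labels():
    assert RarityRule("frequency", 0.005).comparator == "le"
    assert RarityRule("size", 100_000).comparator == "ge"
    with pytest.raises(ValueError):
        RarityRule("frequency", 0.005, comparator="ge")
    with pytest.raises(ValueError):
        RarityRule("density", 1)
    assert RarityRule("size", 100_000).label == "size>=100kb"


def test_rare_mask_frequency_and_size_boundaries():
    freq = pd.DataFrame({"freq": [0.004, 0.008, 0.0]})
    smap = SegmentMap(by_chrom={"1": [
        Segment("1", 1000, 100_999),    # 99,999 bp
        Segment("1", 300_000, 400_000),  # 100,000 bp
        Segment("1", 600_000, 800_000),
    ]})
    m = rare_mask(freq, smap, RarityRule("frequency", 0.005))
    assert m.tolist() == [True, False, True]  # 0.4% rare, 0.8% not, 0 always rare
    m = rare_mask(freq, smap, RarityRule("size", 100_000))
    assert m.tolist() == [False, True, True]


def test_per_subject_burden_cap_and_brute_force():
    rng = np.random.default_rng(3)
    carrier = rng.random((40, 30)) < 0.5
    mx = _matrix(carrier)
    mask = rng.random(30) < 0.7
    burden = per_subject_burden(mx, mask, cap=20)
    uncapped = carrier[:, mask].sum(axis=1)
    assert (burden == np.minimum(uncapped, 20)).all()
    # a subject carrying 25 rare segments is truncated at 20
    heavy = np.zeros((1, 30), dtype=bool)
    heavy[0, :25] = True
    assert per_subject_burden(_matrix(heavy), np.ones(30, dtype=bool), 20)[0] == 20
    # no-call subject counts zero; huge cap equals brute force
    assert per_subject_burden(_matrix(np.zeros((1, 30), dtype=bool)), mask, 20)[0] == 0
    assert (per_subject_burden(mx, mask, cap=10**9) == uncapped).all()
    with pytest.raises(ValueError):
        per_subject_burden(mx, mask, cap=0)


def test_rarity_nesting_is_monotone(planted_cohort):
    """freq<=0.1% within <=0.5% within <=1%; size>=500kb within >=200kb within >=100kb."""
    cohort, _ = planted_cohort
    cohort, _ = apply_qc(cohort)
    smap = build_segments(cohort.calls)
    mx = build_matrix(cohort.calls, smap, cohort.subjects)
    freq = frequency_table(mx, cohort.subjects)
    masks = {r.label: rare_mask(freq, smap, r) for r in DEFAULT_RULES}
    assert (masks["freq<=0.1%"] <= masks["freq<=0.5%"]).all()
    assert (masks["freq<=0.5%"] <= masks["freq<=1%"]).all()
    assert (masks["size>=500kb"] <= masks["size>=200kb"]).all()
    assert (masks["size>=200kb"] <= masks["size>=100kb"]).all()


def test_zero_burden_untestable():
    res = burden_regression(np.zeros(50), _subjects(20, 30))
    assert not res.testable and res.p_raw == 1.0 and np.isnan(res.or_per_cnv)


def test_bonferroni_arithmetic_exact():
    rng = np.random.default_rng(9)
    burden = rng.poisson(0.8, 300).astype(float)
    res = burden_regression(burden, _subjects(100, 200, batches=2), n_settings=6)
    assert res.p_bonferroni == min(1.0, 6 * res.p_raw)


def test_burden_regression_recovers_planted_slope():
    """Counts drawn with true OR 1.5 per CNV give an estimate near 1.5."""
    rng = np.random.default_rng(21)
    n_case, n_ctrl = 475, 1133
    ests = []
    for _ in range(30):
        k = np.concatenate([
            np.minimum(rng.poisson(1.0 * 1.5, n_case), 20),
            np.minimum(rng.poisson(1.0, n_ctrl), 20),
        ]).astype(float)
        res = burden_regression(k, _subjects(n_case, n_ctrl))
        ests.append(np.log(res.or_per_cnv))
    mean = np.mean(ests)
    sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(mean - np.log(1.5)) < 3 * sem + 0.02


def test_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(5)
    ps = []
    for _ in range(100):
        burden = rng.poisson(1.0, 400).astype(float)
        ps.append(burden_regression(burden, _subjects(130, 270)).p_raw)
    ps = np.array(ps)
    assert 0.2 < (ps < 0.5).mean() < 0.8  # crude uniformity band
    assert (ps < 0.05).mean() < 0.15


def test_mean_burden_ratio_identity_and_planted():
    rng = np.random.default_rng(13)
    subjects = _subjects(200, 400)
    same = np.tile(rng.poisson(1.0, 600), 1).astype(float)
    ratio, p = mean_burden_ratio(same, subjects, n_permutations=300, seed=1)
    # identical generating distribution: ratio near 1, p not small
    assert 0.8 < ratio < 1.25
    # planted 1.2x case mean
    k = np.concatenate([rng.poisson(1.2, 200), rng.poisson(1.0, 400)]).astype(float)
    ratio2, _ = mean_burden_ratio(k, subjects, n_permutations=300, seed=2)
    assert ratio2 == pytest.approx(k[:200].mean() / k[200:].mean())
    assert 1.0 < ratio2 < 1.45
    # undefined with zero control mean
    z = np.concatenate([np.ones(200), np.zeros(400)])
    r, p = mean_burden_ratio(z, subjects, n_permutations=100, seed=3)
    assert np.isnan(r) and np.isnan(p)


def test_mean_ratio_permutation_calibrated_on_null():
    rng = np.random.default_rng(31)
    subjects = _subjects(60, 140)
    rejections = 0
    reps = 60
    for i in range(reps):
        k = rng.poisson(1.0, 200).astype(float)
        _, p = mean_burden_ratio(k, subjects, n_permutations=400, seed=i)
        rejections += p < 0.05
    assert rejections / reps < 0.15


def test_burden_model_end_to_end(planted_cohort):
    cohort, _ = planted_cohort
    cohort, _ = apply_qc(cohort)
    smap = build_segments(cohort.calls)
    mx = build_matrix(cohort.calls, smap, cohort.subjects)
    freq = frequency_table(mx, cohort.subjects)
    results = BurdenModel(mx, freq, smap, cohort.subjects).fit(ratio_permutations=200, seed=4)
    frame = results.frame
    assert len(frame) == 6
    testable = frame[frame["or_per_cnv"].notna()]
    assert (frame["p_bonferroni"] >= frame["p_raw"] - 1e-12).all()
    assert "Rare-CNV burden" in results.summary()
    assert (testable["total_rare_cnvs"] >= 0).all()
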