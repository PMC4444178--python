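"""Rare-CNV burden analysis.

Rare segments are defined either by population carrier frequency
(<= 0.1%, 0.5% or 1.0%, computed on the full post-QC cohort) or by
size (>= 100 kb, 200 kb or 500 kb).  Each subject's burden is the
number of rare carrier segments it carries, truncated at 20 so that
single outlier individuals cannot drive group effects.  Case status is
regressed on the burden count with logistic regression adjusted for
assay batch; the odds ratio per additional rare CNV is the
exponentiated slope, and p-values are Bonferroni-corrected across the
six rarity settings.  A complementary descriptive comparison reports
the case/control ratio of mean burden with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import build_design
from .segmentation import SegmentMap, SegmentMatrix
from .types import SubjectRecord

N_SETTINGS_DEFAULT = 6
CAP_DEFAULT = 20


@dataclass(frozen=True)
class RarityRule:
    """Definition of 'rare': by carrier frequency (<=) or by size (>=)."""

    kind: str  # "frequency" | "size"
    threshold: float  # frequency in [0,1] or size in bp
    comparator: str = ""  # derived: "le" for frequency, "ge" for size

    def __post_init__(self) -> None:
        if self.kind not in ("frequency", "size"):
            raise ValueError("kind must be 'frequency' or 'size'")
        cmp = "le" if self.kind == "frequency" else "ge"
        if self.comparator and self.comparator != cmp:
            raise ValueError(f"{self.kind} rules must use comparator {cmp!r}")
        object.__setattr__(self, "comparator", cmp)
        if self.kind == "frequency" and not (0 <= self.threshold <= 1):
            raise ValueError("frequency threshold must be in [0, 1]")
        if self.kind == "size" and self.threshold <= 0:
            raise ValueError("size threshold must be positive")

    @property
    def label(self) -> str:
        if self.kind == "frequency":
            return f"freq<={100 * self.threshold:g}%"
        return f"size>={self.threshold / 1000:g}kb"


DEFAULT_RULES: tuple[RarityRule, ...] = (
    RarityRule("frequency", 0.001),
    RarityRule("frequency", 0.005),
    RarityRule("frequency", 0.01),
    RarityRule("size", 100_000),
    RarityRule("size", 200_000),
    RarityRule("size", 500_000),
)


def rare_mask(freq_table: pd.DataFrame, segments: SegmentMap, rule: RarityRule) -> np.ndarray:
    """Boolean per segment: does it qualify as rare under ``rule``?

    Frequency rules compare the overall carrier frequency (full-cohort
    denominator); size rules compare the segment span in bp.
    """
    if rule.kind == "frequency":
        return (freq_table["freq"].to_numpy() <= rule.threshold + 1e-12)
    spans = np.array([s.span_bp for s in segments.all_segments()])
    return spans >= rule.threshold


def per_subject_burden(matrix: SegmentMatrix, mask: np.ndarray, cap: int = CAP_DEFAULT) -> np.ndarray:
    """Count of rare carrier segments per subject, truncated at ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != matrix.n_segments:
        raise ValueError("mask not aligned to segments")
    counts = matrix.carrier[:, mask].sum(axis=1)
    return np.minimum(counts, cap).astype(int)


@dataclass
class BurdenResult:
    """One rarity setting's regression output."""

    rule: RarityRule
    n_rare_segments: int
    total_rare_cnvs: int  # carrier events summed over subjects (uncapped)
    or_per_cnv: float
    p_raw: float
    p_bonferroni: float
    n_settings: int
    testable: bool = True

    def __post_init__(self) -> None:
        assert self.p_bonferroni == min(1.0, self.p_raw * self.n_settings) or not self.testable


def burden_regression(
    burden: np.ndarray,
    subjects: list[SubjectRecord],
    covariates: tuple[str, ...] = ("batch",),
    n_settings: int = N_SETTINGS_DEFAULT,
    rule: RarityRule | None = None,
    n_rare_segments: int = 0,
    total_rare_cnvs: int | None = None,
) -> BurdenResult:
    """Logistic regression of case status on the per-subject burden count.

    ``or_per_cnv`` is the exponentiated slope; ``p_raw`` the two-sided
    Wald p; ``p_bonferroni = min(1, p_raw * n_settings)``.  Zero
    variance in burden makes the setting untestable (OR undefined,
    p = 1, flagged).
    """
    burden = np.asarray(burden, dtype=float)
    y = np.array([float(s.is_case) for s in subjects])
    if y.min() == y.max():
        raise ValueError("both cases and controls are required")
    rule = rule or RarityRule("frequency", 1.0)
    total = int(total_rare_cnvs) if total_rare_cnvs is not None else int(burden.sum())
    if burden.std() == 0:
        return BurdenResult(
            rule=rule, n_rare_segments=n_rare_segments, total_rare_cnvs=total,
            or_per_cnv=float("nan"), p_raw=1.0, p_bonferroni=1.0,
            n_settings=n_settings, testable=False,
        )
    X = np.column_stack([build_design(subjects, covariates), burden])
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(fit.params[-1])
        p_raw = float(fit.pvalues[-1])
    except Exception:
        # sparse or separated burden distributions: Firth penalisation
        from .association import firth_logistic

        beta, se, _ = firth_logistic(X, y)
        slope = float(beta[-1])
        z = slope / se[-1] if se[-1] > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
    return BurdenResult(
        rule=rule, n_rare_segments=n_rare_segments, total_rare_cnvs=total,
        or_per_cnv=float(np.exp(slope)), p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_settings), n_settings=n_settings,
    )


def mean_burden_ratio(
    burden: np.ndarray,
    subjects: list[SubjectRecord],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Case/control ratio of mean burden with a permutation two-sided p.

    The statistic is |log ratio|; labels are permuted freely.  A zero
    control mean leaves the ratio undefined (NaN, NaN).
    """
    burden = np.asarray(burden, dtype=float)
    y = np.array([s.is_case for s in subjects])
    n_case = int(y.sum())
    if n_case == 0 or n_case == len(y):
        raise ValueError("both cases and controls are required")
    mean_ctrl = burden[~y].mean()
    if mean_ctrl == 0:
        return float("nan"), float("nan")
    ratio = burden[y].mean() / mean_ctrl
    rng = np.random.default_rng(seed)
    tot = burden.sum()
    obs = abs(np.log(ratio)) if ratio > 0 else np.inf
    count = 0
    n = len(y)
    for _ in range(n_permutations):
        idx = rng.choice(n, size=n_case, replace=False)
        cs = burden[idx].sum()
        m1 = cs / n_case
        m0 = (tot - cs) / (n - n_case)
        if m0 == 0:
            r = np.inf
        else:
            r = m1 / m0
        stat = abs(np.log(r)) if 0 < r < np.inf else np.inf
        if stat >= obs * (1 - 1e-12):
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return float(ratio), float(p)


class BurdenModel:
    """Rare-CNV burden model over a set of rarity definitions.

    Built from a segment matrix, its full-cohort frequency table and
    the subject list; ``fit()`` runs the capped burden regression for
    every rarity rule and returns a :class:`BurdenResults`.
    """

    def __init__(
        self,
        matrix: SegmentMatrix,
        freq_table: pd.DataFrame,
        segments: SegmentMap,
        subjects: list[SubjectRecord],
        rules: tuple[RarityRule, ...] = DEFAULT_RULES,
        cap: int = CAP_DEFAULT,
        covariates: tuple[str, ...] = ("batch",),
    ):
        self.matrix = matrix
        self.freq_table = freq_table
        self.segments = segments
        self.subjects = subjects
        self.rules = rules
        self.cap = cap
        self.covariates = covariates

    def fit(self, ratio_permutations: int = 2_000, seed: int = 0) -> "BurdenResults":
        results = []
        ratios = []
        for rule in self.rules:
            mask = rare_mask(self.freq_table, self.segments, rule)
            burden = per_subject_burden(self.matrix, mask, self.cap)
            uncapped = self.matrix.carrier[:, mask].sum(axis=1)
            res = burden_regression(
                burden,
                self.subjects,
                covariates=self.covariates,
                n_settings=len(self.rules),
                rule=rule,
                n_rare_segments=int(mask.sum()),
                total_rare_cnvs=int(uncapped.sum()),
            )
            results.append(res)
            ratios.append(
                mean_burden_ratio(burden, self.subjects, ratio_permutations, seed)
                if res.testable
                else (float("nan"), float("nan"))
            )
        return BurdenResults(results, ratios)


class BurdenResults:
    """Per-rarity-setting burden regression results."""

    def __init__(self, results: list[BurdenResult], mean_ratios: list[tuple[float, float]]):
        self.results = results
        self.mean_ratios = mean_ratios

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [r.rule.label for r in self.results],
                "n_rare_segments": [r.n_rare_segments for r in self.results],
                "total_rare_cnvs": [r.total_rare_cnvs for r in self.results],
                "or_per_cnv": [r.or_per_cnv for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_bonferroni": [r.p_bonferroni for r in self.results],
                "mean_ratio": [m[0] for m in self.mean_ratios],
                "mean_ratio_p": [m[1] for m in self.mean_ratios],
            }
        )

    def summary(self) -> str:
        lines = ["Rare-CNV burden analysis (OR per additional rare CNV; "
                 f"Bonferroni over {self.results[0].n_settings} settings)"]
        for r, (ratio, rp) in zip(self.results, self.mean_ratios):
            orr = f"{r.or_per_cnv:.3f}" if np.isfinite(r.or_per_cnv) else "   NA"
            lines.append(
                f"  {r.rule.label:<14} total={r.total_rare_cnvs:<6} OR={orr} "
                f"p={r.p_raw:.3f} p_bonf={r.p_bonferroni:.3f} "
                f"mean-ratio={ratio:.2f} (perm p={rp:.3f})"
            )
        return "\n".join(lines)
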