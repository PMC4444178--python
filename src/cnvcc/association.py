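"""Segment-wise case-control association with a permutation genome-wide null.

Per-segment testing
-------------------
Carrier status (copy state != 2, deletions and duplications combined)
is tested against case status with one of three statistics:

* ``fisher_exact`` — the exact hypergeometric test on the 2x2 table
  (no covariates);
* ``score_test`` — the logistic score z for the carrier term adjusted
  for covariates;
* ``firth_logistic_wald`` — Wald z from Firth penalised-likelihood
  logistic regression, which stays finite under complete separation
  (e.g. case-only segments).

Genome-wide (family-wise) p-values
----------------------------------
Case/control labels are permuted (within assay-batch strata when batch
is a covariate) and the genome-wide extreme of the statistic recorded
per permutation; each segment's genome-wide p is
``(1 + #{permutation extreme at least as extreme as observed}) /
(1 + n_permutations)``.  With ``exhaustive=True`` all distinct label
assignments are enumerated instead and the p-value is the exact
fraction.  Two-sidedness: the extreme is taken over the magnitude of
the statistic (minimum two-sided p for Fisher).

The batch-stratified score-test path is fully vectorised: within-batch
permutation keeps each batch's case count fixed, so the null fitted
probabilities (per-batch case fractions) and the per-segment score
variances are permutation-invariant and each permutation reduces to a
single matrix product.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .segmentation import SegmentMatrix, build_matrix, build_segments
from .types import Cohort, Group, SubjectRecord

VALID_STATISTICS = ("firth_logistic_wald", "score_test", "fisher_exact")
VALID_COMPARISONS = ("all_cases_vs_controls", "suicides_vs_controls", "attempters_vs_controls")
MIN_PERMUTATIONS = 100


@dataclass
class AssociationConfig:
    n_permutations: int = 10_000
    seed: int = 0
    statistic: str = "firth_logistic_wald"
    covariates: tuple[str, ...] = ("batch",)
    comparison: str = "all_cases_vs_controls"

    def __post_init__(self) -> None:
        if self.n_permutations < MIN_PERMUTATIONS:
            raise ValueError(f"n_permutations must be >= {MIN_PERMUTATIONS}")
        if self.statistic not in VALID_STATISTICS:
            raise ValueError(f"statistic must be one of {VALID_STATISTICS}")
        if self.comparison not in VALID_COMPARISONS:
            raise ValueError(f"comparison must be one of {VALID_COMPARISONS}")
        unknown = set(self.covariates) - {"batch", "age", "sex"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Firth penalised logistic regression
# ---------------------------------------------------------------------------

def firth_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit logistic regression with Jeffreys-prior (Firth) penalisation.

    Newton iterations on the modified score
    ``U*(b) = X'(y - p + h (1/2 - p))`` where ``h`` is the diagonal of
    the logistic hat matrix.  Estimates are finite even under complete
    separation.

    Returns ``(beta, standard errors, converged)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving keeps the iteration stable on separated data
        for _ in range(10):
            if np.all(np.abs(step) < 5.0):
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    w = expit(eta) * (1.0 - expit(eta))
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, converged


def build_design(subjects: list[SubjectRecord], covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept + covariate design matrix (batch/sex as treatment dummies)."""
    cols = [np.ones(len(subjects))]
    if "batch" in covariates:
        batches = sorted({s.batch for s in subjects})
        for b in batches[1:]:
            cols.append(np.array([1.0 if s.batch == b else 0.0 for s in subjects]))
    if "age" in covariates:
        ages = np.array([s.age if s.age is not None else np.nan for s in subjects])
        if np.isnan(ages).any():
            raise ValueError("age covariate requested but age missing for some subjects")
        cols.append(ages - ages.mean())
    if "sex" in covariates:
        cols.append(np.array([1.0 if s.sex == "F" else 0.0 for s in subjects]))
    return np.column_stack(cols)


def _score_z(carrier: np.ndarray, y: np.ndarray, Z0: np.ndarray) -> tuple[float, float]:
    """Logistic score z for one carrier vector adjusted for null design Z0."""
    # null fit: logit(y ~ Z0)
    beta, _, _ = firth_logistic(Z0, y)  # Firth-stabilised null fit
    p0 = expit(Z0 @ beta)
    w = p0 * (1.0 - p0)
    u = float(carrier @ (y - p0))
    zw = Z0 * w[:, None]
    q = Z0.T @ (w * carrier)
    try:
        sol = np.linalg.solve(Z0.T @ zw, q)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(Z0.T @ zw, q, rcond=None)[0]
    var = float((w * carrier * carrier).sum() - q @ sol)
    if var <= 1e-12:
        return 0.0, 1.0
    z = u / math.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def segment_statistic(
    carrier: np.ndarray,
    case_status: np.ndarray,
    covariates: pd.DataFrame | list[SubjectRecord] | None,
    cfg: AssociationConfig,
) -> tuple[float, float]:
    """Two-sided association statistic and pointwise p for one segment.

    Returns ``(statistic, p)``: the statistic is a signed z (log-OR
    scaled) for the regression statistics, or the signed standardised
    difference direction with Fisher's exact p.  Zero carriers make the
    segment untestable: ``(0.0, 1.0)``.
    """
    carrier = np.asarray(carrier, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if y.min() == y.max():
        raise ValueError("case_status is constant; both groups required")
    if carrier.sum() == 0:
        return 0.0, 1.0
    subjects = None
    if isinstance(covariates, list):
        subjects = covariates
    if cfg.statistic == "fisher_exact":
        if cfg.covariates and covariates is not None:
            raise ValueError("fisher_exact supports no covariates")
        a = int(carrier[y == 1].sum())
        b = int((y == 1).sum()) - a
        c = int(carrier[y == 0].sum())
        d = int((y == 0).sum()) - c
        _, p = stats.fisher_exact([[a, b], [c, d]])
        sign = np.sign(a / max(a + b, 1) - c / max(c + d, 1))
        return float(sign * stats.norm.isf(min(p, 1.0) / 2)) if p < 1 else 0.0, float(p)
    if subjects is not None:
        Z0 = build_design(subjects, cfg.covariates)
    elif isinstance(covariates, pd.DataFrame) and len(covariates.columns):
        Z0 = np.column_stack(
            [np.ones(len(y))]
            + [
                pd.get_dummies(covariates[c], drop_first=True).to_numpy(dtype=float)
                if covariates[c].dtype == object
                else covariates[[c]].to_numpy(dtype=float)
                for c in covariates.columns
            ]
        )
    else:
        Z0 = np.ones((len(y), 1))
    if cfg.statistic == "score_test":
        return _score_z(carrier, y, Z0)
    # firth_logistic_wald
    X = np.column_stack([Z0, carrier])
    beta, se, _ = firth_logistic(X, y)
    z = beta[-1] / se[-1] if se[-1] > 0 else 0.0
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def firth_segment_estimates(
    matrix: SegmentMatrix, subjects: list[SubjectRecord], covariates: tuple[str, ...]
) -> pd.DataFrame:
    """Firth log-OR, SE and Wald p for every testable segment."""
    y = np.array([float(s.is_case) for s in subjects])
    Z0 = build_design(subjects, covariates)
    carrier = matrix.carrier
    rows = []
    for j in range(matrix.n_segments):
        c = carrier[:, j].astype(float)
        if c.sum() == 0 or c.min() == c.max():
            rows.append((np.nan, np.nan, 1.0))
            continue
        X = np.column_stack([Z0, c])
        beta, se, _ = firth_logistic(X, y)
        z = beta[-1] / se[-1] if se[-1] > 0 else 0.0
        rows.append((beta[-1], se[-1], 2.0 * stats.norm.sf(abs(z))))
    return pd.DataFrame(rows, columns=["log_or", "se_log_or", "p_wald"])


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def _strata(subjects: list[SubjectRecord], covariates: tuple[str, ...]) -> np.ndarray:
    if "batch" in covariates:
        labels = [s.batch for s in subjects]
        uniq = {b: i for i, b in enumerate(sorted(set(labels)))}
        return np.array([uniq[b] for b in labels])
    return np.zeros(len(subjects), dtype=int)


def _permuted_labels(
    y: np.ndarray, strata: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) matrix of case labels permuted within strata."""
    n = len(y)
    Y = np.empty((n_perm, n), dtype=np.float64)
    idx_by_stratum = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for b in range(n_perm):
        row = np.empty(n)
        for idx in idx_by_stratum:
            row[idx] = y[rng.permutation(idx)]
        Y[b] = row
    return Y


def _exhaustive_labels(y: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """All distinct within-stratum case/control label assignments."""
    idx_by_stratum = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    per_stratum: list[list[np.ndarray]] = []
    for idx in idx_by_stratum:
        k = int(y[idx].sum())
        rows = []
        for combo in itertools.combinations(range(len(idx)), k):
            v = np.zeros(len(idx))
            v[list(combo)] = 1.0
            rows.append(v)
        per_stratum.append(rows)
    total = math.prod(len(r) for r in per_stratum)
    if total > 500_000:
        raise ValueError(f"exhaustive enumeration infeasible: {total} assignments")
    out = np.empty((total, len(y)))
    for b, parts in enumerate(itertools.product(*per_stratum)):
        row = np.empty(len(y))
        for idx, v in zip(idx_by_stratum, parts):
            row[idx] = v
        out[b] = row
    return out


def _fisher_p_lookup(n: int, n_case: int, max_m: int) -> np.ndarray:
    """L[m, a] = two-sided Fisher p for a case-carriers out of m carriers.

    Table margins: m carriers among n subjects of which n_case are
    cases.  Matches :func:`scipy.stats.fisher_exact` (sum of
    hypergeometric probabilities not exceeding that of the observed
    table, with a small relative tolerance).
    """
    L = np.ones((max_m + 1, max_m + 1))
    for m in range(1, max_m + 1):
        a = np.arange(0, m + 1)
        pmf = stats.hypergeom.pmf(a, n, n_case, m)
        for ai in range(m + 1):
            L[m, ai] = pmf[pmf <= pmf[ai] * (1.0 + 1e-7)].sum()
    return np.minimum(L, 1.0)


def genomewide_permutation(
    matrix: SegmentMatrix,
    subjects: list[SubjectRecord],
    cfg: AssociationConfig,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation max-statistic genome-wide p-values for every segment.

    Returns one row per segment: carrier counts by group, observed
    statistic, pointwise p, genome-wide p and direction.  Genome-wide
    p >= pointwise p by construction.  Identical seed gives identical
    output; with ``exhaustive=True`` all label assignments are
    enumerated and p-values are exact fractions.
    """
    if matrix.n_segments < 1:
        raise ValueError("no segments to test")
    y = np.array([float(s.is_case) for s in subjects])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both cases and controls are required")
    strata = _strata(subjects, cfg.covariates)
    C = matrix.carrier.astype(np.float64)
    m_tot = C.sum(axis=0).astype(int)
    testable = (m_tot > 0) & (m_tot < len(y))

    rng = np.random.default_rng(cfg.seed)
    if exhaustive:
        Y = _exhaustive_labels(y, strata)
    else:
        Y = _permuted_labels(y, strata, cfg.n_permutations, rng)
    B = Y.shape[0]

    if cfg.statistic == "fisher_exact":
        L = _fisher_p_lookup(len(y), int(y.sum()), int(m_tot.max(initial=0)))
        a_obs = (y @ C).astype(int)
        p_obs = L[m_tot, a_obs]
        A = (Y @ C).astype(int)
        P = L[np.broadcast_to(m_tot, A.shape), A]
        P[:, ~testable] = 1.0
        p_obs = np.where(testable, p_obs, 1.0)
        extreme_perm = P.min(axis=1)
        # permutation counts: smaller p = more extreme
        point_ge = (P <= p_obs[None, :] * (1 + 1e-12)).sum(axis=0)
        gw_ge = (extreme_perm[:, None] <= p_obs[None, :] * (1 + 1e-12)).sum(axis=0)
        stat_obs = np.zeros(matrix.n_segments)
        with np.errstate(divide="ignore"):
            z_mag = stats.norm.isf(np.clip(p_obs, 1e-300, 1.0) / 2)
        z_mag[p_obs >= 1.0] = 0.0
        direction = np.sign(a_obs / max(y.sum(), 1) - (m_tot - a_obs) / max((1 - y).sum(), 1))
        stat_obs = direction * z_mag
    else:
        if cfg.statistic == "firth_logistic_wald" and B * matrix.n_segments > 2_000_000:
            raise ValueError(
                "firth_logistic_wald permutation is only supported for small problems; "
                "use statistic='score_test' for genome-wide permutation at scale"
            )
        if cfg.statistic == "score_test" and set(cfg.covariates) <= {"batch"}:
            # fast path: within-batch permutation fixes per-batch case
            # fractions, so the null fit and score variances are constant
            p0 = np.empty(len(y))
            for s in np.unique(strata):
                idx = strata == s
                p0[idx] = y[idx].mean()
            w = p0 * (1.0 - p0)
            # null design spanned by stratum indicators: projection of
            # carrier on stratum space under W
            var = np.empty(matrix.n_segments)
            for j in range(matrix.n_segments):
                c = C[:, j]
                v = (w * c * c).sum()
                for s in np.unique(strata):
                    idx = strata == s
                    ws = w[idx].sum()
                    if ws > 0:
                        v -= (w[idx] * c[idx]).sum() ** 2 / ws
                var[j] = v
            ok = testable & (var > 1e-12)
            sd = np.where(ok, np.sqrt(np.where(ok, var, 1.0)), 1.0)
            z_obs = np.where(ok, (C.T @ (y - p0)) / sd, 0.0)
            U = (Y - p0[None, :]) @ C
            Zp = np.where(ok[None, :], U / sd[None, :], 0.0)
        else:
            # generic slow path: per-permutation statistic via segment_statistic
            sub_cfg = cfg
            z_obs = np.zeros(matrix.n_segments)
            for j in range(matrix.n_segments):
                if testable[j]:
                    z_obs[j], _ = segment_statistic(C[:, j], y, subjects, sub_cfg)
            Zp = np.zeros((B, matrix.n_segments))
            for b in range(B):
                yb = Y[b]
                for j in range(matrix.n_segments):
                    if testable[j]:
                        Zp[b, j], _ = segment_statistic(C[:, j], yb, subjects, sub_cfg)
        abs_obs = np.abs(z_obs)
        extreme_perm = np.abs(Zp).max(axis=1)
        point_ge = (np.abs(Zp) >= abs_obs[None, :] * (1 - 1e-12)).sum(axis=0)
        gw_ge = (extreme_perm[:, None] >= abs_obs[None, :] * (1 - 1e-12)).sum(axis=0)
        stat_obs = z_obs

    if exhaustive:
        p_point = point_ge / B
        p_gw = gw_ge / B
    else:
        p_point = (1.0 + point_ge) / (1.0 + B)
        p_gw = (1.0 + gw_ge) / (1.0 + B)
    p_point = np.where(testable, p_point, 1.0)
    p_gw = np.where(testable, p_gw, 1.0)

    is_case = y == 1
    carrier_bool = matrix.carrier
    n_case_car = carrier_bool[is_case].sum(axis=0)
    n_ctrl_car = carrier_bool[~is_case].sum(axis=0)
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in matrix.segments],
            "start": [g.start for g in matrix.segments],
            "end": [g.end for g in matrix.segments],
            "span_bp": [g.span_bp for g in matrix.segments],
            "n_case_carriers": n_case_car,
            "n_control_carriers": n_ctrl_car,
            "statistic": stat_obs,
            "p_pointwise": p_point,
            "p_genomewide": p_gw,
            "direction": np.sign(stat_obs).astype(int),
            "seed": cfg.seed,
        }
    )


def stratified_analysis(
    cohort: Cohort, cfg: AssociationConfig, exhaustive: bool = False
) -> dict[str, pd.DataFrame]:
    """Run the genome-wide permutation scan for all three comparisons.

    Segments are built once from the full cohort's calls; each
    comparison subsets the subjects, reusing the same seed policy.
    """
    segments = build_segments(cohort.calls)
    results = {}
    for comparison in VALID_COMPARISONS:
        subjects = _comparison_subjects(cohort, comparison)
        n_case = sum(s.is_case for s in subjects)
        n_ctrl = len(subjects) - n_case
        if n_case == 0 or n_ctrl == 0:
            raise ValueError(f"comparison {comparison!r}: empty stratum")
        sub = cohort.subset([s.sample_id for s in subjects])
        matrix = build_matrix(sub.calls, segments, sub.subjects)
        results[comparison] = genomewide_permutation(
            matrix, sub.subjects, replace(cfg, comparison=comparison), exhaustive=exhaustive
        )
    return results


def _comparison_subjects(cohort: Cohort, comparison: str) -> list[SubjectRecord]:
    if comparison == "all_cases_vs_controls":
        return list(cohort.subjects)
    keep_group = Group.SUICIDE if comparison == "suicides_vs_controls" else Group.SUICIDE_ATTEMPT
    return [s for s in cohort.subjects if s.group in (keep_group, Group.CONTROL)]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SegmentAssociationModel:
    """Segment-wise case-control association model.

    Parameters
    ----------
    matrix : SegmentMatrix
        Subjects x segments copy-state matrix.
    subjects : list of SubjectRecord
        Aligned to the matrix rows.
    config : AssociationConfig, optional
        Permutation count, seed, statistic and covariates.

    ``fit()`` returns a :class:`SegmentAssociationResults` with
    per-segment Firth effect estimates and permutation genome-wide
    p-values.
    """

    def __init__(
        self,
        matrix: SegmentMatrix,
        subjects: list[SubjectRecord],
        config: AssociationConfig | None = None,
    ):
        if matrix.n_subjects != len(subjects):
            raise ValueError("matrix rows and subjects differ in length")
        self.matrix = matrix
        self.subjects = subjects
        self.config = config or AssociationConfig()

    @classmethod
    def from_cohort(cls, cohort: Cohort, config: AssociationConfig | None = None):
        segments = build_segments(cohort.calls)
        matrix = build_matrix(cohort.calls, segments, cohort.subjects)
        return cls(matrix, cohort.subjects, config)

    def fit(self, permutation_statistic: str | None = "score_test") -> "SegmentAssociationResults":
        """Fit per-segment Firth estimates plus the permutation scan.

        The permutation null uses the batch-adjusted score statistic by
        default (its ordering matches the Wald statistic under the null
        and it vectorises across permutations); pass
        ``permutation_statistic=None`` to permute with the configured
        statistic instead.
        """
        perm_cfg = self.config
        if permutation_statistic is not None and perm_cfg.statistic != permutation_statistic:
            perm_cfg = replace(perm_cfg, statistic=permutation_statistic)
        scan = genomewide_permutation(self.matrix, self.subjects, perm_cfg)
        est = firth_segment_estimates(self.matrix, self.subjects, self.config.covariates)
        frame = pd.concat([scan.reset_index(drop=True), est], axis=1)
        frame["odds_ratio"] = np.exp(frame["log_or"])
        return SegmentAssociationResults(frame, self.config, perm_cfg.statistic)


class SegmentAssociationResults:
    """Results of a segment-wise association scan."""

    def __init__(self, frame: pd.DataFrame, config: AssociationConfig, permutation_statistic: str):
        self.frame = frame
        self.config = config
        self.permutation_statistic = permutation_statistic

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Segments with genome-wide p below ``alpha``."""
        return self.frame[self.frame["p_genomewide"] < alpha]

    def summary(self, alpha: float = 0.05) -> str:
        hits = self.significant(alpha)
        lines = [
            "Segment-wise CNV case-control association",
            f"  segments tested:      {len(self.frame)}",
            f"  permutations:         {self.config.n_permutations} (seed {self.config.seed})",
            f"  permutation statistic:{self.permutation_statistic}",
            f"  covariates:           {', '.join(self.config.covariates) or 'none'}",
            f"  genome-wide hits (p < {alpha:g}): {len(hits)}",
        ]
        for _, r in hits.iterrows():
            lines.append(
                f"    chr{r.chrom}:{r.start}-{r.end}  cases {r.n_case_carriers} / "
                f"controls {r.n_control_carriers}  OR {r.odds_ratio:.2f}  "
                f"p_gw {r.p_genomewide:.4g}"
            )
        return "\n".join(lines)
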