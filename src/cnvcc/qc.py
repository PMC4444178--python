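"""Call-level and subject-level quality-control filters.

Filter order is fixed: the probe filter runs first, and the
hypervariable-subject filter counts only calls that survive it ("more
than ``max_calls_per_subject`` calls spanning at least ``min_probes``
probes").  Subjects with zero calls are always retained — controls
without CNVs stay in every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .types import CNVCall, Cohort, Group


@dataclass
class QCConfig:
    min_probes: int = 30
    max_calls_per_subject: int = 50
    exclude_mdd_controls: bool = False

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.max_calls_per_subject < 1:
            raise ValueError("max_calls_per_subject must be >= 1")


@dataclass
class QCReport:
    """Exclusion counts from one QC pass."""

    n_calls_in: int = 0
    n_calls_kept: int = 0
    n_subjects_in: int = 0
    n_subjects_removed_hypervariable: int = 0
    n_controls_removed_mdd: int = 0
    removed_subject_ids: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.removed_subject_ids is None:
            self.removed_subject_ids = []

    @property
    def n_subjects_kept(self) -> int:
        return self.n_subjects_in - self.n_subjects_removed_hypervariable - self.n_controls_removed_mdd


def filter_min_probes(calls: list[CNVCall], min_probes: int = 30) -> list[CNVCall]:
    """Keep only calls spanning at least ``min_probes`` array probes."""
    return [c for c in calls if c.num_probes >= min_probes]


def filter_hypervariable_subjects(cohort: Cohort, cfg: QCConfig) -> tuple[Cohort, QCReport]:
    """Drop subjects with more than ``max_calls_per_subject`` qualifying calls.

    Qualifying = spanning at least ``cfg.min_probes`` probes.  Dropped
    subjects lose all their calls; every other subject is retained even
    with zero calls.
    """
    qualifying = filter_min_probes(cohort.calls, cfg.min_probes)
    counts: dict[str, int] = {}
    for c in qualifying:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    removed = {sid for sid, n in counts.items() if n > cfg.max_calls_per_subject}
    kept_subjects = [s for s in cohort.subjects if s.sample_id not in removed]
    kept_calls = [c for c in qualifying if c.sample_id not in removed]
    report = QCReport(
        n_calls_in=len(cohort.calls),
        n_calls_kept=len(kept_calls),
        n_subjects_in=len(cohort.subjects),
        n_subjects_removed_hypervariable=len(removed),
        removed_subject_ids=sorted(removed),
    )
    return Cohort(subjects=kept_subjects, calls=kept_calls), report


def select_controls(cohort: Cohort, exclude_mdd: bool) -> Cohort:
    """Optionally drop controls with a history of major depression (MDD).

    Cases are never removed.  With ``exclude_mdd`` the cohort must carry
    MDD information for at least one control; an all-missing flag would
    silently pass everything through, so it raises instead.
    """
    if not exclude_mdd:
        return cohort
    controls = [s for s in cohort.subjects if s.group is Group.CONTROL]
    if any(s.mdd is None for s in controls):
        raise ValueError(
            "exclude_mdd requested but MDD status is missing for some controls"
        )
    keep = [s.sample_id for s in cohort.subjects if s.is_case or not s.mdd]
    return cohort.subset(keep)


def apply_qc(
    cohort: Cohort, cfg: QCConfig | None = None, audit_path: str | Path | None = None
) -> tuple[Cohort, QCReport]:
    """Full QC pass: probe filter, hypervariable filter, optional MDD exclusion.

    When ``audit_path`` is given the removed-subject list is written to a
    sidecar TSV for reproducibility of cohort attrition.
    """
    cfg = cfg or QCConfig()
    filtered, report = filter_hypervariable_subjects(cohort, cfg)
    if cfg.exclude_mdd_controls:
        before = len(filtered.subjects)
        filtered = select_controls(filtered, exclude_mdd=True)
        report.n_controls_removed_mdd = before - len(filtered.subjects)
    if audit_path is not None:
        with Path(audit_path).open("w") as fh:
            fh.write("sample_id\treason\n")
            for sid in report.removed_subject_ids:
                fh.write(f"{sid}\thypervariable\n")
    return filtered, report
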