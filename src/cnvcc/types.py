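"""Domain types: CNV calls, subject phenotype records, and cohorts.

Coordinate convention: CNV call positions are 1-based inclusive as in
PennCNV output; a call's span in base pairs is defined as ``end - start``
(the convention under which published segment spans match their printed
coordinates).  BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS)}

VALID_COPY_NUMBERS = frozenset({0, 1, 3, 4})


class Group(str, Enum):
    """Phenotype group of a subject."""

    SUICIDE = "suicide"
    SUICIDE_ATTEMPT = "suicide_attempt"
    CONTROL = "control"

    @property
    def is_case(self) -> bool:
        return self is not Group.CONTROL


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and validate the chromosome label."""
    c = label[3:] if label.lower().startswith("chr") else label
    c = c.upper() if c.upper() in ("X", "Y") else c
    if c not in _CHROM_ORDER:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_ORDER[chrom]


@dataclass(frozen=True)
class CNVCall:
    """One detected deletion/duplication for one subject.

    Attributes
    ----------
    sample_id : str
    chrom : str
        Chromosome label without ``chr`` prefix ("1".."22", "X", "Y").
    start, end : int
        1-based inclusive positions, ``end > start``.
    num_probes : int
        Number of array probes spanned (>= 1).
    copy_number : int
        Integer copy-number state in {0, 1, 3, 4}; 2 (copy-neutral)
        is never stored.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    num_probes: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.num_probes < 1:
            raise ValueError("num_probes must be >= 1")
        if self.copy_number == 2:
            raise ValueError("copy-neutral state 2 is never stored as a call")
        if self.copy_number not in VALID_COPY_NUMBERS:
            raise ValueError(f"copy_number must be in {{0,1,3,4}}, got {self.copy_number}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def span_bp(self) -> int:
        """Span in base pairs, defined as ``end - start``."""
        return self.end - self.start

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2


@dataclass(frozen=True)
class SubjectRecord:
    """Phenotype/covariate row for one subject."""

    sample_id: str
    group: Group
    batch: str = "0"
    mdd: bool | None = None  # None = unknown / column absent
    age: float | None = None
    sex: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")

    @property
    def is_case(self) -> bool:
        return self.group.is_case


def sort_calls(calls: Iterable[CNVCall]) -> list[CNVCall]:
    return sorted(calls, key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end, c.sample_id))


@dataclass
class Cohort:
    """Subjects plus their CNV calls.

    Invariants: sample ids unique; every call's sample id belongs to a
    subject; calls sorted by (chromosome, start).
    """

    subjects: list[SubjectRecord]
    calls: list[CNVCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id in cohort: {dupes[:5]}")
        known = set(ids)
        orphans = sorted({c.sample_id for c in self.calls} - known)
        if orphans:
            raise ValueError(f"calls reference unknown subjects: {orphans[:5]}")
        self.calls = sort_calls(self.calls)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.subjects]

    @property
    def n_cases(self) -> int:
        return sum(s.is_case for s in self.subjects)

    @property
    def n_controls(self) -> int:
        return sum(not s.is_case for s in self.subjects)

    def case_status(self) -> list[bool]:
        return [s.is_case for s in self.subjects]

    def calls_by_subject(self) -> dict[str, list[CNVCall]]:
        out: dict[str, list[CNVCall]] = {s.sample_id: [] for s in self.subjects}
        for c in self.calls:
            out[c.sample_id].append(c)
        return out

    def subset(self, keep_ids: Sequence[str]) -> "Cohort":
        """Cohort restricted to the given subjects (order preserved)."""
        keep = set(keep_ids)
        return Cohort(
            subjects=[s for s in self.subjects if s.sample_id in keep],
            calls=[c for c in self.calls if c.sample_id in keep],
        )
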