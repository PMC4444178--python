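"""Breakpoint-union genome segmentation and the subjects x segments matrix.

A *segment* is a maximal genomic interval on which no subject's inferred
copy number changes; its boundaries are the union of all call start and
end positions.  Calls are treated as half-open [start, end) during
partitioning (a call covers base positions start..end-1), which makes
the partition exact with no double counting; segments are reported with
the same (start, end) bounds, so ``span_bp = end - start``.  Only
regions covered by at least one call are segmented — copy-neutral
genome is not enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CNVCall, SubjectRecord, chrom_sort_key


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int  # bounds inherited from call breakpoints; covers start..end-1

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass
class SegmentMap:
    """Ordered, per-chromosome list of non-overlapping segments."""

    by_chrom: dict[str, list[Segment]] = field(default_factory=dict)

    def all_segments(self) -> list[Segment]:
        out: list[Segment] = []
        for chrom in sorted(self.by_chrom, key=chrom_sort_key):
            out.extend(self.by_chrom[chrom])
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())


def build_segments(calls: list[CNVCall]) -> SegmentMap:
    """Partition call-covered genome at the union of call breakpoints.

    Within each chromosome, the sorted set of all call starts and ends
    cuts the covered genome into maximal intervals on which every
    subject's copy state is constant.  Uncovered gaps between calls are
    not emitted.
    """
    by_chrom: dict[str, list[Segment]] = {}
    chroms: dict[str, list[CNVCall]] = {}
    for c in calls:
        chroms.setdefault(c.chrom, []).append(c)
    for chrom, cc in chroms.items():
        bps = np.unique(np.array([[c.start, c.end] for c in cc]).ravel())
        starts_arr = np.array([c.start for c in cc])
        ends_arr = np.array([c.end for c in cc])
        segs = []
        for s, e in zip(bps[:-1], bps[1:]):
            # keep [s, e) only if covered by >= 1 call
            if np.any((starts_arr <= s) & (ends_arr >= e)):
                segs.append(Segment(chrom=chrom, start=int(s), end=int(e)))
        by_chrom[chrom] = segs
    return SegmentMap(by_chrom={c: by_chrom[c] for c in sorted(by_chrom, key=chrom_sort_key)})


class SegmentationError(RuntimeError):
    """A call partially overlaps a segment — signals a segmentation bug."""


@dataclass
class SegmentMatrix:
    """Copy states of every subject at every segment (default 2)."""

    segments: list[Segment]
    sample_ids: list[str]
    copy_state: np.ndarray  # (n_subjects, n_segments) int

    @property
    def carrier(self) -> np.ndarray:
        """Boolean (n_subjects, n_segments): copy state differs from 2."""
        return self.copy_state != 2

    @property
    def n_subjects(self) -> int:
        return len(self.sample_ids)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def build_matrix(
    calls: list[CNVCall], segments: SegmentMap, subjects: list[SubjectRecord]
) -> SegmentMatrix:
    """Fill the subjects x segments copy-state matrix from calls.

    Every segment a call overlaps must be fully contained in the call's
    half-open interval; partial overlap means the segment map was not
    built from these calls and raises :class:`SegmentationError`.
    """
    seg_list = segments.all_segments()
    sample_ids = [s.sample_id for s in subjects]
    row = {sid: i for i, sid in enumerate(sample_ids)}
    state = np.full((len(sample_ids), len(seg_list)), 2, dtype=np.int16)

    # per-chromosome segment index for fast lookup
    seg_idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in segments.by_chrom:
        ss = segments.by_chrom[chrom]
        offs = np.array([seg_list.index(ss[0])]) if ss else np.array([], dtype=int)
        # contiguous block per chromosome in all_segments order
        starts = np.array([g.start for g in ss])
        ends = np.array([g.end for g in ss])
        seg_idx[chrom] = (starts, ends, offs)

    for c in calls:
        if c.sample_id not in row:
            continue
        starts, ends, offs = seg_idx.get(c.chrom, (None, None, None))
        if starts is None or len(starts) == 0:
            raise SegmentationError(f"call on chromosome {c.chrom} has no segments")
        lo = int(np.searchsorted(starts, c.start, side="left"))
        hi = int(np.searchsorted(ends, c.end, side="right"))
        if lo >= hi or starts[lo] != c.start or ends[hi - 1] != c.end:
            raise SegmentationError(
                f"call {c.chrom}:{c.start}-{c.end} does not align with segment boundaries"
            )
        # gaps inside the call interval would mean uncovered segments, impossible
        base = offs[0]
        state[row[c.sample_id], base + lo : base + hi] = c.copy_number
    return SegmentMatrix(segments=seg_list, sample_ids=sample_ids, copy_state=state)


def frequency_table(matrix: SegmentMatrix, subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Per-segment carrier counts and frequencies by group.

    Columns: chrom, start, end, span_bp, n_case_carriers,
    n_control_carriers, n_carriers, freq_cases, freq_controls, freq.
    """
    is_case = np.array([s.is_case for s in subjects])
    carrier = matrix.carrier
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    case_carriers = carrier[is_case].sum(axis=0)
    ctrl_carriers = carrier[~is_case].sum(axis=0)
    n = len(subjects)
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in matrix.segments],
            "start": [g.start for g in matrix.segments],
            "end": [g.end for g in matrix.segments],
            "span_bp": [g.span_bp for g in matrix.segments],
            "n_case_carriers": case_carriers,
            "n_control_carriers": ctrl_carriers,
            "n_carriers": case_carriers + ctrl_carriers,
            "freq_cases": case_carriers / n_case if n_case else np.nan,
            "freq_controls": ctrl_carriers / n_ctrl if n_ctrl else np.nan,
            "freq": (case_carriers + ctrl_carriers) / n,
        }
    )
    return df


def exclusivity_summary(freq: pd.DataFrame, min_group_count: int = 5) -> dict[str, int]:
    """Descriptive summary of group-exclusive segments.

    Reports how many carrier segments are unique to cases or to
    controls, how many of those reach ``min_group_count`` carriers, and
    the maximum carrier count over exclusive segments.
    """
    seen = freq[freq["n_carriers"] > 0]
    case_only = seen[(seen["n_case_carriers"] > 0) & (seen["n_control_carriers"] == 0)]
    ctrl_only = seen[(seen["n_control_carriers"] > 0) & (seen["n_case_carriers"] == 0)]
    exclusive = pd.concat([case_only, ctrl_only])
    return {
        "n_case_only": len(case_only),
        "n_case_only_ge_min": int((case_only["n_case_carriers"] >= min_group_count).sum()),
        "n_control_only": len(ctrl_only),
        "n_control_only_ge_min": int((ctrl_only["n_control_carriers"] >= min_group_count).sum()),
        "n_exclusive": len(exclusive),
        "max_carriers_exclusive": int(exclusive["n_carriers"].max()) if len(exclusive) else 0,
    }


def collapse_identical_columns(matrix: SegmentMatrix) -> int:
    """Number of distinct carrier patterns across segments (diagnostic)."""
    if matrix.n_segments == 0:
        return 0
    cols = np.ascontiguousarray(matrix.carrier.T)
    return len({cols[j].tobytes() for j in range(cols.shape[0])})
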