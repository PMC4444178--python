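"""Readers and writers for the file formats the pipeline touches.

Supported formats
-----------------
* PennCNV ``rawcnv`` call lists (read/write), one call per line::

      chr12:40549708-40716694 numsnp=45 length=166,987 state2,cn=1 sampleA [startsnp=..] [endsnp=..]

  Positions are 1-based inclusive.  The redundant ``length=`` token is
  ignored on read (span is recomputed as ``end - start``); a warning is
  logged when it disagrees by more than 1.  Thousands separators are
  tolerated in numeric fields.
* Phenotype TSV with header (``sample_id``, ``group``, ``batch``
  required; ``mdd``, ``age``, ``sex``, ``site`` optional).
* BED (write), 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .types import CNVCall, Cohort, Group, SubjectRecord

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import SegmentMap

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>[\d,]+)-(?P<end>[\d,]+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=\S+)?(?:\s+endsnp=\S+)?\s*$"
)


def _int(tok: str) -> int:
    return int(tok.replace(",", ""))


def read_penncnv_calls(path: str | Path) -> list[CNVCall]:
    """Read a PennCNV rawcnv file into validated :class:`CNVCall` objects.

    Copy-neutral (``cn=2``) lines are skipped with a warning; a copy
    number outside {0,1,2,3,4} or a malformed line raises.
    """
    calls: list[CNVCall] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed rawcnv line: {line!r}")
            cn = _int(m["cn"])
            if cn not in (0, 1, 2, 3, 4):
                raise ValueError(f"{path}:{lineno}: copy number {cn} outside {{0..4}}")
            if cn == 2:
                log.warning("%s:%d: skipping copy-neutral (cn=2) line", path, lineno)
                continue
            start, end = _int(m["start"]), _int(m["end"])
            call = CNVCall(
                sample_id=m["sample"],
                chrom=m["chrom"],
                start=start,
                end=end,
                num_probes=_int(m["numsnp"]),
                copy_number=cn,
            )
            stated = _int(m["length"])
            if abs(stated - call.span_bp) > 1:
                log.warning(
                    "%s:%d: length=%d disagrees with end-start=%d; recomputed value used",
                    path, lineno, stated, call.span_bp,
                )
            calls.append(call)
    return calls


def write_penncnv_calls(calls: list[CNVCall], path: str | Path) -> None:
    """Write calls in rawcnv layout (``length`` = span_bp + 1, PennCNV's own count)."""
    with Path(path).open("w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.num_probes} "
                f"length={c.span_bp + 1:,} state{c.copy_number},cn={c.copy_number} {c.sample_id}\n"
            )


_REQUIRED_PHENO = ("sample_id", "group", "batch")


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read a phenotype TSV into validated :class:`SubjectRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    missing = [c for c in _REQUIRED_PHENO if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id: {dupes[:5]}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SubjectRecord(
                sample_id=d["sample_id"],
                group=Group(d["group"]),
                batch=str(d["batch"]),
                mdd=(bool(int(d["mdd"])) if "mdd" in d and not pd.isna(d["mdd"]) else None),
                age=float(d["age"]) if "age" in d and not pd.isna(d["age"]) else None,
                sex=d.get("sex") if isinstance(d.get("sex"), str) else None,
                site=d.get("site") if isinstance(d.get("site"), str) else None,
            )
        )
    return records


def write_phenotypes(subjects: list[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in subjects],
            "group": [s.group.value for s in subjects],
            "batch": [s.batch for s in subjects],
            "mdd": [None if s.mdd is None else int(s.mdd) for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "site": [s.site for s in subjects],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort(calls_path: str | Path, pheno_path: str | Path) -> Cohort:
    """Read calls + phenotypes and validate them into a :class:`Cohort`."""
    return Cohort(subjects=read_phenotypes(pheno_path), calls=read_penncnv_calls(calls_path))


def write_segments_bed(segments: "SegmentMap", path: str | Path) -> None:
    """Write segments as BED (0-based half-open).

    A segment with 1-based inclusive bounds [s, e] becomes the BED line
    ``chrom  s-1  e``.
    """
    with Path(path).open("w") as fh:
        for seg in segments.all_segments():
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\n")


def read_segments_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file back to 1-based inclusive [start, end] bounds."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, s, e = line.split("\t")[:3]
            out.append((chrom, int(s) + 1, int(e)))
    return out
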