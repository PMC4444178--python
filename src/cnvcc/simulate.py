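"""Seeded synthetic cohort generator.

Emulates the data structure of a SNP-array CNV case-control study: a
cohort of ~475 suicide / suicide-attempt cases and ~1,133 controls with
rare CNV calls (carrier frequencies concentrated below 1%, sizes from
tens of probes to >500 kb), assay batches, optional planted risk loci
at specified odds ratios, an optional per-CNV burden effect, and a
minority of hypervariable subjects whose call counts exceed the
50-call QC limit.  Group-specific carrier frequencies are derived from
odds ratios on the odds scale (case odds = OR x control odds).  All
randomness flows from a single seeded generator; given the same
configuration and seed the generated files are byte-identical.

The generator does not simulate probe-level intensities, linkage
between loci, GC artefacts or call-boundary uncertainty (unless
``overlap`` jitter is enabled); loci are non-overlapping by default so
the segment decomposition equals the locus list and planted truth is
exactly recoverable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import write_penncnv_calls, write_phenotypes
from .power import case_frequency_from_or
from .types import CNVCall, Cohort, Group, SubjectRecord

# approximate autosome lengths (bp), hg19 scale
DEFAULT_CHROM_LENGTHS = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}


@dataclass
class PlantedEffect:
    """A risk locus with a group-specific odds ratio.

    ``target_group`` is "case" (both suicide and attempt), "suicide",
    or "suicide_attempt"; other groups keep the control frequency.
    """

    locus: int
    odds_ratio: float
    target_group: str = "case"

    def __post_init__(self) -> None:
        if self.target_group not in ("case", "suicide", "suicide_attempt"):
            raise ValueError("target_group must be 'case', 'suicide' or 'suicide_attempt'")
        if self.odds_ratio <= 0 or not np.isfinite(self.odds_ratio):
            raise ValueError("odds_ratio must be positive and finite")


@dataclass
class SimulationConfig:
    n_cases: int = 475
    n_controls: int = 1_133
    suicide_fraction_of_cases: float = 276 / 475  # rest are attempters
    n_batches: int = 4
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_loci: int = 200
    freq_range: tuple[float, float] = (5e-4, 0.02)  # log-uniform carrier frequency
    probe_range: tuple[int, int] = (20, 2_000)  # log-uniform probe count; tail below 30 feeds QC
    probe_spacing_bp: float = 1_500.0
    deletion_fraction: float = 0.6
    planted_effects: tuple[PlantedEffect, ...] = ()
    burden_effect: float = 1.0  # odds ratio per carried locus, applied to every locus for cases
    frac_hypervariable: float = 0.0
    mdd_control_fraction: float = 0.3
    overlap: bool = False  # jitter call boundaries to exercise breakpoint-union segmentation
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("suicide_fraction_of_cases", self.suicide_fraction_of_cases),
                        ("frac_hypervariable", self.frac_hypervariable),
                        ("mdd_control_fraction", self.mdd_control_fraction),
                        ("deletion_fraction", self.deletion_fraction)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for eff in self.planted_effects:
            if not (0 <= eff.locus < self.n_loci):
                raise ValueError(f"planted locus {eff.locus} outside 0..{self.n_loci - 1}")


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    num_probes: int
    copy_number: int
    control_freq: float
    case_freq: dict[str, float]  # per group label


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every recovery test."""

    loci: list[Locus]
    burden: dict[str, int]  # per-subject carried-locus count (pre-QC, real loci only)
    hypervariable_ids: list[str]
    seed: int


def _draw_loci(cfg: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    chroms = list(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    loci: list[Locus] = []
    lo_f, hi_f = cfg.freq_range
    lo_p, hi_p = cfg.probe_range
    planted_idx = {eff.locus for eff in cfg.planted_effects}
    while len(loci) < cfg.n_loci:
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        # planted risk loci model well-supported CNVs: force them past
        # the default 30-probe QC line so truth stays recoverable
        lo_here = max(lo_p, 30) if len(loci) in planted_idx else lo_p
        n_probes = int(round(np.exp(rng.uniform(np.log(lo_here), np.log(hi_p)))))
        span = int(round(n_probes * cfg.probe_spacing_bp * np.exp(rng.normal(0, 0.2))))
        span = max(span, 1_000)
        L = cfg.chrom_lengths[chrom]
        if span >= L - 2:
            continue
        start = int(rng.integers(1, L - span))
        end = start + span
        # keep loci separated so segmentation truth is clean
        if any(not (end + 10_000 < s or start - 10_000 > e) for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        cn = 1 if rng.random() < cfg.deletion_fraction else 3
        f = float(np.exp(rng.uniform(np.log(lo_f), np.log(hi_f))))
        loci.append(Locus(chrom, start, end, n_probes, cn, f, {}))
    # group frequencies: burden effect applies to all loci for all cases,
    # planted effects multiply on top for their target group
    for j, loc in enumerate(loci):
        or_by_group = {"suicide": cfg.burden_effect, "suicide_attempt": cfg.burden_effect}
        for eff in cfg.planted_effects:
            if eff.locus == j:
                targets = (
                    ("suicide", "suicide_attempt") if eff.target_group == "case" else (eff.target_group,)
                )
                for g in targets:
                    or_by_group[g] *= eff.odds_ratio
        loc.case_freq = {
            g: case_frequency_from_or(loc.control_freq, orr) for g, orr in or_by_group.items()
        }
        if any(f >= 1.0 for f in loc.case_freq.values()):
            raise ValueError(f"planted odds ratio at locus {j} pushes case frequency to 1")
    return loci


def simulate_cohort(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[Cohort, SyntheticTruth]:
    """Generate a cohort; optionally write rawcnv + phenotype TSV files.

    Returns the in-memory :class:`Cohort` and the :class:`SyntheticTruth`.
    When ``out_dir`` is given, ``calls.rawcnv``, ``phenotypes.tsv`` and
    ``truth.json`` are written there (byte-identical across reruns with
    the same config).
    """
    rng = np.random.default_rng(cfg.seed)
    loci = _draw_loci(cfg, rng)

    n_suicide = int(round(cfg.n_cases * cfg.suicide_fraction_of_cases))
    groups = (
        [Group.SUICIDE] * n_suicide
        + [Group.SUICIDE_ATTEMPT] * (cfg.n_cases - n_suicide)
        + [Group.CONTROL] * cfg.n_controls
    )
    n = len(groups)
    batch_probs = np.arange(1, cfg.n_batches + 1, dtype=float)
    batch_probs /= batch_probs.sum()  # mild size imbalance across batches
    batches = rng.choice(cfg.n_batches, size=n, p=batch_probs)
    sexes = np.where(rng.random(n) < 0.52, "M", "F")
    ages = np.clip(rng.normal(45, 12, n), 18, 90).round(1)
    mdd = rng.random(n) < cfg.mdd_control_fraction

    subjects = []
    for i, g in enumerate(groups):
        subjects.append(
            SubjectRecord(
                sample_id=f"S{i:05d}",
                group=g,
                batch=f"B{batches[i] + 1}",
                mdd=bool(mdd[i]) if g is Group.CONTROL else None,
                age=float(ages[i]),
                sex=str(sexes[i]),
                site="site1",
            )
        )

    calls: list[CNVCall] = []
    burden = {s.sample_id: 0 for s in subjects}
    group_labels = np.array([g.value for g in groups])
    for loc in loci:
        p = np.full(n, loc.control_freq)
        for g, f in loc.case_freq.items():
            p[group_labels == g] = f
        carriers = np.flatnonzero(rng.random(n) < p)
        for i in carriers:
            sid = subjects[i].sample_id
            burden[sid] += 1
            start, end = loc.start, loc.end
            if cfg.overlap:
                span = end - start
                start = max(1, start + int(rng.integers(-span // 5, span // 5 + 1)))
                end = max(start + 1_000, end + int(rng.integers(-span // 5, span // 5 + 1)))
            calls.append(
                CNVCall(
                    sample_id=sid, chrom=loc.chrom, start=start, end=end,
                    num_probes=loc.num_probes, copy_number=loc.copy_number,
                )
            )

    # hypervariable subjects: an artifact burst of qualifying calls
    n_hyper = int(round(cfg.frac_hypervariable * n))
    hyper_idx = rng.choice(n, size=n_hyper, replace=False) if n_hyper else np.array([], dtype=int)
    chroms = list(cfg.chrom_lengths)
    for i in sorted(hyper_idx):
        sid = subjects[i].sample_id
        n_extra = int(rng.integers(55, 85))
        for _ in range(n_extra):
            chrom = chroms[int(rng.integers(len(chroms)))]
            span = int(rng.integers(50_000, 300_000))
            start = int(rng.integers(1, cfg.chrom_lengths[chrom] - span))
            calls.append(
                CNVCall(
                    sample_id=sid, chrom=chrom, start=start, end=start + span,
                    num_probes=max(30, int(span / cfg.probe_spacing_bp)),
                    copy_number=int(rng.choice([1, 3])),
                )
            )

    cohort = Cohort(subjects=subjects, calls=calls)
    truth = SyntheticTruth(
        loci=loci,
        burden=burden,
        hypervariable_ids=sorted(subjects[i].sample_id for i in hyper_idx),
        seed=cfg.seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_penncnv_calls(cohort.calls, out / "calls.rawcnv")
        write_phenotypes(cohort.subjects, out / "phenotypes.tsv")
        with (out / "truth.json").open("w") as fh:
            json.dump(
                {
                    "seed": truth.seed,
                    "hypervariable_ids": truth.hypervariable_ids,
                    "burden": truth.burden,
                    "loci": [asdict(l) for l in truth.loci],
                },
                fh, indent=1, sort_keys=True,
            )
    return cohort, truth


def _manifest(paths: list[Path]) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(paths)}


def end_to_end_fixture(
    scale: str = "tiny", out_dir: str | Path | None = None, seed: int = 0
) -> dict:
    """Ready-made bundles for testing.

    ``tiny``: 30 subjects / 20 loci with inflated frequencies, suitable
    for exhaustive oracles.  ``full``: the default 1,608-subject
    cohort with hypervariable subjects and a mild burden effect.
    Returns a dict with the cohort, truth, config and (when written)
    file paths plus a sha256 manifest.
    """
    if scale == "tiny":
        cfg = SimulationConfig(
            n_cases=10, n_controls=20, n_loci=20, freq_range=(0.05, 0.3),
            probe_range=(30, 200), n_batches=2, frac_hypervariable=0.0, seed=seed,
        )
    elif scale == "full":
        cfg = SimulationConfig(frac_hypervariable=0.02, burden_effect=1.1, seed=seed)
    else:
        raise ValueError("scale must be 'tiny' or 'full'")
    cohort, truth = simulate_cohort(cfg, out_dir=out_dir)
    bundle = {"cohort": cohort, "truth": truth, "config": cfg}
    if out_dir is not None:
        out = Path(out_dir)
        files = [out / "calls.rawcnv", out / "phenotypes.tsv", out / "truth.json"]
        bundle["paths"] = files
        bundle["manifest"] = _manifest(files)
        with (out / "manifest.json").open("w") as fh:
            json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)
    return bundle
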