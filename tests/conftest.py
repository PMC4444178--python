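import numpy as np
import pytest

from cnvcc.simulate import PlantedEffect, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 subjects / 20 loci with inflated frequencies (exhaustive-oracle scale)."""
    cfg = SimulationConfig(
        n_cases=10, n_controls=20, n_loci=20, freq_range=(0.05, 0.3),
        probe_range=(30, 200), n_batches=2, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with one strong planted risk locus and hypervariable subjects."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=300, n_loci=60, freq_range=(0.01, 0.08),
        frac_hypervariable=0.02,
        planted_effects=(PlantedEffect(locus=0, odds_ratio=6.0, target_group="case"),),
        seed=23,
    )
    return simulate_cohort(cfg)


def random_tiny_calls(rng: np.random.Generator, chrom_len: int = 1000, n_subjects: int = 6):
    """Random per-subject non-overlapping calls on a toy chromosome.

    Each subject gets 0-3 disjoint intervals; all calls of one subject
    share a copy state so overlaps between subjects are the only
    segmentation work.
    """
    from cnvcc.types import CNVCall

    calls = []
    for i in range(n_subjects):
        k = int(rng.integers(0, 4))
        if k == 0:
            continue
        pts = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=2 * k, replace=False))
        cn = int(rng.choice([0, 1, 3, 4]))
        for j in range(k):
            s, e = int(pts[2 * j]), int(pts[2 * j + 1])
            calls.append(CNVCall(sample_id=f"T{i}", chrom="1", start=s, end=e,
                                 num_probes=30, copy_number=cn))
    return calls


def per_base_states(calls, chrom_len: int, sample_ids):
    """Per-base copy states (half-open coverage: a call covers start..end-1)."""
    states = np.full((len(sample_ids), chrom_len + 1), 2, dtype=int)  # 1-based positions
    row = {sid: i for i, sid in enumerate(sample_ids)}
    for c in calls:
        states[row[c.sample_id], c.start:c.end] = c.copy_number
    return states


def oracle_segments(calls, chrom_len: int, sample_ids):
    """Maximal constant runs of the joint per-base state vector, covered bases only."""
    states = per_base_states(calls, chrom_len, sample_ids)
    covered = (states != 2).any(axis=0)
    segs = []
    start = None
    for pos in range(1, chrom_len + 1):
        if not covered[pos]:
            if start is not None:
                segs.append((start, pos))
                start = None
            continue
        if start is None:
            start = pos
        elif not np.array_equal(states[:, pos], states[:, pos - 1]):
            segs.append((start, pos))
            start = pos
    if start is not None:
        segs.append((start, chrom_len + 1))
    return segs, states
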