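"""Rarefaction and per-sample repertoire summary statistics.

All diversity metrics use the natural logarithm (nats); Pielou's evenness
divides Shannon entropy by ln S so the base cancels. Metrics are intended to
be computed on samples rarefied to a common depth so that richness and
diversity are comparable across sequencing runs.
"""
from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np

from .clonotype import convergent_groups
from .model import Clonotype, DeltaMetrics, RepertoireSample, SampleMetrics

_SUM_TOL = 1e-9


def rarefy(
    sample: RepertoireSample,
    depth: int,
    seed: Union[int, np.random.Generator],
) -> RepertoireSample:
    """Subsample a repertoire to ``depth`` reads without replacement.

    The drawn counts follow the multivariate hypergeometric distribution
    over the clonotype read counts, i.e. the exact distribution of taking
    ``depth`` reads out of the observed pool. Clonotypes drawn zero times
    are dropped. Deterministic given the seed (or generator state).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if depth > sample.depth:
        raise ValueError(
            f"rarefaction depth {depth} exceeds sample depth {sample.depth}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = sample.counts()
    drawn = rng.multivariate_hypergeometric(counts, depth)
    clonotypes = [
        Clonotype(c.cdr3_nt, c.cdr3_aa, c.v_gene, c.j_gene, int(n))
        for c, n in zip(sample.clonotypes, drawn)
        if n > 0
    ]
    return RepertoireSample(
        clonotypes=clonotypes,
        patient_id=sample.patient_id,
        timepoint=sample.timepoint,
        discarded_reads=sample.discarded_reads,
        source=sample.source,
    )


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(freqs.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {freqs.sum()!r}, not 1")
    return freqs


def shannon_diversity(freqs) -> float:
    """Shannon entropy H = -sum p_i ln p_i over clonotype frequencies."""
    freqs = _check_freqs(freqs)
    return float(-(freqs * np.log(freqs)).sum())


def pielou_evenness(freqs) -> float:
    """Pielou's J = H / ln S; NaN for a single-clone repertoire (S = 1)."""
    freqs = _check_freqs(freqs)
    s = freqs.size
    if s == 1:
        return math.nan
    return shannon_diversity(freqs) / math.log(s)


def convergence_frequency(sample: RepertoireSample) -> float:
    """Cumulative read fraction in convergent (V gene, CDR3 aa) groups.

    Dimensionless proportion in [0, 1]; 0 when every amino-acid sequence is
    unique within its V gene.
    """
    depth = sample.depth
    if depth == 0:
        raise ValueError("cannot compute convergence on a zero-depth sample")
    return sum(g.aggregate_count for g in convergent_groups(sample)) / depth


def unique_clone_count(sample: RepertoireSample) -> int:
    """Number of distinct (CDR3 nt, V, J) keys in a collapsed sample."""
    return len({c.key for c in sample.clonotypes})


def percent_decline(pre: float, post: float) -> float:
    """(pre - post) / pre x 100; positive when the count dropped."""
    if pre <= 0:
        raise ValueError(f"pre must be positive, got {pre}")
    if post < 0:
        raise ValueError(f"post must be non-negative, got {post}")
    return (pre - post) / pre * 100.0


def compute_sample_metrics(
    sample: RepertoireSample,
    patient_id: Optional[str] = None,
    timepoint: Optional[str] = None,
    group: Optional[str] = None,
) -> SampleMetrics:
    """Bundle the four per-sample metrics plus depth and richness."""
    freqs = sample.frequencies()
    return SampleMetrics(
        patient_id=patient_id or sample.patient_id or "NA",
        timepoint=timepoint or sample.timepoint or "NA",
        group=group,
        depth=sample.depth,
        unique_clones=unique_clone_count(sample),
        shannon=shannon_diversity(freqs),
        evenness=pielou_evenness(freqs),
        convergence=convergence_frequency(sample),
    )


def compute_delta(
    patient_id: str,
    group: Optional[str],
    pre_clones: int,
    post_clones: int,
) -> DeltaMetrics:
    """T1 -> T2 unique-clone change for one patient."""
    return DeltaMetrics(
        patient_id=patient_id,
        group=group,
        pre_clones=pre_clones,
        post_clones=post_clones,
        delta_clones=post_clones - pre_clones,
        percent_decline=percent_decline(pre_clones, post_clones),
    )
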