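from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from tcrdyn.model import Clonotype, RepertoireSample
from tcrdyn.simulate import (
    SimulationConfig,
    simulate_longitudinal_cohort,
    synonymous_variants,
)


@pytest.fixture
def convergent_toy_sample() -> RepertoireSample:
    """Hand-built sample: one convergent pair (70 reads) plus a bystander.

    TRBV5-1/CASSLF appears as two distinct nt sequences (counts 50 + 20);
    the same amino-acid sequence under TRBV7-2 (30 reads) is no group on
    its own. Depth 100, so convergence frequency is 0.70.
    """
    nt1, nt2, nt3 = synonymous_variants("CASSLF", 3, seed=7)
    return RepertoireSample(
        clonotypes=[
            Clonotype(nt1, "CASSLF", "TRBV5-1", "TRBJ2-1", 50),
            Clonotype(nt2, "CASSLF", "TRBV5-1", "TRBJ2-7", 20),
            Clonotype(nt3, "CASSLF", "TRBV7-2", "TRBJ2-1", 30),
        ]
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Desk-sized synthetic cohort shared across pipeline tests."""
    config = SimulationConfig(
        n_dcg=5,
        n_pd=3,
        clones_t1=250,
        depth=5_000,
        public_clones=10,
        t3_for_pd=True,
        seed=11,
    )
    return simulate_longitudinal_cohort(config)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort, tmp_path_factory):
    from tcrdyn.simulate import write_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    manifest_path = write_cohort(tiny_cohort, outdir)
    return manifest_path


def brute_force_convergent_classes(sample: RepertoireSample):
    """Independent all-pairs oracle for convergent-group detection.

    Compares every clonotype pair for V + amino-acid identity with differing
    nucleotide sequences and takes the connected classes.
    """
    n = len(sample.clonotypes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = sample.clonotypes[i], sample.clonotypes[j]
            if a.v_gene == b.v_gene and a.cdr3_aa == b.cdr3_aa:
                union(i, j)
    classes = defaultdict(list)
    for i in range(n):
        classes[find(i)].append(sample.clonotypes[i])
    out = {}
    for members in classes.values():
        nts = {c.cdr3_nt for c in members}
        if len(nts) >= 2:
            key = (members[0].v_gene, members[0].cdr3_aa)
            out[key] = (frozenset(nts), sum(c.count for c in members))
    return out


def logrank_oracle(times, events, groups) -> float:
    """Hand-rolled two-group log-rank chi-square p-value (1 df)."""
    from scipy.stats import chi2

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    assert len(labels) == 2
    in1 = groups == labels[0]
    obs1 = 0.0
    exp1 = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in1).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (obs1 - exp1) ** 2 / var
    return float(chi2.sf(stat, df=1))
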