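"""Synthetic longitudinal TCR-beta cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-sample repertoires of thousands of clonotypes with power-law-like
abundances, convergent (V, CDR3-aa) classes created through codon
degeneracy, group-specific clone retention between baseline (T1) and
post-treatment (T2), group-specific convergence levels, shared dominant
(public) clonotypes within the disease-control group versus idiosyncratic
per-patient dominance in progressive disease, and exponential survival with
administrative right censoring. Every generated junction is productive by
construction, and the intended amino-acid sequence always equals the
translation of the generated nucleotide sequence.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_name

from . import io as tio
from .model import Clonotype, CohortManifest, PatientRecord, RepertoireSample
from ._genes import TRBJ_NAMES, TRBJ_WEIGHTS, TRBV_NAMES, TRBV_WEIGHTS

# sense codons per amino acid, deterministic order
_FWD = unambiguous_dna_by_name["Standard"].forward_table
CODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c in _FWD if _FWD[c] == aa))
    for aa in sorted(set(_FWD.values()))
}
AA_ALPHABET = "".join(sorted(CODONS_BY_AA))

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def max_encodings(cdr3_aa: str) -> int:
    """Number of distinct nucleotide sequences encoding an amino-acid string."""
    total = 1
    for res in cdr3_aa:
        if res not in CODONS_BY_AA:
            raise ValueError(f"unknown amino acid {res!r} in {cdr3_aa!r}")
        total *= len(CODONS_BY_AA[res])
    return total


def synonymous_variants(cdr3_aa: str, k: int, seed: RngLike = None) -> list[str]:
    """Draw ``k`` distinct nucleotide sequences that all translate to ``cdr3_aa``.

    Deterministic given the seed. Raises when ``k`` exceeds the number of
    possible encodings under the standard genetic code (reported in the
    error message).
    """
    if not cdr3_aa:
        raise ValueError("empty amino-acid sequence")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    total = max_encodings(cdr3_aa)
    if k > total:
        raise ValueError(
            f"{cdr3_aa!r} has only {total} possible encodings, cannot draw {k}"
        )
    rng = _as_rng(seed)
    codon_lists = [CODONS_BY_AA[res] for res in cdr3_aa]
    if total <= 8192:
        all_encodings = ["".join(t) for t in itertools.product(*codon_lists)]
        idx = rng.permutation(total)[:k]
        return [all_encodings[i] for i in idx]
    # huge space: rejection-sample random codon choices until k distinct
    seen: dict[str, None] = {}
    while len(seen) < k:
        nt = "".join(codons[rng.integers(len(codons))] for codons in codon_lists)
        seen.setdefault(nt, None)
    return list(seen)


@dataclass
class SimulationConfig:
    """Cohort-level generator settings; defaults define the study conditions.

    Retention complements (1 - retention) set the expected T1->T2 unique-
    clone decline per group; convergence injections set the read-mass
    fraction in convergent groups; hazards are exponential death rates per
    day with administrative censoring at ``censor_day``.
    """

    n_dcg: int = 11
    n_pd: int = 4
    clones_t1: int = 2800
    abundance_shape: float = 1.0
    depth: int = 50_000
    convergence_injection_dcg: float = 0.0040
    convergence_injection_pd: float = 0.0023
    retention_dcg: float = 0.84
    retention_pd: float = 0.59
    hazard_dcg: float = 0.0004
    hazard_pd: float = 0.0035
    censor_day: float = 420.0
    pr_fraction: float = 4 / 11
    novel_clone_fraction: float = 0.0
    public_clones: int = 25
    public_mass_dcg: float = 0.15
    pd_dominant_mass: tuple[float, float] = (0.05, 0.35)
    convergence_t2_factor_dcg: float = 0.6
    pd_t2_rise: float = 3.0
    t3_for_pd: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "convergence_injection_dcg",
            "convergence_injection_pd",
            "retention_dcg",
            "retention_pd",
            "pr_fraction",
            "novel_clone_fraction",
            "public_mass_dcg",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_dcg < 1 or self.n_pd < 1:
            raise ValueError("need at least one patient per group")
        if self.clones_t1 < 1:
            raise ValueError("clones_t1 must be >= 1")
        if self.depth < self.clones_t1:
            raise ValueError("depth must be >= clones_t1")
        if self.hazard_dcg < 0 or self.hazard_pd < 0 or self.censor_day < 0:
            raise ValueError("hazards and censor_day must be non-negative")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SyntheticCohort:
    manifest: CohortManifest
    samples: dict[tuple[str, str], RepertoireSample]
    ground_truth: dict = field(default_factory=dict)


@dataclass
class _SimClone:
    """One underlying nucleotide clonotype with its relative abundance."""

    v: str
    j: str
    aa: str
    nt: str
    p: float


def _random_cdr3(rng: np.random.Generator, used: set[str]) -> str:
    """Random CDR3 amino-acid string, length 12-17, anchored C...F, unique."""
    while True:
        length = int(rng.integers(12, 18))
        middle = "".join(
            AA_ALPHABET[i] for i in rng.integers(len(AA_ALPHABET), size=length - 2)
        )
        aa = "C" + middle + "F"
        if aa not in used:
            used.add(aa)
            return aa


def _encode(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS_BY_AA[res][rng.integers(len(CODONS_BY_AA[res]))] for res in aa
    )


def _base_population(
    n_clones: int, abundance_shape: float, rng: np.random.Generator
) -> list[_SimClone]:
    ranks = np.arange(1, n_clones + 1, dtype=float)
    p = ranks ** (-abundance_shape)
    p /= p.sum()
    vs = rng.choice(len(TRBV_NAMES), size=n_clones, p=TRBV_WEIGHTS)
    js = rng.choice(len(TRBJ_NAMES), size=n_clones, p=TRBJ_WEIGHTS)
    used: set[str] = set()
    pop = []
    for i in range(n_clones):
        aa = _random_cdr3(rng, used)
        pop.append(
            _SimClone(
                v=TRBV_NAMES[vs[i]],
                j=TRBJ_NAMES[js[i]],
                aa=aa,
                nt=_encode(aa, rng),
                p=float(p[i]),
            )
        )
    return pop


def _convergent_mass(pop: list[_SimClone]) -> float:
    """Abundance mass currently sitting in classes with >= 2 distinct nt."""
    by_class: dict[tuple[str, str], list[_SimClone]] = {}
    for c in pop:
        by_class.setdefault((c.v, c.aa), []).append(c)
    mass = 0.0
    for members in by_class.values():
        if len({m.nt for m in members}) >= 2:
            mass += sum(m.p for m in members)
    return mass


def _inject_convergence(
    pop: list[_SimClone], target: float, rng: np.random.Generator
) -> float:
    """Split clones into synonymous variants until ~``target`` mass is convergent.

    Greedy over clones in descending abundance: a clone is converted when its
    mass fits in the remaining budget, splitting its abundance across 2-4
    distinct synonymous encodings. Returns the realized convergent mass.
    Modifies ``pop`` in place.
    """
    realized = _convergent_mass(pop)
    if target <= realized:
        return realized
    remaining = target - realized
    # spread the injected mass over several classes (each at most ~1/6 of
    # the budget) so later reductions have fine enough granularity
    cap = remaining / 6.0
    singles = sorted(
        (i for i, c in enumerate(pop)),
        key=lambda i: -pop[i].p,
    )
    converted: list[_SimClone] = []
    drop: set[int] = set()
    class_nts: dict[tuple[str, str], set[str]] = {}
    for c in pop:
        class_nts.setdefault((c.v, c.aa), set()).add(c.nt)
    for i in singles:
        c = pop[i]
        if len(class_nts[(c.v, c.aa)]) >= 2:
            continue  # already convergent
        if c.p > min(cap, remaining * 1.02):
            continue
        m = int(rng.integers(2, 5))
        m = min(m, max_encodings(c.aa))
        if m < 2:
            continue
        nts = synonymous_variants(c.aa, m, rng)
        shares = rng.dirichlet(np.full(m, 8.0)) * c.p
        for nt, share in zip(nts, shares):
            converted.append(_SimClone(v=c.v, j=c.j, aa=c.aa, nt=nt, p=float(share)))
        drop.add(i)
        remaining -= c.p
        if remaining <= 1e-12:
            break
    kept = [c for i, c in enumerate(pop) if i not in drop]
    pop[:] = kept + converted
    return _convergent_mass(pop)


def _reduce_convergence(pop: list[_SimClone], target: float) -> float:
    """De-converge classes (merge synonymous variants) down toward ``target``.

    Greedy over convergent classes in descending mass: a class is collapsed
    onto a single nucleotide sequence whenever removing it keeps the
    convergent mass at or above the target. Modifies ``pop`` in place.
    """
    by_class: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(pop):
        by_class.setdefault((c.v, c.aa), []).append(i)
    conv_classes = [
        (key, idxs)
        for key, idxs in by_class.items()
        if len({pop[i].nt for i in idxs}) >= 2
    ]
    realized = sum(sum(pop[i].p for i in idxs) for _, idxs in conv_classes)
    conv_classes.sort(key=lambda kv: -sum(pop[i].p for i in kv[1]))
    merged: set[int] = set()
    extra: list[_SimClone] = []
    for _key, idxs in conv_classes:
        mass = sum(pop[i].p for i in idxs)
        if realized - mass < target:
            continue
        first = pop[idxs[0]]
        extra.append(_SimClone(first.v, first.j, first.aa, first.nt, mass))
        merged.update(idxs)
        realized -= mass
        if realized <= target:
            break
    if merged:
        pop[:] = [c for i, c in enumerate(pop) if i not in merged] + extra
    return _convergent_mass(pop)


def _set_convergence(
    pop: list[_SimClone], target: float, rng: np.random.Generator
) -> float:
    """Move the convergent read mass of ``pop`` toward ``target`` either way."""
    realized = _convergent_mass(pop)
    if realized < target:
        return _inject_convergence(pop, target, rng)
    if realized > target:
        return _reduce_convergence(pop, target)
    return realized


def _draw_reads(
    pop: list[_SimClone],
    depth: int,
    rng: np.random.Generator,
    patient_id: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> RepertoireSample:
    probs = np.asarray([c.p for c in pop], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(depth, probs)
    clonotypes = [
        Clonotype(cdr3_nt=c.nt, cdr3_aa=c.aa, v_gene=c.v, j_gene=c.j, count=int(n))
        for c, n in zip(pop, counts)
        if n > 0
    ]
    clonotypes.sort(key=lambda c: (-c.count, c.key))
    return RepertoireSample(
        clonotypes=clonotypes, patient_id=patient_id, timepoint=timepoint
    )


def sample_repertoire(
    n_clones: int,
    abundance_shape: float,
    depth: int,
    convergence_injection: float,
    seed: RngLike = None,
    patient_id: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> RepertoireSample:
    """One synthetic repertoire: power-law abundances, optional convergence.

    Relative clone abundances are proportional to rank^(-shape); reads are
    drawn multinomially to ``depth``. With ``convergence_injection = 0``
    every (V, CDR3-aa) class holds a single nucleotide sequence, so the
    sample's convergence frequency is exactly zero.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if depth < n_clones:
        raise ValueError(f"depth {depth} < n_clones {n_clones}")
    if not 0.0 <= convergence_injection <= 1.0:
        raise ValueError("convergence_injection must be in [0, 1]")
    rng = _as_rng(seed)
    pop = _base_population(n_clones, abundance_shape, rng)
    _inject_convergence(pop, convergence_injection, rng)
    return _draw_reads(pop, depth, rng, patient_id=patient_id, timepoint=timepoint)


def _retain(
    pop: list[_SimClone],
    retention: float,
    rng: np.random.Generator,
    always_keep: Optional[set[int]] = None,
) -> tuple[list[_SimClone], float]:
    """Bernoulli clone retention with renormalised abundances."""
    keep = rng.random(len(pop)) < retention
    if always_keep:
        for i in always_keep:
            keep[i] = True
    kept = [
        _SimClone(c.v, c.j, c.aa, c.nt, c.p) for c, k in zip(pop, keep) if k
    ]
    if not kept:  # degenerate tiny repertoires: keep the largest clone
        top = max(range(len(pop)), key=lambda i: pop[i].p)
        kept = [pop[top]]
    total = sum(c.p for c in kept)
    for c in kept:
        c.p /= total
    return kept, float(np.mean(keep))


def _add_novel(
    pop: list[_SimClone], fraction: float, rng: np.random.Generator
) -> None:
    if fraction <= 0:
        return
    n_new = int(round(fraction * len(pop)))
    if n_new == 0:
        return
    used = {c.aa for c in pop}
    p_new = float(np.median([c.p for c in pop]))
    vs = rng.choice(len(TRBV_NAMES), size=n_new, p=TRBV_WEIGHTS)
    js = rng.choice(len(TRBJ_NAMES), size=n_new, p=TRBJ_WEIGHTS)
    for i in range(n_new):
        aa = _random_cdr3(rng, used)
        pop.append(
            _SimClone(
                v=TRBV_NAMES[vs[i]],
                j=TRBJ_NAMES[js[i]],
                aa=aa,
                nt=_encode(aa, rng),
                p=p_new,
            )
        )
    total = sum(c.p for c in pop)
    for c in pop:
        c.p /= total


def simulate_longitudinal_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full longitudinal cohort with ground truth attached.

    Disease-control patients share a pool of dominant public clonotypes
    (stable repertoire architecture); progressive-disease patients each get
    an idiosyncratic dominant private clone of variable mass (heterogeneous
    architecture). T2 repertoires arise from Bernoulli clone retention at
    the group rate, renormalisation, optional novel-clone influx, and a
    convergence top-up to the group's injection target. Survival times are
    exponential with the group hazard, censored at ``config.censor_day``.
    """
    rng = np.random.default_rng(config.seed)

    # shared public pool for the disease-control group
    used_public: set[str] = set()
    public: list[_SimClone] = []
    if config.public_clones > 0 and config.public_mass_dcg > 0:
        weights = rng.dirichlet(np.full(config.public_clones, 2.0))
        vs = rng.choice(len(TRBV_NAMES), size=config.public_clones, p=TRBV_WEIGHTS)
        js = rng.choice(len(TRBJ_NAMES), size=config.public_clones, p=TRBJ_WEIGHTS)
        for i in range(config.public_clones):
            aa = _random_cdr3(rng, used_public)
            public.append(
                _SimClone(
                    v=TRBV_NAMES[vs[i]],
                    j=TRBJ_NAMES[js[i]],
                    aa=aa,
                    nt=_encode(aa, rng),
                    p=float(weights[i]) * config.public_mass_dcg,
                )
            )

    n_pr = int(round(config.pr_fraction * config.n_dcg))
    groups = ["DCG"] * config.n_dcg + ["PD"] * config.n_pd
    responses = (
        ["PR"] * n_pr + ["SD"] * (config.n_dcg - n_pr) + ["PD"] * config.n_pd
    )
    samples: dict[tuple[str, str], RepertoireSample] = {}
    patients: list[PatientRecord] = []
    per_patient_truth: dict[str, dict] = {}

    for idx, (group, response) in enumerate(zip(groups, responses)):
        pid = f"P{idx + 1:03d}"
        retention = config.retention_dcg if group == "DCG" else config.retention_pd
        injection = (
            config.convergence_injection_dcg
            if group == "DCG"
            else config.convergence_injection_pd
        )
        n_clones = max(
            50, int(round(rng.normal(config.clones_t1, 0.08 * config.clones_t1)))
        )
        pop = _base_population(n_clones, config.abundance_shape, rng)

        protected: set[int] = set()
        if group == "DCG" and public:
            # private clones rescaled to leave room for the shared pool
            for c in pop:
                c.p *= 1.0 - config.public_mass_dcg
            jitter = np.exp(rng.normal(0.0, 0.2, size=len(public)))
            pub_mass = config.public_mass_dcg
            pw = np.asarray([c.p for c in public]) * jitter
            pw *= pub_mass / pw.sum()
            for c, w in zip(public, pw):
                pop.append(_SimClone(c.v, c.j, c.aa, c.nt, float(w)))
            protected = set(range(len(pop) - len(public), len(pop)))
        elif group == "PD":
            lo, hi = config.pd_dominant_mass
            dom = float(rng.uniform(lo, hi))
            rest = 1.0 - dom
            scale = rest / (1.0 - pop[0].p)
            for c in pop[1:]:
                c.p *= scale
            pop[0].p = dom
            protected = {0}

        inj_t1 = _inject_convergence(pop, injection, rng)
        samples[(pid, "T1")] = _draw_reads(
            pop, config.depth, rng, patient_id=pid, timepoint="T1"
        )

        pop_t2, realized_retention = _retain(
            pop, retention, rng, always_keep=protected
        )
        _add_novel(pop_t2, config.novel_clone_fraction, rng)
        if group == "DCG":
            target_t2 = injection * config.convergence_t2_factor_dcg
        elif config.t3_for_pd:
            # transient activation scenario: convergence rises at T2
            target_t2 = min(injection * config.pd_t2_rise, 1.0)
        else:
            target_t2 = injection
        inj_t2 = _set_convergence(pop_t2, target_t2, rng)
        samples[(pid, "T2")] = _draw_reads(
            pop_t2, config.depth, rng, patient_id=pid, timepoint="T2"
        )

        has_t3 = config.t3_for_pd and group == "PD"
        if has_t3:
            pop_t3, _ = _retain(pop_t2, retention, rng)
            _set_convergence(pop_t3, 0.7 * injection, rng)
            samples[(pid, "T3")] = _draw_reads(
                pop_t3, config.depth, rng, patient_id=pid, timepoint="T3"
            )

        hazard = config.hazard_dcg if group == "DCG" else config.hazard_pd
        if hazard > 0:
            raw_os = float(rng.exponential(1.0 / hazard))
        else:
            raw_os = math.inf
        event = 1 if raw_os <= config.censor_day else 0
        os_days = min(raw_os, config.censor_day)

        per_patient_truth[pid] = {
            "group": group,
            "n_clones": n_clones,
            "realized_retention": realized_retention,
            "realized_injection_t1": inj_t1,
            "realized_injection_t2": inj_t2,
            "raw_os": raw_os,
        }
        sample_paths: dict[str, Path] = {}  # filled by write_cohort
        patients.append(
            PatientRecord(
                patient_id=pid,
                response=response,
                os_days=round(os_days, 1),
                event=event,
                sample_paths=sample_paths,
            )
        )

    manifest = CohortManifest(patients=patients)
    return SyntheticCohort(
        manifest=manifest,
        samples=samples,
        ground_truth={"config": config.as_dict(), "patients": per_patient_truth},
    )


def write_cohort(cohort: SyntheticCohort, outdir: Union[str, Path]) -> Path:
    """Write all samples as AIRR TSVs plus a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (pid, tp), sample in cohort.samples.items():
        fname = f"{pid}_{tp}.tsv"
        tio.write_repertoire(sample, outdir / fname)
        cohort.manifest.by_id(pid).sample_paths[tp] = outdir / fname
    manifest_path = outdir / "manifest.csv"
    # store paths relative to the manifest for a relocatable cohort
    rel = CohortManifest(
        patients=[
            PatientRecord(
                patient_id=p.patient_id,
                response=p.response,
                os_days=p.os_days,
                event=p.event,
                sample_paths={tp: Path(pth.name) for tp, pth in p.sample_paths.items()},
            )
            for p in cohort.manifest
        ]
    )
    tio.write_cohort_manifest(rel, manifest_path)
    return manifest_path
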