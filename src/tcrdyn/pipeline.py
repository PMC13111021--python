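"""End-to-end orchestration: ingest, rarefy, metrics, PCA, tests, survival.

Pooled inferential analyses use only T1 and T2 samples; T3 samples (taken
at confirmed progression) are summarised descriptively per patient and
never enter group tests. The BH-FDR family is exactly the registered list
of primary tests — three by default — rather than every p-value printed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as tio
from .metrics import compute_delta, compute_sample_metrics, rarefy
from .model import CohortManifest, RepertoireSample
from .multivariate import build_frequency_matrix, pc_group_test, pca_scores
from .stats import KmResult, TestResult, bh_adjust, km_logrank, response_summary
from .stats import spearman_trend, wilcoxon_rank_sum

ATTRITION_STAGES = (
    "enrolled",
    "T1-evaluable",
    "T2-evaluable",
    "T3-evaluable",
    "OS-evaluable",
)

DEFAULT_PRIMARY_TESTS = (
    "spearman_convergence_trend_dcg",
    "wilcoxon_delta_clones",
    "wilcoxon_pc1",
)


@dataclass
class RunConfig:
    manifest_path: Union[str, Path]
    output_dir: Optional[Union[str, Path]] = None
    rarefaction_depth: Optional[int] = None  # None -> min across loaded samples
    seed: int = 0
    top_m: int = 500
    pca_components: int = 2
    matrix_level: str = "aa"
    primary_tests: tuple[str, ...] = DEFAULT_PRIMARY_TESTS
    alpha_p: float = 0.05
    alpha_q: float = 0.05

    def __post_init__(self) -> None:
        if not self.primary_tests:
            raise ValueError("primary-test registry must be non-empty")


@dataclass
class AttritionTable:
    counts: pd.DataFrame  # columns: stage, n
    reasons: pd.DataFrame  # columns: stage, reason, n


@dataclass
class RunReport:
    seed: int
    rarefaction_depth: int
    metrics: pd.DataFrame
    deltas: pd.DataFrame
    tests: list[TestResult]
    pca: Optional[object]
    pc_dispersion: dict
    km: Optional[KmResult]
    attrition: AttritionTable
    exclusions: list[tuple[str, str, str]]
    log: list[dict] = field(default_factory=list)

    def tests_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": t.name,
                "statistic": t.statistic,
                "p": t.p,
                "q": t.q if t.q is not None else math.nan,
                "evaluable": t.evaluable,
                "note": t.note,
                **{f"n_{k}": v for k, v in t.n.items()},
            }
            for t in self.tests
        ]
        return pd.DataFrame(rows)


def attrition_accounting(
    manifest: Union[CohortManifest, int],
    exclusions: Sequence[tuple[str, str, str]] = (),
) -> AttritionTable:
    """Stage-by-stage cohort accounting with per-reason tallies.

    ``exclusions`` holds (patient, stage, reason) triples; a triple at stage
    S removes the patient from S onwards along the sample track
    (enrolled -> T1 -> T2 -> T3). OS follow-up is independent of sample
    availability, so the OS-evaluable count is the T1-evaluable count minus
    exclusions recorded explicitly at the OS stage.
    """
    enrolled = manifest if isinstance(manifest, int) else len(manifest)
    per_stage: dict[str, int] = {s: 0 for s in ATTRITION_STAGES}
    reason_rows: dict[tuple[str, str], int] = {}
    for _patient, stage, reason in exclusions:
        if stage not in ATTRITION_STAGES:
            raise ValueError(f"unknown attrition stage {stage!r}")
        per_stage[stage] += 1
        reason_rows[(stage, reason)] = reason_rows.get((stage, reason), 0) + 1

    counts = {"enrolled": enrolled}
    running = enrolled
    for stage in ("T1-evaluable", "T2-evaluable", "T3-evaluable"):
        running -= per_stage[stage]
        counts[stage] = running
    counts["OS-evaluable"] = counts["T1-evaluable"] - per_stage["OS-evaluable"]

    counts_df = pd.DataFrame(
        {"stage": list(counts), "n": list(counts.values())}
    )
    reasons_df = pd.DataFrame(
        [
            {"stage": s, "reason": r, "n": n}
            for (s, r), n in sorted(reason_rows.items())
        ],
        columns=["stage", "reason", "n"],
    )
    return AttritionTable(counts=counts_df, reasons=reasons_df)


def _not_evaluable(name: str, note: str) -> TestResult:
    return TestResult(
        name=name, statistic=math.nan, p=math.nan, evaluable=False, note=note
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis; deterministic given ``config.seed``."""
    manifest = tio.read_cohort_manifest(config.manifest_path)
    log: list[dict] = [{"event": "start", "seed": config.seed}]
    exclusions: list[tuple[str, str, str]] = []

    # ---- ingest -----------------------------------------------------------
    raw: dict[tuple[str, str], RepertoireSample] = {}
    for patient in manifest:
        for tp in ("T1", "T2", "T3"):
            if tp in patient.sample_paths:
                s = tio.read_repertoire(patient.sample_paths[tp])
                s.patient_id = patient.patient_id
                s.timepoint = tp
                raw[(patient.patient_id, tp)] = s
            else:
                exclusions.append(
                    (patient.patient_id, f"{tp}-evaluable", "sample unavailable")
                )
    if not raw:
        raise ValueError("no sample file could be loaded from the manifest")

    # ---- rarefaction QC ---------------------------------------------------
    depths = {k: s.depth for k, s in raw.items()}
    if config.rarefaction_depth is None:
        target = min(depths.values())
    else:
        target = config.rarefaction_depth
    kept = {}
    for key in sorted(raw):
        if depths[key] < target:
            exclusions.append(
                (key[0], f"{key[1]}-evaluable", "below rarefaction depth")
            )
            log.append(
                {
                    "event": "exclude",
                    "sample": f"{key[0]}_{key[1]}",
                    "reason": "below rarefaction depth",
                    "depth": depths[key],
                }
            )
            continue
        kept[key] = raw[key]
    if not kept:
        raise ValueError(f"no sample meets the rarefaction depth {target}")
    log.append({"event": "rarefy", "depth": target})

    rng = np.random.default_rng(config.seed)
    rarefied = {k: rarefy(kept[k], target, rng) for k in sorted(kept)}

    # ---- per-sample metrics ----------------------------------------------
    metrics_rows = []
    for (pid, tp), s in sorted(rarefied.items()):
        metrics_rows.append(
            compute_sample_metrics(
                s, patient_id=pid, timepoint=tp, group=manifest.by_id(pid).group
            )
        )
    metrics_df = tio.metrics_to_frame(metrics_rows)

    # ---- per-patient deltas (T1 -> T2) -----------------------------------
    deltas = []
    for patient in manifest:
        pid = patient.patient_id
        if (pid, "T1") in rarefied and (pid, "T2") in rarefied:
            pre = len(rarefied[(pid, "T1")].clonotypes)
            post = len(rarefied[(pid, "T2")].clonotypes)
            deltas.append(compute_delta(pid, patient.group, pre, post))
    deltas_df = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "group": d.group or "",
                "pre_clones": d.pre_clones,
                "post_clones": d.post_clones,
                "delta_clones": d.delta_clones,
                "percent_decline": d.percent_decline,
            }
            for d in deltas
        ],
        columns=[
            "patient_id",
            "group",
            "pre_clones",
            "post_clones",
            "delta_clones",
            "percent_decline",
        ],
    )

    # ---- PCA on pooled T1/T2 samples of grouped patients ------------------
    pca_samples = [
        s
        for (pid, tp), s in sorted(rarefied.items())
        if tp in ("T1", "T2") and manifest.by_id(pid).group is not None
    ]
    pca_groups = [manifest.by_id(s.patient_id).group for s in pca_samples]
    pca_result = None
    pc_dispersion: dict = {}
    if len(pca_samples) >= 3:
        matrix = build_frequency_matrix(
            pca_samples, top_m=config.top_m, level=config.matrix_level
        )
        k = min(config.pca_components, len(pca_samples) - 1, matrix.shape[1])
        pca_result = pca_scores(matrix, k=k)

    # ---- primary tests ----------------------------------------------------
    tests: list[TestResult] = []
    for name in config.primary_tests:
        if name == "spearman_convergence_trend_dcg":
            sub = metrics_df[
                (metrics_df.group == "DCG") & (metrics_df.timepoint.isin(["T1", "T2"]))
            ]
            codes = sub.timepoint.map({"T1": 1, "T2": 2, "T3": 3})
            try:
                tests.append(
                    spearman_trend(sub.convergence.to_numpy(), codes.to_numpy(), name=name)
                )
            except ValueError as exc:
                tests.append(_not_evaluable(name, str(exc)))
        elif name == "wilcoxon_delta_clones":
            x = deltas_df.loc[deltas_df.group == "DCG", "delta_clones"].to_numpy()
            y = deltas_df.loc[deltas_df.group == "PD", "delta_clones"].to_numpy()
            if x.size == 0 or y.size == 0:
                tests.append(_not_evaluable(name, "a group has no delta"))
            else:
                tests.append(wilcoxon_rank_sum(x, y, name=name))
        elif name == "wilcoxon_pc1":
            if pca_result is None:
                tests.append(_not_evaluable(name, "PCA not computed"))
            else:
                try:
                    t, pc_dispersion = pc_group_test(pca_result, pca_groups, component=1)
                    t.name = name
                    tests.append(t)
                except ValueError as exc:
                    tests.append(_not_evaluable(name, str(exc)))
        else:
            raise ValueError(f"unknown primary test {name!r}")

    evaluable = [t for t in tests if t.evaluable]
    if evaluable:
        qs = bh_adjust([t.p for t in evaluable])
        for t, q in zip(evaluable, qs):
            t.q = float(q)

    # also record PC2 dispersion when PCA has two components
    if pca_result is not None and "PC2" in pca_result.scores.columns:
        try:
            _, disp2 = pc_group_test(pca_result, pca_groups, component=2)
            pc_dispersion = {"PC1": pc_dispersion, "PC2": disp2}
        except ValueError:
            pc_dispersion = {"PC1": pc_dispersion}

    # ---- survival ---------------------------------------------------------
    grouped = [p for p in manifest if p.group is not None]
    km = None
    if grouped and len({p.group for p in grouped}) >= 1:
        km = km_logrank(
            [p.os_days for p in grouped],
            [p.event for p in grouped],
            [p.group for p in grouped],
        )

    attrition = attrition_accounting(manifest, exclusions)
    report = RunReport(
        seed=config.seed,
        rarefaction_depth=target,
        metrics=metrics_df,
        deltas=deltas_df,
        tests=tests,
        pca=pca_result,
        pc_dispersion=pc_dispersion,
        km=km,
        attrition=attrition,
        exclusions=exclusions,
        log=log,
    )
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    report.deltas.to_csv(outdir / "deltas.tsv", sep="\t", index=False)
    report.tests_frame().to_csv(outdir / "tests.tsv", sep="\t", index=False)
    if report.pca is not None:
        report.pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        report.pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    if report.km is not None:
        rows = []
        for group, curve in report.km.curves.items():
            for t, s in zip(curve.times, curve.survival):
                rows.append({"group": group, "time": t, "survival": s})
        pd.DataFrame(rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    report.attrition.counts.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
    report.attrition.reasons.to_csv(
        outdir / "attrition_reasons.tsv", sep="\t", index=False
    )
    with open(outdir / "run_log.jsonl", "w") as fh:
        header = {
            "event": "report",
            "seed": report.seed,
            "rarefaction_depth": report.rarefaction_depth,
            "n_exclusions": len(report.exclusions),
        }
        fh.write(json.dumps(header) + "\n")
        for entry in report.log:
            fh.write(json.dumps(entry) + "\n")
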