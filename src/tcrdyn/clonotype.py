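"""Clonotype identity, junction translation and convergent-rearrangement detection.

Convergent rearrangement — distinct nucleotide sequences encoding the same
CDR3 amino-acid sequence with the same V gene — is the central bespoke
computation here; everything else (translation, gene-name normalisation,
count collapsing) exists to support it.
"""
from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq

from .model import Clonotype, ConvergentGroup, RepertoireSample

_VALID_NT = frozenset("ACGT")
_ALLELE_RE = re.compile(r"\*.*$")


@dataclass(frozen=True)
class RawRearrangementRecord:
    """One uncollapsed rearrangement row as parsed from an AIRR-style table."""

    v_call: str
    j_call: str
    junction: str
    junction_aa: Optional[str] = None
    duplicate_count: int = 1

    def __post_init__(self) -> None:
        if not self.junction:
            raise ValueError("junction must be non-empty")
        bad = set(self.junction) - _VALID_NT
        if bad:
            raise ValueError(
                f"junction contains non-ACGT symbols {sorted(bad)}: {self.junction!r}"
            )
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")


def normalize_gene_call(call: str) -> str:
    """Reduce a V/J call to a bare gene name.

    Strips whitespace, keeps the first gene of a multi-assignment
    ("/" or "," separated), and removes any "*NN" allele suffix.
    """
    call = call.strip()
    if not call:
        raise ValueError("empty gene call")
    first = re.split(r"[/,]", call)[0].strip()
    gene = _ALLELE_RE.sub("", first).strip()
    if not gene:
        raise ValueError(f"gene call {call!r} reduces to an empty name")
    return gene


# the convergence definition speaks of V gene segments, so the public name
# is V-flavoured; J calls go through the same rule
normalize_v_call = normalize_gene_call


def translate_junction(cdr3_nt: str) -> tuple[str, bool]:
    """Translate a CDR3 junction in frame 1 under the standard genetic code.

    Returns ``(aa, productive)`` where ``productive`` requires the length to
    be divisible by 3 and the translation to be stop-free. For out-of-frame
    junctions the translation of the complete codons is returned alongside
    ``False``.
    """
    bad = set(cdr3_nt) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGT symbol(s) {sorted(bad)} in junction {cdr3_nt!r}")
    n_codons = len(cdr3_nt) // 3
    aa = str(Seq(cdr3_nt[: 3 * n_codons]).translate())
    productive = (len(cdr3_nt) % 3 == 0) and ("*" not in aa)
    return aa, productive


def collapse_clonotypes(
    records: Iterable[RawRearrangementRecord],
) -> tuple[list[Clonotype], int]:
    """Collapse raw rearrangement rows into clonotypes.

    Identity key is (CDR3 nt, V gene, J gene) after gene-level normalisation;
    counts of identical keys are summed. Unproductive junctions (out of frame
    or containing a stop) are excluded; their summed read mass is returned as
    the discard tally so that counts stay lossless. Output order is
    deterministic: descending count, then lexicographic key.
    """
    merged: dict[tuple[str, str, str], int] = defaultdict(int)
    aa_of: dict[tuple[str, str, str], str] = {}
    discarded = 0
    for rec in records:
        nt = rec.junction.upper()
        aa, productive = translate_junction(nt)
        if not productive:
            discarded += rec.duplicate_count
            continue
        key = (nt, normalize_gene_call(rec.v_call), normalize_gene_call(rec.j_call))
        merged[key] += rec.duplicate_count
        aa_of[key] = aa
    clonotypes = [
        Clonotype(cdr3_nt=k[0], cdr3_aa=aa_of[k], v_gene=k[1], j_gene=k[2], count=n)
        for k, n in merged.items()
    ]
    clonotypes.sort(key=lambda c: (-c.count, c.key))
    return clonotypes, discarded


def convergent_groups(sample: RepertoireSample) -> list[ConvergentGroup]:
    """Find convergent (V gene, CDR3 aa) classes in a collapsed sample.

    A class qualifies when it contains two or more *distinct* nucleotide
    sequences; the J gene is deliberately not part of the key. Aggregate
    frequency uses the sample depth as denominator.
    """
    depth = sample.depth
    if depth == 0:
        raise ValueError("cannot compute convergent groups on a zero-depth sample")
    classes: dict[tuple[str, str], list[Clonotype]] = defaultdict(list)
    for c in sample.clonotypes:
        classes[(c.v_gene, c.cdr3_aa)].append(c)
    groups: list[ConvergentGroup] = []
    for (v, aa), members in sorted(classes.items()):
        nts = frozenset(c.cdr3_nt for c in members)
        if len(nts) < 2:
            continue
        agg = sum(c.count for c in members)
        groups.append(
            ConvergentGroup(
                v_gene=v,
                cdr3_aa=aa,
                members=nts,
                aggregate_count=agg,
                aggregate_frequency=agg / depth,
            )
        )
    return groups
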