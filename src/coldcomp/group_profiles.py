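"""Assemble per-organism, per-CDS-group metric distributions.

Only annotated proteins enter the analysis.  A protein contributes to every
cellular-function group it carries, to its subcellular-localization group,
and to the organism-wide group ``ALL``; groups are therefore not disjoint.
The per-(organism, group, metric) value lists built here are the samples
on which the Tukey screen and the difference regressions operate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import AA_ALPHABET, ALL_CODE, AnnotationRecord, InputError
from .composition_metrics import CompositionProfile

logger = logging.getLogger("coldcomp")

#: Metric identifiers: the 20 residue letters plus the grouped parameters.
DERIVED_METRICS = ("Vf", "VMf", "Tn", "Tln")
ALL_METRICS: tuple[str, ...] = tuple(AA_ALPHABET) + DERIVED_METRICS


@dataclass(frozen=True)
class GroupMetricSample:
    """Values of one metric over one organism's proteins in one group."""

    organism_id: str
    group_code: str
    metric: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _metric_value(profile: CompositionProfile, metric: str) -> float | None:
    if metric == "Vf":
        return profile.vf_pct
    if metric == "VMf":
        return profile.vmf_pct
    if metric == "Tn":
        return profile.tn_pct
    if metric == "Tln":
        return profile.tln_pct
    return profile.aa_pct[metric]


def build_group_samples(
    profiles: Sequence[CompositionProfile],
    annotations: Sequence[AnnotationRecord],
    metrics: Sequence[str] = ALL_METRICS,
) -> list[GroupMetricSample]:
    """One sample per (organism, group, metric) with n >= 1.

    Unannotated proteins are excluded.  For the dipeptide metrics Tn/Tln,
    only proteins with defined dipeptide fields contribute.  Output order is
    deterministic (organism, group, metric).
    """
    by_protein: dict[str, AnnotationRecord] = {}
    for a in annotations:
        by_protein[a.protein_id] = a
    bad = [m for m in metrics if m not in ALL_METRICS]
    if bad:
        raise InputError(f"unknown metrics {bad}")

    acc: dict[tuple[str, str, str], list[float]] = {}
    organisms = set()
    annotated_orgs = set()
    for prof in sorted(profiles, key=lambda p: (p.organism_id, p.protein_id)):
        organisms.add(prof.organism_id)
        ann = by_protein.get(prof.protein_id)
        if ann is None:
            continue
        annotated_orgs.add(prof.organism_id)
        groups = set(ann.group_codes) | {ALL_CODE}
        for metric in metrics:
            v = _metric_value(prof, metric)
            if v is None:
                continue
            for g in groups:
                acc.setdefault((prof.organism_id, g, metric), []).append(v)
    for org in organisms - annotated_orgs:
        logger.warning("organism %s has no annotated proteins; excluded", org)
    return [
        GroupMetricSample(org, g, metric, tuple(vals))
        for (org, g, metric), vals in sorted(acc.items())
    ]


def samples_by_cell(
    samples: Iterable[GroupMetricSample],
) -> dict[tuple[str, str], dict[str, GroupMetricSample]]:
    """Index samples as (group, metric) -> organism -> sample."""
    out: dict[tuple[str, str], dict[str, GroupMetricSample]] = {}
    for s in samples:
        out.setdefault((s.group_code, s.metric), {})[s.organism_id] = s
    return out


def normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip().casefold())


@dataclass(frozen=True)
class LabelMetricTable:
    """Per-annotation-label metric values across organisms.

    ``values`` maps organism -> mean metric over that organism's proteins
    carrying the label; ``presence`` counts the organisms.
    """

    label: str
    metric: str
    values: Mapping[str, float]

    @property
    def presence(self) -> int:
        return len(self.values)


def build_label_table(
    profiles: Sequence[CompositionProfile],
    annotations: Sequence[AnnotationRecord],
    min_label_presence: int = 3,
    metrics: Sequence[str] = DERIVED_METRICS,
) -> list[LabelMetricTable]:
    """Label-level tables for labels shared by >= ``min_label_presence`` organisms.

    Multiple same-label proteins within one organism are averaged.
    """
    prof_by_id = {p.protein_id: p for p in profiles}
    acc: dict[tuple[str, str, str], list[float]] = {}
    for a in annotations:
        prof = prof_by_id.get(a.protein_id)
        if prof is None:
            continue
        label = normalize_label(a.label)
        for metric in metrics:
            v = _metric_value(prof, metric)
            if v is not None:
                acc.setdefault((label, metric, prof.organism_id), []).append(v)

    per_label: dict[tuple[str, str], dict[str, float]] = {}
    for (label, metric, org), vals in acc.items():
        per_label.setdefault((label, metric), {})[org] = float(np.mean(vals))
    return [
        LabelMetricTable(label, metric, dict(sorted(orgvals.items())))
        for (label, metric), orgvals in sorted(per_label.items())
        if len(orgvals) >= min_label_presence
    ]


def bin_by_temperature(
    organism_temps: Mapping[str, float],
    temp_bins: Mapping[str, tuple[float, float]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Assign organisms to named inclusive temperature bins.

    Returns (bin -> organism set, unbinned organisms).  Overlapping bin
    definitions raise.
    """
    bins = sorted(temp_bins.items(), key=lambda kv: kv[1])
    for (na, (la, ha)), (nb, (lb, hb)) in zip(bins, bins[1:]):
        if hb < lb or ha < la:
            raise InputError(f"bin with inverted endpoints: {na if ha < la else nb}")
        if lb <= ha:
            raise InputError(f"overlapping bins {na} and {nb}")
    assignment: dict[str, set[str]] = {name: set() for name in temp_bins}
    unbinned: set[str] = set()
    for org, T in organism_temps.items():
        for name, (lo, hi) in temp_bins.items():
            if lo <= T <= hi:
                assignment[name].add(org)
                break
        else:
            unbinned.add(org)
    if unbinned:
        logger.warning("organisms outside all temperature bins: %s", sorted(unbinned))
    return assignment, unbinned


def samples_frame(samples: Iterable[GroupMetricSample]) -> pd.DataFrame:
    """Long-format export: organism, group, metric, n, mean, sd."""
    rows = [
        {
            "organism_id": s.organism_id,
            "group_code": s.group_code,
            "metric": s.metric,
            "n": s.n,
            "mean": s.mean,
            "sd": float(np.std(s.values, ddof=1)) if s.n > 1 else 0.0,
        }
        for s in samples
    ]
    return pd.DataFrame(rows)
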