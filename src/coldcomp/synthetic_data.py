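"""Synthetic study generator with planted statistical structure.

Emulates the design of an eight-organism cold-adapted-yeast study:
organisms with planted optimal growth temperatures spanning 10-22 degC
(two of them tied between 15 and 22, i.e. planted at 18.5), planted maximal
growth rates straddling 1 h^-1, per-CDS-group proteomes whose flexible
amino-acid content varies linearly with the planted OTG (or Gr) plus
sampling noise, and triplicate logistic growth curves measured at
4/10/15/22/30 degC whose rate peaks at the planted OTG.

Sequences are i.i.d. residue draws from per-protein Dirichlet-jittered
composition vectors, so residue-level metrics have exact multinomial
expectations and the dipeptide metrics have the analytic i.i.d. expectation
E[Tn] = sum of p_i p_j over negative dipeptides - both used as
self-checks.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_model import (
    AA_ALPHABET,
    AA_INDEX,
    DIPEPTIDES,
    AnnotationRecord,
    FlexibilityScheme,
    GrowthCurve,
    InputError,
    ProteinRecord,
    TmWeightTable,
    round_half_up,
    write_annotations,
    write_growth_csv,
    write_protein_fasta,
    write_tm_table,
)

#: Average amino-acid frequencies (percent) of well-curated protein
#: databases; the base composition every synthetic proteome starts from.
BASE_COMPOSITION: Mapping[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.63, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}

DEFAULT_GROUPS = ("ENZY", "RIBO", "TNFA", "CHFC", "METR", "PEPT")
MEASURED_TEMPS = (4.0, 10.0, 15.0, 22.0, 30.0)


@dataclass(frozen=True)
class PlantedGradient:
    """Linear dependence of one metric's expectation on one growth axis.

    ``metric`` must name a residue-set metric (a single letter, "Vf" or
    "VMf"); the dipeptide metrics cannot be planted by residue reweighting.
    ``slope`` is in percentage points per degC (axis "OTG") or per h^-1
    (axis "Gr"); the expectation equals the base value at ``reference``.
    """

    group: str
    metric: str
    slope: float
    axis: str = "OTG"
    reference: float = 16.0


@dataclass
class SyntheticStudySpec:
    """Complete description of a synthetic study; same seed, same bytes."""

    seed: int = 0
    organism_ids: tuple[str, ...] = tuple(f"yeast{i+1:02d}" for i in range(8))
    planted_otg: tuple[float, ...] = (10, 15, 15, 15, 18.5, 18.5, 22, 22)
    planted_gr: tuple[float, ...] = (0.6, 0.7, 1.2, 1.4, 1.1, 0.8, 1.3, 0.5)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    proteins_per_group: int = 300
    length_log_mu: float = 6.15
    length_log_sigma: float = 0.35
    min_length: int = 60
    dirichlet_concentration: float = 2000.0
    gradients: tuple[PlantedGradient, ...] = ()
    labels_per_group: int = 50
    # growth-curve model
    temperatures: tuple[float, ...] = MEASURED_TEMPS
    replicates: int = 3
    carrying_capacity: float = 2.0
    od0: float = 0.02
    rate_width: float = 16.0
    od_noise_sd: float = 0.005  # typical OD600 instrument repeatability
    t_max_h: float = 72.0
    t_step_h: float = 0.25

    def __post_init__(self):
        n = len(self.organism_ids)
        if not (len(self.planted_otg) == len(self.planted_gr) == n):
            raise InputError("planted OTG/Gr lists must match organism count")
        if self.proteins_per_group < 1:
            raise InputError("proteins_per_group must be >= 1")
        for g in self.gradients:
            if g.metric not in set(AA_ALPHABET) | {"Vf", "VMf"}:
                raise InputError(f"cannot plant gradient on metric {g.metric!r}")
            if g.group not in self.groups:
                raise InputError(f"gradient group {g.group!r} not in study groups")
        # validate planted compositions stay positive over the axis span
        for i in range(n):
            for g in self.groups:
                p = group_composition(self, g, i)
                if np.any(p <= 0):
                    raise InputError(
                        f"planted gradient drives composition negative for "
                        f"{self.organism_ids[i]}/{g}"
                    )

    @property
    def otg_display(self) -> tuple[int, ...]:
        return tuple(round_half_up(x) for x in self.planted_otg)


def _metric_mask(metric: str) -> np.ndarray:
    scheme = FlexibilityScheme()
    if metric == "Vf":
        letters = scheme.very_flexible
    elif metric == "VMf":
        letters = scheme.very_flexible | scheme.moderately_flexible
    else:
        letters = {metric}
    return np.array([a in letters for a in AA_ALPHABET])


def group_composition(spec: SyntheticStudySpec, group: str, organism_index: int) -> np.ndarray:
    """Expected residue probabilities for one organism's proteins in a group.

    Applies every planted gradient for the group by rescaling the metric's
    residue class against its complement, preserving within-class ratios.
    """
    p = np.array([BASE_COMPOSITION[a] for a in AA_ALPHABET])
    p = p / p.sum()
    for g in spec.gradients:
        if g.group != group:
            continue
        axis_val = (
            spec.planted_otg[organism_index] if g.axis == "OTG" else spec.planted_gr[organism_index]
        )
        mask = _metric_mask(g.metric)
        current = p[mask].sum()
        target = current + g.slope * (axis_val - g.reference) / 100.0
        if not 0 < target < 1:
            raise InputError(f"gradient {g} drives class probability to {target:.3f}")
        p = p.copy()
        comp = p[~mask].sum()
        p[mask] *= target / current
        p[~mask] *= (1 - target) / comp
    return p / p.sum()


def _org_rng(spec: SyntheticStudySpec, organism_index: int, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, organism, purpose)."""
    h = hashlib.sha256(
        f"{spec.seed}:{spec.organism_ids[organism_index]}:{stream}".encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def generate_proteome(
    spec: SyntheticStudySpec, organism_index: int
) -> tuple[list[ProteinRecord], list[AnnotationRecord]]:
    """Draw one organism's proteins and annotations.

    Each group contributes ``proteins_per_group`` proteins carrying that
    group as their (single) function code; labels cycle through a shared
    per-group label set so every label is present in every organism.
    """
    org = spec.organism_ids[organism_index]
    rng = _org_rng(spec, organism_index, "proteome")
    proteins: list[ProteinRecord] = []
    annotations: list[AnnotationRecord] = []
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    for group in spec.groups:
        p = group_composition(spec, group, organism_index)
        lengths = np.maximum(
            spec.min_length,
            rng.lognormal(spec.length_log_mu, spec.length_log_sigma, spec.proteins_per_group).astype(int),
        )
        probs = rng.dirichlet(spec.dirichlet_concentration * p, size=spec.proteins_per_group)
        for k in range(spec.proteins_per_group):
            idx = rng.choice(20, size=int(lengths[k]), p=probs[k])
            seq = bytes(aa[idx]).decode()
            pid = f"{org}_{group}_{k:04d}"
            proteins.append(ProteinRecord(pid, org, seq))
            annotations.append(
                AnnotationRecord(
                    pid,
                    f"{group.lower()} protein {k % spec.labels_per_group}",
                    frozenset({group}),
                    None,
                )
            )
    return proteins, annotations


def planted_rate(spec: SyntheticStudySpec, organism_index: int, temperature: float) -> float:
    """Unimodal r(T): quadratic in sqrt(r), single interior peak at planted OTG."""
    otg = spec.planted_otg[organism_index]
    r_opt = spec.planted_gr[organism_index]
    u = 1.0 - ((temperature - otg) / spec.rate_width) ** 2
    return float(r_opt * u * u) if u > 0 else 0.0


def generate_growth_curves(
    spec: SyntheticStudySpec, organism_index: int
) -> list[GrowthCurve]:
    """Replicate logistic OD600 curves over the measurement temperatures."""
    org = spec.organism_ids[organism_index]
    rng = _org_rng(spec, organism_index, "growth")
    t = np.arange(0.0, spec.t_max_h + 1e-9, spec.t_step_h)
    K, od0 = spec.carrying_capacity, spec.od0
    curves = []
    for T in spec.temperatures:
        r = planted_rate(spec, organism_index, T)
        if r > 0:
            od = K / (1.0 + (K - od0) / od0 * np.exp(-r * t))
        else:
            od = np.full_like(t, od0)
        for rep in range(1, spec.replicates + 1):
            noisy = od + rng.normal(0.0, spec.od_noise_sd, t.size)
            curves.append(
                GrowthCurve(org, float(T), rep, tuple(t), tuple(np.maximum(noisy, 1e-4)))
            )
    return curves


def generate_tm_table(
    seed: int, frac_negative: float = 0.25, frac_low: float = 0.25,
    low_threshold: float = 0.5,
) -> TmWeightTable:
    """A synthetic 400-dipeptide Tm-weight table with exact category counts.

    ``round_half_up(400 * frac)`` dipeptides get negative weights in
    (-3, 0), the next block gets low weights in [0, low_threshold), the
    rest weights in [low_threshold, 3).  Which dipeptides land in which
    category is a seeded permutation.
    """
    if frac_negative < 0 or frac_low < 0 or frac_negative + frac_low > 1:
        raise InputError("need frac_negative, frac_low >= 0 and sum <= 1")
    rng = np.random.default_rng(seed)
    n_neg = round_half_up(400 * frac_negative)
    n_low = round_half_up(400 * frac_low)
    if n_neg + n_low > 400:
        raise InputError("category counts exceed 400")
    order = rng.permutation(400)
    weights = np.empty(400)
    weights[order[:n_neg]] = rng.uniform(-3.0, -1e-6, n_neg)
    weights[order[n_neg : n_neg + n_low]] = rng.uniform(0.0, low_threshold * (1 - 1e-9), n_low)
    n_rest = 400 - n_neg - n_low
    weights[order[n_neg + n_low :]] = rng.uniform(low_threshold, 3.0, n_rest)
    return TmWeightTable(dict(zip(DIPEPTIDES, weights.tolist())), low_threshold)


@dataclass
class SyntheticStudy:
    """A fully generated study plus its planted truth."""

    spec: SyntheticStudySpec
    proteins: list[ProteinRecord]
    annotations: list[AnnotationRecord]
    curves: list[GrowthCurve]
    tm_table: TmWeightTable

    def proteins_by_organism(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {o: [] for o in self.spec.organism_ids}
        for p in self.proteins:
            out[p.organism_id].append(p)
        return out


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    proteins: list[ProteinRecord] = []
    annotations: list[AnnotationRecord] = []
    curves: list[GrowthCurve] = []
    for i in range(len(spec.organism_ids)):
        ps, anns = generate_proteome(spec, i)
        proteins.extend(ps)
        annotations.extend(anns)
        curves.extend(generate_growth_curves(spec, i))
    tm = generate_tm_table(spec.seed + 101)
    return SyntheticStudy(spec, proteins, annotations, curves, tm)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Write the study directory: per-organism FASTA, TSVs, CSV, truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    by_org = study.proteins_by_organism()
    for org, prots in by_org.items():
        p = outdir / f"{org}.faa"
        write_protein_fasta(prots, p)
        paths[f"fasta:{org}"] = str(p)
    write_annotations(study.annotations, outdir / "annotations.tsv")
    write_growth_csv(study.curves, outdir / "growth.csv")
    write_tm_table(study.tm_table, outdir / "tm_weights.tsv")
    truth = {
        "seed": study.spec.seed,
        "organisms": list(study.spec.organism_ids),
        "planted_otg": [float(x) for x in study.spec.planted_otg],
        "planted_gr": [float(x) for x in study.spec.planted_gr],
        "gradients": [
            {"group": g.group, "metric": g.metric, "slope": g.slope, "axis": g.axis,
             "reference": g.reference}
            for g in study.spec.gradients
        ],
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    paths.update(
        annotations=str(outdir / "annotations.tsv"),
        growth=str(outdir / "growth.csv"),
        tm_table=str(outdir / "tm_weights.tsv"),
        truth=str(outdir / "truth.yaml"),
    )
    return paths


def default_recovery_spec(seed: int = 0, slope: float = -0.15,
                          affected: Sequence[str] = ("ENZY", "RIBO", "TNFA")) -> SyntheticStudySpec:
    """The standard parameter-recovery study: an inverse VMf-vs-OTG gradient
    planted in the designated groups, all other groups null."""
    return SyntheticStudySpec(
        seed=seed,
        gradients=tuple(PlantedGradient(g, "VMf", slope, "OTG") for g in affected),
    )
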