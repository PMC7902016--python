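"""Pairwise difference regression: the pipeline's core inference.

For each (CDS group, metric) cell, the mean differences of Tukey-significant
organism pairs (P2 - P1) are plotted against the corresponding differences
in optimal growth temperature (OTG2 - OTG1) or growth rate (Gr2 - Gr1), and
an ordinary least-squares line is fitted.  Fits need at least
``min_points`` points; results are reported only at R^2 >= ``r2_report``
and highlighted at R^2 >= ``r2_highlight``.  A positive slope is a *direct*
correlation, a negative one *inverse*.  Pairs are canonically oriented so
the member with the larger axis value is "2" (delta_axis > 0); equal-axis
pairs carry no slope information and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import InputError, StudyConfig
from .comparative_stats import SignificantPair
from .group_profiles import LabelMetricTable
from .growth_kinetics import GrowthParameters

logger = logging.getLogger("coldcomp")

AXES = ("OTG", "Gr")


@dataclass(frozen=True)
class StratumSpec:
    """An organism filter: an OTG interval or a side of the Gr cut."""

    id: str
    axis: str  # "OTG" | "Gr"
    interval: tuple[float, float] | None = None  # inclusive OTG interval
    gr_side: str | None = None  # "high" (> cut) or "low" (<= cut)
    gr_cut: float = 1.0

    def admits(self, params: GrowthParameters, use_display_otg: bool = True) -> bool:
        if self.axis == "OTG":
            v = params.otg_display if use_display_otg else params.otg
            lo, hi = self.interval
            return lo <= v <= hi
        v = params.max_gr
        return v > self.gr_cut if self.gr_side == "high" else v <= self.gr_cut


def default_strata(config: StudyConfig) -> list[StratumSpec]:
    """The study's organism subgroups: OTG intervals and the Gr cut sides."""
    strata = [
        StratumSpec(f"OTG{lo:g}-{hi:g}", "OTG", interval=(lo, hi))
        for lo, hi in config.otg_strata
    ]
    strata += [
        StratumSpec(f"Gr>{config.gr_stratum_cut:g}", "Gr", gr_side="high", gr_cut=config.gr_stratum_cut),
        StratumSpec(f"Gr<={config.gr_stratum_cut:g}", "Gr", gr_side="low", gr_cut=config.gr_stratum_cut),
    ]
    return strata


@dataclass(frozen=True)
class DifferencePoint:
    """One oriented pair: (delta_axis, delta_metric)."""

    delta_axis: float
    delta_metric: float
    organism_1: str
    organism_2: str


@dataclass(frozen=True)
class RegressionResult:
    group_code: str
    metric: str
    axis: str
    stratum: str  # "" for unstratified
    n_points: int
    slope: float
    slope_se: float
    intercept: float
    r2: float

    @property
    def direction(self) -> str:
        return "direct" if self.slope > 0 else "inverse"

    def reported(self, config: StudyConfig) -> bool:
        return self.r2 >= config.r2_report

    def highlighted(self, config: StudyConfig) -> bool:
        return self.r2 >= config.r2_highlight


@dataclass(frozen=True)
class RegressionRejection:
    group_code: str
    metric: str
    axis: str
    stratum: str
    n_points: int
    reason: str  # "too_few_points" | "zero_axis_variance"


def _axis_value(params: GrowthParameters, axis: str, use_display_otg: bool) -> float:
    if axis == "OTG":
        return float(params.otg_display if use_display_otg else params.otg)
    if axis == "Gr":
        return float(params.max_gr)
    raise InputError(f"unknown axis {axis!r}")


def build_difference_points(
    pairs: Sequence[SignificantPair],
    growth_params: Mapping[str, GrowthParameters],
    axis: str = "OTG",
    stratum: StratumSpec | None = None,
    use_display_otg: bool = True,
) -> tuple[list[DifferencePoint], int]:
    """Oriented (delta_axis, delta_metric) points from significant pairs.

    Returns (points, n_excluded_equal_axis).  When a stratum is given, both
    pair members must satisfy it.  Missing growth parameters raise.
    """
    points: list[DifferencePoint] = []
    n_equal = 0
    for p in pairs:
        for org in (p.organism_a, p.organism_b):
            if org not in growth_params:
                raise InputError(f"no growth parameters for organism {org!r}")
        ga, gb = growth_params[p.organism_a], growth_params[p.organism_b]
        if stratum is not None and not (
            stratum.admits(ga, use_display_otg) and stratum.admits(gb, use_display_otg)
        ):
            continue
        xa, xb = _axis_value(ga, axis, use_display_otg), _axis_value(gb, axis, use_display_otg)
        if xa == xb:
            n_equal += 1
            continue
        if xb > xa:
            points.append(
                DifferencePoint(xb - xa, p.mean_b - p.mean_a, p.organism_a, p.organism_b)
            )
        else:
            points.append(
                DifferencePoint(xa - xb, p.mean_a - p.mean_b, p.organism_b, p.organism_a)
            )
    return points, n_equal


def fit_difference_regression(
    points: Sequence[DifferencePoint],
    config: StudyConfig | None = None,
    *,
    group_code: str = "",
    metric: str = "",
    axis: str = "",
    stratum: str = "",
) -> RegressionResult | RegressionRejection:
    """OLS with intercept on the difference points.

    Rejects (does not fit) below ``min_points`` points or with zero
    variance in delta_axis.
    """
    config = config or StudyConfig()
    if len(points) < config.min_points:
        return RegressionRejection(
            group_code, metric, axis, stratum, len(points), "too_few_points"
        )
    x = np.array([p.delta_axis for p in points])
    y = np.array([p.delta_metric for p in points])
    if np.ptp(x) == 0:
        return RegressionRejection(
            group_code, metric, axis, stratum, len(points), "zero_axis_variance"
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        group_code,
        metric,
        axis,
        stratum,
        len(points),
        float(fit.slope),
        float(fit.stderr),
        float(fit.intercept),
        float(fit.rvalue**2),
    )


@dataclass
class MatrixResult:
    """All fits over (group, metric, axis, stratum) cells plus tallies."""

    results: list[RegressionResult]
    rejections: list[RegressionRejection]
    config: StudyConfig

    def reported(self) -> list[RegressionResult]:
        return [r for r in self.results if r.reported(self.config)]

    def highlighted(self) -> list[RegressionResult]:
        return [r for r in self.results if r.highlighted(self.config)]

    def tally(self, r2_min: float) -> dict[tuple[str, str, str], int]:
        """(axis, stratum, direction) -> count of results with R^2 >= r2_min."""
        out: dict[tuple[str, str, str], int] = {}
        for r in self.results:
            if r.r2 >= r2_min:
                key = (r.axis, r.stratum, r.direction)
                out[key] = out.get(key, 0) + 1
        return out


def run_matrix(
    pairs: Sequence[SignificantPair],
    growth_params: Mapping[str, GrowthParameters],
    config: StudyConfig | None = None,
    axes: Sequence[str] = AXES,
    strata: Sequence[StratumSpec] | None = None,
    include_unstratified: bool = True,
) -> MatrixResult:
    """Fit the full regression matrix over every (group, metric, axis, stratum).

    Every fit attempt is recorded: results carry slope/R^2, rejections the
    reason (too few points / no axis spread).  Reported and highlighted
    subsets follow the configured R^2 thresholds.
    """
    config = config or StudyConfig()
    cells: dict[tuple[str, str], list[SignificantPair]] = {}
    for p in pairs:
        cells.setdefault((p.group_code, p.metric), []).append(p)
    strata_list: list[StratumSpec | None] = [None] if include_unstratified else []
    if strata is not None:
        strata_list += list(strata)
    results, rejections = [], []
    for (group, metric), cell_pairs in sorted(cells.items()):
        for axis in axes:
            for st in strata_list:
                st_id = st.id if st is not None else ""
                pts, _ = build_difference_points(
                    cell_pairs, growth_params, axis, st, config.use_display_otg
                )
                out = fit_difference_regression(
                    pts, config, group_code=group, metric=metric, axis=axis, stratum=st_id
                )
                (results if isinstance(out, RegressionResult) else rejections).append(out)
    return MatrixResult(results, rejections, config)


# ---------------------------------------------------------------------------
# label-level variant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelSlope:
    label: str
    metric: str
    n: int
    slope: float
    intercept: float
    r2: float

    @property
    def direction(self) -> str:
        return "direct" if self.slope > 0 else "inverse"


def label_level_regression(
    label_tables: Sequence[LabelMetricTable],
    axis_values: Mapping[str, float],
    config: StudyConfig | None = None,
) -> list[LabelSlope]:
    """Per-label OLS of metric value vs axis value across organisms.

    Labels with fewer than ``min_points`` organisms having both a value and
    an axis value are skipped.
    """
    config = config or StudyConfig()
    out: list[LabelSlope] = []
    for tbl in label_tables:
        orgs = [o for o in tbl.values if o in axis_values]
        if len(orgs) < config.min_points:
            continue
        x = np.array([axis_values[o] for o in orgs])
        y = np.array([tbl.values[o] for o in orgs])
        if np.ptp(x) == 0:
            continue
        fit = stats.linregress(x, y)
        out.append(
            LabelSlope(
                tbl.label, tbl.metric, len(orgs), float(fit.slope), float(fit.intercept),
                float(fit.rvalue**2),
            )
        )
    return out


def label_slope_summary(slopes: Sequence[LabelSlope], r2_min: float = 0.7):
    """Per-metric summary of label slopes with R^2 >= r2_min.

    Mirrors the style of slope-range reporting: count, mean slope, modal
    sign, and the (min, max) slope range.
    """
    import pandas as pd

    rows = []
    by_metric: dict[str, list[LabelSlope]] = {}
    for s in slopes:
        if s.r2 >= r2_min:
            by_metric.setdefault(s.metric, []).append(s)
    for metric, group in sorted(by_metric.items()):
        vals = np.array([s.slope for s in group])
        n_direct = int((vals > 0).sum())
        n_inverse = int((vals < 0).sum())
        rows.append(
            {
                "metric": metric,
                "n_labels": len(group),
                "mean_slope": float(vals.mean()),
                "mode_sign": "direct" if n_direct >= n_inverse else "inverse",
                "n_direct": n_direct,
                "n_inverse": n_inverse,
                "slope_min": float(vals.min()),
                "slope_max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


_MATRIX_COLS = [
    "group_code", "metric", "axis", "stratum", "n_points", "slope", "slope_se",
    "intercept", "r2", "direction", "reported", "highlighted",
]


def matrix_frame(matrix: MatrixResult):
    """TSV-ready results table including reported/highlighted flags."""
    import pandas as pd

    rows = []
    for r in matrix.results:
        rows.append(
            {
                "group_code": r.group_code,
                "metric": r.metric,
                "axis": r.axis,
                "stratum": r.stratum,
                "n_points": r.n_points,
                "slope": r.slope,
                "slope_se": r.slope_se,
                "intercept": r.intercept,
                "r2": r.r2,
                "direction": r.direction,
                "reported": r.reported(matrix.config),
                "highlighted": r.highlighted(matrix.config),
            }
        )
    return pd.DataFrame(rows, columns=_MATRIX_COLS)
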