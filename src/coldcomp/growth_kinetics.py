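"""Growth-curve kinetics: exponential-phase rate, optimal temperature, range.

The growth rate Gr (h^-1) is the slope of ln(OD600) vs time over the best
log-linear window of the curve.  The optimal temperature for growth (OTG) is
the temperature with the highest mean Gr; temperatures statistically
indistinguishable from the top one are averaged (so equal maxima at 15 and
22 degC report an OTG of 18.5, displayed as 19).  The growth temperature
range collects every temperature whose mean Gr reaches at least 40% of the
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import GrowthCurve, InputError, StudyConfig, round_half_up

logger = logging.getLogger("coldcomp")


@dataclass(frozen=True)
class GrowthRateFit:
    """Result of the exponential-phase search on one curve."""

    gr: float  # h^-1
    window: tuple[int, int] | None  # [start, stop) indices into the positive-OD points
    r2: float
    flag: str  # "ok" | "low_quality" | "no_growth"


@dataclass(frozen=True)
class GrowthParameters:
    """Per-organism growth summary."""

    organism_id: str
    gr_by_temp: Mapping[float, tuple[float, float, int]]  # T -> (mean, sd, n)
    otg: float
    otg_display: int
    max_gr: float
    temp_range: tuple[float, float]
    range_set: tuple[float, ...]

    @property
    def gr_at_otg(self) -> float:
        return self.max_gr


def _scan_windows(t: np.ndarray, y: np.ndarray, min_window: int, r2_gate: float):
    """Best-slope window search via prefix sums, vectorized over starts.

    Returns ((slope, r2, (i, j)) best among R^2-gated windows or None,
    same for the unconditional best).
    """
    n = t.size
    c1 = lambda v: np.concatenate(([0.0], np.cumsum(v)))
    St, Sy, Stt, Sty, Syy = c1(t), c1(y), c1(t * t), c1(t * y), c1(y * y)
    best_gated = best_any = None
    for L in range(min_window, n + 1):
        i = np.arange(n - L + 1)
        j = i + L
        st = St[j] - St[i]
        sy = Sy[j] - Sy[i]
        stt = Stt[j] - Stt[i] - st * st / L
        sty = Sty[j] - Sty[i] - st * sy / L
        syy = Syy[j] - Syy[i] - sy * sy / L
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(stt > 0, sty / stt, 0.0)
            r2 = np.where(syy > 0, np.where(stt > 0, sty * sty / (stt * syy), 0.0), 1.0)
        k = int(np.argmax(slope))
        if best_any is None or slope[k] > best_any[0]:
            best_any = (float(slope[k]), float(r2[k]), (int(i[k]), int(j[k])))
        ok = r2 >= r2_gate
        if ok.any():
            sg = np.where(ok, slope, -np.inf)
            k = int(np.argmax(sg))
            if best_gated is None or sg[k] > best_gated[0]:
                best_gated = (float(slope[k]), float(r2[k]), (int(i[k]), int(j[k])))
    return best_gated, best_any


def fit_growth_rate(
    curve: GrowthCurve,
    min_window: int = 4,
    r2_gate: float = 0.98,
    od_floor: float = 0.0,
    saturation_correction: bool = False,
) -> GrowthRateFit:
    """Estimate Gr as the maximal ln(OD) slope over qualifying windows.

    All contiguous windows of at least ``min_window`` points with
    OD > max(0, ``od_floor``) are scanned; among windows whose internal
    linear fit has R^2 >= ``r2_gate`` the largest slope wins.  If no window
    passes the gate, the largest slope over all windows is returned flagged
    ``low_quality``.  A best slope <= 0 reports Gr = 0 flagged
    ``no_growth``.  ``od_floor`` models the instrument detection floor;
    sub-floor readings are treated as unmeasured.

    With ``saturation_correction`` the window slope is divided by
    ``1 - mean(od_window)/K_hat`` (``K_hat`` = the curve's observed
    plateau), undoing the downward bias a log-linear window acquires on
    logistic curves as it touches saturation.  Use only for curves that
    actually approach a plateau; on unsaturated exponential data the
    correction overshoots.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    keep = od > max(0.0, od_floor) if od_floor > 0 else od > 0
    if keep.sum() < min_window:
        if od_floor > 0 and (od > 0).sum() >= min_window:
            # culture never rose above the detection floor
            return GrowthRateFit(0.0, None, 0.0, "no_growth")
        raise InputError(
            f"{curve.organism_id}@{curve.temperature}: "
            f"fewer than {min_window} usable OD points"
        )
    od_kept = od[keep]
    best_gated, best_any = _scan_windows(t[keep], np.log(od_kept), min_window, r2_gate)
    chosen, flag = (best_gated, "ok") if best_gated is not None else (best_any, "low_quality")
    slope, r2, window = chosen
    if slope <= 0:
        return GrowthRateFit(0.0, window, r2, "no_growth")
    if saturation_correction:
        k_hat = float(od_kept.max())
        od_win = float(od_kept[window[0] : window[1]].mean())
        slope /= 1.0 - min(od_win / k_hat, 0.5)
    return GrowthRateFit(float(slope), window, float(r2), flag)


def determine_otg(
    gr_replicates: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
    tie_method: str = "tukey",
    pool_fraction: float = 0.4,
) -> tuple[float, int]:
    """OTG from replicate growth rates per temperature.

    The candidate set is the argmax temperature plus every temperature whose
    replicate rates are statistically indistinguishable from it at level
    ``alpha``.  OTG is the mean of the candidates; ``otg_display`` rounds it
    half-up to the nearest degree (equal maxima at 15 and 22 degC report
    18.5, displayed as 19).

    ``tie_method="tukey"`` (default) judges ties with a Tukey-Kramer
    studentized-range test whose variance is pooled only over temperatures
    inside the organism's growth regime — mean Gr at least
    ``pool_fraction`` (default 0.4, the growth-range rule) of the top mean,
    with non-degenerate replicate variance.  Replicate Gr variance is
    strongly heteroscedastic across temperature regimes (no-growth and
    far-sub-optimal temperatures are estimated with categorically higher
    precision), and pooling across regimes understates the top pair's
    error, breaking genuine ties far more often than the nominal rate.
    Temperatures outside the pooled regime cannot tie except on exact
    equality — they are by construction far from the maximum.  ``"welch"``
    uses unadjusted two-sided Welch tests against the argmax.
    """
    if tie_method not in ("tukey", "welch"):
        raise InputError(f"unknown tie_method {tie_method!r}")
    temps = sorted(gr_replicates)
    if not temps:
        raise InputError("no temperatures measured")
    means = {T: float(np.mean(gr_replicates[T])) for T in temps}
    top = max(temps, key=lambda T: means[T])
    if means[top] <= 0:
        raise InputError("no growth at any temperature")
    if len(temps) == 1:
        logger.warning("single temperature measured; OTG = %s by default", top)
        return float(top), round_half_up(float(top))

    arrays = {T: np.asarray(gr_replicates[T], dtype=float) for T in temps}
    top_vals = arrays[top]
    scale = max(abs(means[top]), 1e-12)
    tiny = (1e-9 * scale) ** 2
    # pool variance over the growth regime only: non-degenerate groups whose
    # mean is within pool_fraction of the top
    usable = [
        T
        for T in temps
        if arrays[T].size >= 2
        and arrays[T].var(ddof=1) > tiny
        and means[T] >= pool_fraction * means[top]
    ]
    df = sum(arrays[T].size - 1 for T in usable)
    pooled = (
        sum(((arrays[T] - means[T]) ** 2).sum() for T in usable) / df if df > 0 else 0.0
    )
    k = len(usable)
    can_test = k >= 2 and top in usable

    candidates = [top]
    for T in temps:
        if T == top:
            continue
        vals = arrays[T]
        if not can_test or T not in usable:
            # no usable within-pair variance: tie only on (numerically) equal means
            tied = abs(means[T] - means[top]) <= 1e-9 * scale
        elif tie_method == "welch":
            p = stats.ttest_ind(vals, top_vals, equal_var=False).pvalue
            tied = bool(p >= alpha)
        else:
            se = np.sqrt(pooled / 2 * (1 / vals.size + 1 / top_vals.size))
            q = abs(means[T] - means[top]) / se
            p = stats.studentized_range.sf(q, k, df)
            tied = bool(p >= alpha)
        if tied:
            candidates.append(T)
    otg = float(np.mean(candidates))
    return otg, round_half_up(otg)


def growth_range(
    gr_by_temp: Mapping[float, float], fraction: float = 0.4
) -> tuple[tuple[float, float], tuple[float, ...]]:
    """Temperatures whose mean Gr is at least ``fraction`` of the maximum.

    Returns ``((min, max), members)``; a warning is logged when the member
    set is not contiguous over the measured grid.
    """
    if not gr_by_temp:
        raise InputError("empty Gr map")
    max_gr = max(gr_by_temp.values())
    members = tuple(sorted(T for T, g in gr_by_temp.items() if g >= fraction * max_gr))
    span = (members[0], members[-1])
    measured = sorted(gr_by_temp)
    inside = [T for T in measured if span[0] <= T <= span[1]]
    if len(inside) != len(members):
        logger.warning("growth range is non-contiguous: %s", members)
    return span, members


def estimate_growth_parameters(
    curves: Iterable[GrowthCurve], config: StudyConfig | None = None
) -> GrowthParameters:
    """Full per-organism summary from replicate curves at several temperatures."""
    config = config or StudyConfig()
    curves = list(curves)
    if not curves:
        raise InputError("no curves")
    organisms = {c.organism_id for c in curves}
    if len(organisms) != 1:
        raise InputError(f"curves from multiple organisms: {sorted(organisms)}")
    (org,) = organisms
    reps: dict[float, list[float]] = {}
    for c in curves:
        fit = fit_growth_rate(
            c,
            config.min_window,
            config.fit_r2_gate,
            config.od_floor,
            config.saturation_correction,
        )
        reps.setdefault(c.temperature, []).append(fit.gr)
    gr_by_temp = {
        T: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, len(v))
        for T, v in reps.items()
    }
    otg, otg_display = determine_otg(
        reps, config.alpha, config.tie_method, config.range_fraction
    )
    means = {T: m for T, (m, _, _) in gr_by_temp.items()}
    max_gr = max(means.values())
    span, members = growth_range(means, config.range_fraction)
    return GrowthParameters(org, gr_by_temp, otg, otg_display, max_gr, span, members)


def growth_parameters_frame(params: Iterable[GrowthParameters]):
    """TSV-ready summary table (one row per organism-temperature plus summary columns)."""
    import pandas as pd

    rows = []
    for p in sorted(params, key=lambda q: q.organism_id):
        for T in sorted(p.gr_by_temp):
            m, sd, n = p.gr_by_temp[T]
            rows.append(
                {
                    "organism_id": p.organism_id,
                    "temperature": T,
                    "gr_mean": m,
                    "gr_sd": sd,
                    "n_replicates": n,
                    "otg": p.otg,
                    "otg_display": p.otg_display,
                    "max_gr": p.max_gr,
                    "range_min": p.temp_range[0],
                    "range_max": p.temp_range[1],
                }
            )
    return pd.DataFrame(rows)
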