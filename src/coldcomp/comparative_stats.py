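"""The ANOVA-Tukey screen over organism pairs.

For every (CDS group, metric) cell, per-protein values are compared across
organisms with a one-way fixed-effects ANOVA and all-pairs Tukey HSD
(Tukey-Kramer for unequal group sizes, via the studentized-range
distribution).  Pairs whose adjusted p falls below alpha are the
"significant pairs" that feed the difference-regression stage.  By default
the Tukey screen is not gated on the omnibus ANOVA p (Tukey controls the
family-wise error rate on its own); ``require_omnibus`` restores gating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import studentized_range

from .io_model import InputError, StudyConfig
from .group_profiles import GroupMetricSample, samples_by_cell

logger = logging.getLogger("coldcomp")


@dataclass(frozen=True)
class SignificantPair:
    """A Tukey-significant organism pair for one group and metric."""

    group_code: str
    metric: str
    organism_a: str
    organism_b: str
    mean_a: float
    mean_b: float
    p_adj: float
    n_a: int
    n_b: int

    @property
    def mean_diff(self) -> float:
        return self.mean_b - self.mean_a


def anova_tukey(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    *,
    group_code: str = "ALL",
    metric: str = "",
    require_omnibus: bool = False,
) -> tuple[float | None, list[SignificantPair]]:
    """One-way ANOVA + all-pairs Tukey HSD across organisms.

    ``samples`` maps organism id -> per-protein values.  Organisms with
    fewer than 2 values are skipped (their variance is undefined).  Returns
    (omnibus p, significant pairs sorted by organism ids).
    """
    eligible = {
        org: np.asarray(v, dtype=float) for org, v in sorted(samples.items()) if len(v) >= 2
    }
    if len(eligible) < 2:
        logger.warning("fewer than 2 eligible organisms for %s/%s", group_code, metric)
        return None, []
    orgs = list(eligible)
    arrays = [eligible[o] for o in orgs]
    pooled_var = sum(((a - a.mean()) ** 2).sum() for a in arrays) / sum(
        a.size - 1 for a in arrays
    )
    means = [a.mean() for a in arrays]
    if pooled_var == 0:
        if np.ptp(means) == 0:
            return 1.0, []
        raise InputError(
            f"{group_code}/{metric}: zero within-organism variance with unequal means"
        )
    omnibus_p = float(stats.f_oneway(*arrays).pvalue)
    if require_omnibus and omnibus_p >= alpha:
        return omnibus_p, []
    k = len(orgs)
    df = sum(a.size for a in arrays) - k
    q_crit = _studentized_range_crit(alpha, k, df)
    out: list[SignificantPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            # Tukey-Kramer studentized-range statistic for unequal n
            se = np.sqrt(pooled_var / 2 * (1 / arrays[i].size + 1 / arrays[j].size))
            q = abs(means[j] - means[i]) / se
            if q > q_crit:
                p = float(studentized_range.sf(q, k, df))
                out.append(
                    SignificantPair(
                        group_code,
                        metric,
                        orgs[i],
                        orgs[j],
                        float(means[i]),
                        float(means[j]),
                        p,
                        arrays[i].size,
                        arrays[j].size,
                    )
                )
    return omnibus_p, out


@lru_cache(maxsize=256)
def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    return float(studentized_range.ppf(1 - alpha, k, df))


def tukey_adjusted_p(
    samples: Mapping[str, Sequence[float]], org_a: str, org_b: str
) -> float:
    """Tukey-Kramer adjusted p for one pair (regardless of significance)."""
    arrays = {o: np.asarray(v, dtype=float) for o, v in samples.items() if len(v) >= 2}
    k = len(arrays)
    df = sum(a.size for a in arrays.values()) - k
    pooled = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df
    a, b = arrays[org_a], arrays[org_b]
    se = np.sqrt(pooled / 2 * (1 / a.size + 1 / b.size))
    q = abs(b.mean() - a.mean()) / se
    return float(studentized_range.sf(q, k, df))


def screen_significant_pairs(
    samples: Iterable[GroupMetricSample], config: StudyConfig | None = None
) -> list[SignificantPair]:
    """Run the Tukey screen over every (group, metric) cell."""
    config = config or StudyConfig()
    pairs: list[SignificantPair] = []
    for (group, metric), by_org in sorted(samples_by_cell(samples).items()):
        _, sig = anova_tukey(
            {org: s.values for org, s in by_org.items()},
            config.alpha,
            group_code=group,
            metric=metric,
            require_omnibus=config.require_omnibus,
        )
        pairs.extend(sig)
    return pairs


_PAIR_COLS = [
    "group_code", "metric", "organism_a", "organism_b", "mean_a", "mean_b",
    "mean_diff", "p_adj", "n_a", "n_b",
]


def pairs_frame(pairs: Iterable[SignificantPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_code": p.group_code,
                "metric": p.metric,
                "organism_a": p.organism_a,
                "organism_b": p.organism_b,
                "mean_a": p.mean_a,
                "mean_b": p.mean_b,
                "mean_diff": p.mean_diff,
                "p_adj": p.p_adj,
                "n_a": p.n_a,
                "n_b": p.n_b,
            }
            for p in pairs
        ],
        columns=_PAIR_COLS,
    )
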