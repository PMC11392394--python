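"""Survival, allocation, lives-saved and life-years-saved metrics.

Replicate-level summaries use a normal interval (mean +/- 1.96 SE over
replicates), reflecting Monte Carlo error. Age-standardised rates use direct
standardisation against a fixed standard age distribution, with confidence
intervals from the modified-gamma method (the gamma interval for directly
standardised rates with the maximum-weight term replaced by the average
weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .cohort import AGE_BANDS
from .simulator import AllocationResult

__all__ = [
    "RateSummary",
    "survival_rate",
    "allocation_rate",
    "lives_saved",
    "life_years_saved",
    "age_adjusted_rate",
    "replicate_age_adjusted_survival",
    "baseline_survival",
    "baseline_life_years",
    "age_strata_masks",
    "build_report",
]

Z95 = 1.959963984540054


@dataclass
class RateSummary:
    """Mean over replicates with a 95% normal CI; NaN marks empty subgroups."""

    mean: float
    ci_low: float
    ci_high: float
    per_replicate: np.ndarray
    n: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.mean)

    def scaled(self, factor: float) -> "RateSummary":
        return RateSummary(
            self.mean * factor,
            self.ci_low * factor,
            self.ci_high * factor,
            self.per_replicate * factor,
            self.n,
        )


def _summarise(per_replicate: np.ndarray, n: int) -> RateSummary:
    mean = float(np.mean(per_replicate))
    if per_replicate.size > 1:
        se = float(np.std(per_replicate, ddof=1)) / np.sqrt(per_replicate.size)
    else:
        se = 0.0
    return RateSummary(mean, mean - Z95 * se, mean + Z95 * se, per_replicate, n)


def _undefined(replicates: int) -> RateSummary:
    nan = np.full(replicates, np.nan)
    return RateSummary(np.nan, np.nan, np.nan, nan, 0)


def _subgroup_mask(result: AllocationResult, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(result.n_encounters, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (result.n_encounters,):
        raise ValueError("subgroup mask must align with the cohort")
    return mask


def survival_rate(result: AllocationResult, mask: np.ndarray | None = None) -> RateSummary:
    """Simulated survival rate (unallocated encounters count as deaths)."""
    mask = _subgroup_mask(result, mask)
    n = int(mask.sum())
    if n == 0:
        return _undefined(result.replicates)
    rates = result.realized_survival[:, mask].sum(axis=1) / n
    return _summarise(rates, n)


def allocation_rate(result: AllocationResult, mask: np.ndarray | None = None) -> RateSummary:
    """Fraction of the subgroup allocated a bed."""
    mask = _subgroup_mask(result, mask)
    n = int(mask.sum())
    if n == 0:
        return _undefined(result.replicates)
    rates = result.allocation[:, mask].sum(axis=1) / n
    return _summarise(rates, n)


def baseline_survival(result: AllocationResult, mask: np.ndarray | None = None) -> float:
    """Scarcity-free survival rate of the subgroup."""
    mask = _subgroup_mask(result, mask)
    if mask.sum() == 0:
        return float("nan")
    return float(result.survived[mask].mean())


def baseline_life_years(result: AllocationResult, mask: np.ndarray | None = None) -> float:
    """Scarcity-free expected post-discharge life-years per patient."""
    if result.life_expectancy is None:
        raise ValueError("cohort not annotated with life expectancy")
    mask = _subgroup_mask(result, mask)
    if mask.sum() == 0:
        return float("nan")
    years = result.life_expectancy * result.survived
    return float(years[mask].mean())


def lives_saved(
    result: AllocationResult,
    baseline_rate: float | None = None,
    mask: np.ndarray | None = None,
) -> RateSummary:
    """Per-patient lives saved: simulated survival minus baseline x capacity."""
    mask = _subgroup_mask(result, mask)
    if baseline_rate is None:
        baseline_rate = baseline_survival(result, mask)
    surv = survival_rate(result, mask)
    if not surv.defined:
        return surv
    ls = surv.per_replicate - baseline_rate * result.capacity
    return _summarise(ls, surv.n)


def life_years_saved(
    result: AllocationResult,
    baseline_ly: float | None = None,
    mask: np.ndarray | None = None,
) -> RateSummary:
    """Per-patient life-years saved relative to the capacity-scaled baseline."""
    if result.life_expectancy is None:
        missing = "all"
        raise ValueError(
            f"life expectancy missing for encounters ({missing}); annotate the cohort first"
        )
    mask = _subgroup_mask(result, mask)
    n = int(mask.sum())
    if n == 0:
        return _undefined(result.replicates)
    if baseline_ly is None:
        baseline_ly = baseline_life_years(result, mask)
    ly_sim = result.realized_life_years[:, mask].sum(axis=1) / n
    lys = ly_sim - baseline_ly * result.capacity
    return _summarise(lys, n)


def age_adjusted_rate(
    events: Sequence[float],
    denominators: Sequence[float],
    weights: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Directly standardised rate with a modified-gamma confidence interval.

    ``events[i] / denominators[i]`` is the stratum rate, combined with the
    standard weights (renormalised to sum to one; zero-denominator strata are
    dropped with a warning). The gamma interval treats stratum events as
    Poisson; the upper bound uses the average stratum weight in place of the
    maximum.
    """
    x = np.asarray(events, dtype=float)
    n = np.asarray(denominators, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (x.shape == n.shape == w.shape):
        raise ValueError("events, denominators and weights must align")
    keep = n > 0
    if not keep.all():
        warnings.warn("dropping strata with zero denominators and renormalising weights")
        x, n, w = x[keep], n[keep], w[keep]
    if x.size == 0 or w.sum() <= 0:
        return float("nan"), float("nan"), float("nan")
    w = w / w.sum()

    wn = w / n
    y = float(np.sum(wn * x))
    v = float(np.sum(wn**2 * x))
    w_avg = float(np.mean(wn))  # modification: average weight, not maximum

    if y <= 0 or v <= 0:
        lower = 0.0
    else:
        lower = float(gamma_dist.ppf(alpha / 2, a=y**2 / v, scale=v / y))
    shape_u = (y + w_avg) ** 2 / (v + w_avg**2)
    scale_u = (v + w_avg**2) / (y + w_avg)
    upper = float(gamma_dist.ppf(1 - alpha / 2, a=shape_u, scale=scale_u))
    return y, lower, upper


def age_strata_masks(ages: np.ndarray) -> list[np.ndarray]:
    """Boolean masks for the reporting age bands."""
    ages = np.asarray(ages)
    masks = []
    for i, (lo, hi) in enumerate(AGE_BANDS):
        if i == len(AGE_BANDS) - 1:
            masks.append(ages >= lo)
        else:
            masks.append((ages >= lo) & (ages <= hi))
    return masks


def replicate_age_adjusted_survival(
    result: AllocationResult,
    mask: np.ndarray | None = None,
    standard_weights: np.ndarray | None = None,
) -> RateSummary:
    """Per-replicate age-standardised survival for a subgroup.

    The standard age distribution defaults to the full cohort's. Strata empty
    within the subgroup are dropped and the weights renormalised (denominators
    are fixed across replicates, so this is done once).
    """
    mask = _subgroup_mask(result, mask)
    ages = result.cohort["age"].to_numpy()
    strata = age_strata_masks(ages)
    if standard_weights is None:
        standard_weights = np.array([m.sum() for m in strata], dtype=float)
    standard_weights = np.asarray(standard_weights, dtype=float)
    if standard_weights.shape != (len(strata),):
        raise ValueError("standard_weights must have one entry per age band")

    sizes = np.array([(m & mask).sum() for m in strata], dtype=float)
    keep = sizes > 0
    if not keep.any():
        return _undefined(result.replicates)
    w = standard_weights[keep]
    w = w / w.sum()

    realized = result.realized_survival
    stratum_rates = np.stack(
        [realized[:, m & mask].sum(axis=1) / (m & mask).sum() for m, k in zip(strata, keep) if k],
        axis=1,
    )
    adjusted = stratum_rates @ w
    return _summarise(adjusted, int(mask.sum()))


_REPORT_RACES = ("black_nh", "hispanic", "white_nh")


def _race_masks(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    race = cohort["race_ethnicity"].to_numpy()
    masks: dict[str, np.ndarray] = {"overall": np.ones(len(cohort), dtype=bool)}
    for r in _REPORT_RACES:
        masks[r] = race == r
    return masks


def build_report(
    results: Mapping[str, Mapping[float, AllocationResult]],
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Tidy metric tables from a protocol -> capacity -> result mapping.

    Produces four tables: survival and allocation by race, lives saved per
    1000 by race, life-years saved per 1000 by race, and an overall
    capacity sweep. Written as CSVs when ``out_dir`` is given.
    """
    surv_rows, ls_rows, lys_rows, sweep_rows = [], [], [], []
    for protocol, by_capacity in results.items():
        for capacity, result in by_capacity.items():
            masks = _race_masks(result.cohort)
            has_ly = result.life_expectancy is not None
            overall_surv = survival_rate(result)
            for group, mask in masks.items():
                surv = survival_rate(result, mask)
                alloc = allocation_rate(result, mask)
                adj = replicate_age_adjusted_survival(result, mask)
                surv_rows.append(
                    {
                        "protocol": protocol,
                        "capacity": capacity,
                        "group": group,
                        "n": surv.n,
                        "survival_pct": surv.mean * 100,
                        "survival_ci_low": surv.ci_low * 100,
                        "survival_ci_high": surv.ci_high * 100,
                        "allocation_pct": alloc.mean * 100,
                        "allocation_ci_low": alloc.ci_low * 100,
                        "allocation_ci_high": alloc.ci_high * 100,
                        "age_adjusted_survival_pct": adj.mean * 100,
                        "age_adjusted_ci_low": adj.ci_low * 100,
                        "age_adjusted_ci_high": adj.ci_high * 100,
                    }
                )
                ls = lives_saved(result, mask=mask).scaled(1000)
                ls_rows.append(
                    {
                        "protocol": protocol,
                        "capacity": capacity,
                        "group": group,
                        "lives_saved_per_1000": ls.mean,
                        "ci_low": ls.ci_low,
                        "ci_high": ls.ci_high,
                    }
                )
                if has_ly:
                    lys = life_years_saved(result, mask=mask).scaled(1000)
                    lys_rows.append(
                        {
                            "protocol": protocol,
                            "capacity": capacity,
                            "group": group,
                            "life_years_saved_per_1000": lys.mean,
                            "ci_low": lys.ci_low,
                            "ci_high": lys.ci_high,
                        }
                    )
            ls_overall = lives_saved(result).scaled(1000)
            sweep_row = {
                "protocol": protocol,
                "capacity": capacity,
                "survival_pct": overall_surv.mean * 100,
                "lives_saved_per_1000": ls_overall.mean,
            }
            if has_ly:
                sweep_row["life_years_saved_per_1000"] = life_years_saved(result).scaled(1000).mean
            sweep_rows.append(sweep_row)

    tables = {
        "table2_survival_allocation": pd.DataFrame(surv_rows),
        "table3_lives_saved": pd.DataFrame(ls_rows),
        "table4_life_years_saved": pd.DataFrame(lys_rows),
        "capacity_sweep": pd.DataFrame(sweep_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
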