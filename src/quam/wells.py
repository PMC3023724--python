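"""Virtual culture wells: translating cell counts into assay sensitivity.

Per-cell intensities of primary neuron cultures are far from normal, so the
sensitivity of a culture-mean readout is estimated by resampling: "virtual
wells" of n cells are drawn from the pool of all measured cells, the mean of
each well is computed, and the SD of those well means quantifies how much a
culture mean of n cells wobbles by sampling alone. An intensity change
smaller than k x that SD (k = 2 by default) cannot be called; if only a
subgroup of fraction f responds, the required within-subgroup change is the
whole-culture bound divided by f.

The closed-form counterpart is ``pop_sd / sqrt(n)``, times the
finite-population correction ``sqrt((N - n) / (N - 1))`` when wells are drawn
without replacement from a pool of N cells. Sampling defaults to WITHOUT
replacement because the finite-population form is what a resampled pool of
measured cells actually obeys; both modes are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "VirtualWellSummary",
    "ConditionComparison",
    "sample_virtual_wells",
    "closed_form_sd",
    "detectable_effect",
    "sensitivity_table",
    "compare_conditions",
]

DEFAULT_N_WELLS = 10_000
DEFAULT_WELL_SIZES = (250, 1000, 5000, 10_000, 20_000)


@dataclass
class VirtualWellSummary:
    """Resampling result for one well size."""

    population_size: int
    cells_per_well: int
    n_wells: int
    replacement: bool
    well_means: np.ndarray
    mean_of_means: float
    sd_of_means: float
    expected_sd: float  # closed form from the population SD
    seed: int | None = None

    def detectable_effect(self, k: float = 2.0,
                          subgroup_fraction: float = 1.0) -> tuple[float, float]:
        return detectable_effect(self, k=k, subgroup_fraction=subgroup_fraction)


def closed_form_sd(pop_sd: float, n: int, N: int | None = None,
                   replacement: bool = True) -> float:
    """Expected SD of a mean of ``n`` cells from a pool of SD ``pop_sd``.

    ``pop_sd / sqrt(n)`` with replacement; multiplied by the
    finite-population correction ``sqrt((N - n) / (N - 1))`` without.
    """
    if pop_sd < 0:
        raise ConfigurationError(f"pop_sd must be >= 0, got {pop_sd}")
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    base = pop_sd / np.sqrt(n)
    if replacement:
        return float(base)
    if N is None:
        raise ConfigurationError("N is required for sampling without replacement")
    if n > N:
        raise ConfigurationError(f"n = {n} exceeds population size N = {N}")
    if N == 1:
        return 0.0
    return float(base * np.sqrt((N - n) / (N - 1)))


def sample_virtual_wells(intensities, n_per_well: int,
                         n_wells: int = DEFAULT_N_WELLS, *,
                         replacement: bool = False,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> VirtualWellSummary:
    """Draw ``n_wells`` virtual wells of ``n_per_well`` cells and summarize.

    Without replacement each well is a uniform random subset of the pool
    (drawn independently per well); with replacement cells may repeat within
    a well. Seed-reproducible; the empirical SD of well means is reported
    next to the closed-form expectation from the pool's own SD.
    """
    values = np.asarray(intensities, dtype=np.float64).ravel()
    N = values.size
    if N == 0:
        raise ConfigurationError("population is empty")
    if n_per_well < 1:
        raise ConfigurationError(f"n_per_well must be >= 1, got {n_per_well}")
    if n_wells < 1:
        raise ConfigurationError(f"n_wells must be >= 1, got {n_wells}")
    if not replacement and n_per_well > N:
        raise ConfigurationError(
            f"n_per_well = {n_per_well} exceeds population size {N} "
            "without replacement")
    if rng is None:
        rng = np.random.default_rng(seed)

    means = np.empty(n_wells)
    if not replacement and n_per_well == N:
        means[:] = values.mean()
    elif replacement:
        # chunked to bound the index matrix at ~2e7 entries
        chunk = max(1, int(2e7 // n_per_well))
        for s in range(0, n_wells, chunk):
            m = min(chunk, n_wells - s)
            idx = rng.integers(0, N, size=(m, n_per_well))
            means[s:s + m] = values[idx].mean(axis=1)
    else:
        # random-keys trick: the n smallest of N iid uniform keys index a
        # uniform n-subset; argpartition keeps it O(N) per well
        chunk = max(1, int(2e7 // N))
        for s in range(0, n_wells, chunk):
            m = min(chunk, n_wells - s)
            keys = rng.random((m, N))
            idx = np.argpartition(keys, n_per_well - 1, axis=1)[:, :n_per_well]
            means[s:s + m] = values[idx].mean(axis=1)

    pop_sd = float(np.std(values, ddof=1)) if N > 1 else 0.0
    return VirtualWellSummary(
        population_size=N, cells_per_well=int(n_per_well), n_wells=int(n_wells),
        replacement=replacement, well_means=means,
        mean_of_means=float(means.mean()),
        sd_of_means=float(np.std(means, ddof=1)) if n_wells > 1 else 0.0,
        expected_sd=closed_form_sd(pop_sd, n_per_well, N, replacement),
        seed=seed)


def detectable_effect(summary_or_sd, k: float = 2.0,
                      subgroup_fraction: float = 1.0, *,
                      mean: float | None = None) -> tuple[float, float]:
    """Minimal detectable intensity change, in % of the culture mean.

    The whole-culture bound is ``k x SD-of-well-means`` expressed as a
    percentage of the mean; a change confined to a subgroup of fraction f
    must be 1/f times larger within that subgroup to move the culture mean
    by the same amount. Returns ``(whole_culture_pct, within_subgroup_pct)``.

    Accepts a :class:`VirtualWellSummary` (using its mean of means) or a bare
    SD-of-means on an already mean-1 scale (``mean`` defaults to 1).
    """
    if not 0 < subgroup_fraction <= 1:
        raise ConfigurationError(
            f"subgroup_fraction must lie in (0, 1], got {subgroup_fraction}")
    if isinstance(summary_or_sd, VirtualWellSummary):
        sd = summary_or_sd.sd_of_means
        m = summary_or_sd.mean_of_means if mean is None else mean
    else:
        sd = float(summary_or_sd)
        m = 1.0 if mean is None else mean
    if m == 0:
        raise ConfigurationError("mean of means is zero; percent change undefined")
    whole = k * sd / abs(m) * 100.0
    return whole, whole / subgroup_fraction


def sensitivity_table(intensities, well_sizes=DEFAULT_WELL_SIZES, *,
                      n_wells: int = DEFAULT_N_WELLS, replacement: bool = False,
                      k: float = 2.0, seed: int | None = None) -> pd.DataFrame:
    """SD-of-mean vs cells-per-well table with detectable-effect bounds."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in well_sizes:
        s = sample_virtual_wells(intensities, n, n_wells,
                                 replacement=replacement, rng=rng)
        whole, _ = s.detectable_effect(k=k)
        rows.append({"cells_per_well": n, "n_wells": n_wells,
                     "mean_of_means": s.mean_of_means,
                     "sd_of_means": s.sd_of_means,
                     "sd_closed_form": s.expected_sd,
                     "detectable_effect_pct": whole})
    return pd.DataFrame(rows)


@dataclass
class ConditionComparison:
    """One-tailed unpaired t-test of treated vs control well/culture means."""

    t_stat: float
    p_value: float
    mean_control: float
    mean_treated: float
    mean_ratio: float
    direction: str
    degenerate: bool = False


def compare_conditions(control_means, treated_means,
                       direction: str = "greater") -> ConditionComparison:
    """Compare treated vs control sample means (one-tailed, unpaired).

    ``direction`` is the alternative for treated relative to control. If
    both groups have zero variance and equal means the comparison is
    degenerate: t = 0, p = 0.5 by convention, flagged.
    """
    a = np.asarray(treated_means, dtype=np.float64)
    b = np.asarray(control_means, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("need >= 2 means per group")
    if direction not in ("greater", "less"):
        raise ConfigurationError(f"direction must be 'greater' or 'less', got {direction!r}")
    mc, mt = float(b.mean()), float(a.mean())
    if np.std(a) == 0 and np.std(b) == 0 and mc == mt:
        return ConditionComparison(0.0, 0.5, mc, mt,
                                   mt / mc if mc else float("nan"),
                                   direction, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=direction)
    return ConditionComparison(float(t), float(p), mc, mt,
                               mt / mc if mc else float("nan"), direction)
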