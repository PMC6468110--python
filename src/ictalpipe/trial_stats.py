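"""Trial-level seizure-count statistics.

Implements the statistical toolkit of a two-arm preclinical seizure trial:

* inclusion filtering — animals with fewer than five seizures in the
  baseline week are excluded (a pre-registered criterion in the trials this
  models);
* per-animal baseline normalization of weekly counts, and normalized
  cumulative daily counts;
* seizure burden — total post-treatment count normalized to baseline,
  compared between groups with an exact Mann–Whitney U test;
* the Fano factor (variance/mean of per-period counts) as a clustering
  index: 1 for a Poisson process, above 1 under seizure clustering;
* the modified Lehr rule-of-thumb sample size for Poisson rates, its
  Monte-Carlo power check, and a permutation test for the
  treatment × week interaction on normalized frequencies.

Count tables are long-format DataFrames with columns
``animal_id, group, period_type, period_index, count, is_baseline`` (week
−1 = last baseline week, week 0 = first post-treatment week; days use day 0
= first post-treatment day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "PowerDesign",
    "apply_inclusion_filter",
    "normalize_frequency",
    "normalize_cumulative_daily",
    "seizure_burden",
    "fano_factor",
    "mann_whitney_exact",
    "lehr_sample_size",
    "power_simulation",
    "sqrt_z_test",
    "permutation_interaction_test",
    "tidy_model_frame",
]

_COLUMNS = ["animal_id", "group", "period_type", "period_index", "count", "is_baseline"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    dup = table.duplicated(subset=["animal_id", "period_type", "period_index"])
    if dup.any():
        raise ValueError("duplicate (animal, period) rows in count table")
    return table


def _baseline_reference(table: pd.DataFrame, animal: str, mode: str) -> float:
    weeks = table[
        (table.animal_id == animal) & (table.period_type == "week")
    ]
    base = weeks[weeks.is_baseline]
    if base.empty:
        raise ValueError(f"animal {animal} has no baseline week")
    if mode == "last_week":
        return float(base.loc[base.period_index.idxmax(), "count"])
    if mode == "mean_of_baseline":
        return float(base["count"].mean())
    raise ValueError(f"unknown baseline_mode {mode!r}")


def apply_inclusion_filter(
    table: pd.DataFrame, min_baseline: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude animals with fewer than ``min_baseline`` baseline-week seizures.

    The rule is strict ("fewer than five"): a count of exactly
    ``min_baseline`` is retained. Uses the last baseline week (week −1).
    Returns the filtered table and an exclusion report (animal, group,
    baseline count) for the removed animals.
    """
    _validate_table(table)
    rows = []
    for animal, sub in table.groupby("animal_id", sort=True):
        ref = _baseline_reference(table, animal, "last_week")
        rows.append((animal, sub["group"].iloc[0], ref, ref < min_baseline))
    report = pd.DataFrame(rows, columns=["animal_id", "group", "baseline_count", "excluded"])
    excluded = set(report.loc[report.excluded, "animal_id"])
    kept = table[~table.animal_id.isin(excluded)].reset_index(drop=True)
    return kept, report[report.excluded].drop(columns="excluded").reset_index(drop=True)


def normalize_frequency(
    table: pd.DataFrame, baseline_mode: str = "last_week"
) -> pd.DataFrame:
    """Normalize each animal's weekly counts to its baseline reference.

    ``baseline_mode='last_week'`` divides by the week −1 count (so week −1
    itself normalizes to exactly 1); ``'mean_of_baseline'`` divides by the
    mean over all baseline weeks. Returns rows
    ``animal_id, group, period_index, normalized`` for every week.
    """
    _validate_table(table)
    out = []
    weeks = table[table.period_type == "week"]
    for animal, sub in weeks.groupby("animal_id", sort=True):
        ref = _baseline_reference(table, animal, baseline_mode)
        if ref == 0:
            raise ValueError(
                f"animal {animal}: baseline reference is 0; apply the "
                "inclusion filter first"
            )
        for r in sub.itertuples():
            out.append((animal, r.group, r.period_index, r.count / ref))
    return pd.DataFrame(out, columns=["animal_id", "group", "period_index", "normalized"])


def normalize_cumulative_daily(table: pd.DataFrame) -> pd.DataFrame:
    """Cumulative post-treatment daily counts, normalized per animal.

    Each animal's running post-treatment total is divided by its total count
    in the baseline week (week −1), mirroring normalized cumulative
    seizure-frequency plots.
    """
    _validate_table(table)
    days = table[(table.period_type == "day") & (~table.is_baseline)]
    if days.empty:
        raise ValueError("count table has no post-treatment day rows")
    out = []
    for animal, sub in days.groupby("animal_id", sort=True):
        ref = _baseline_reference(table, animal, "last_week")
        if ref == 0:
            raise ValueError(f"animal {animal}: baseline reference is 0")
        sub = sub.sort_values("period_index")
        cum = sub["count"].cumsum() / ref
        for idx, val in zip(sub["period_index"], cum):
            out.append((animal, sub["group"].iloc[0], idx, float(val)))
    return pd.DataFrame(
        out, columns=["animal_id", "group", "period_index", "cumulative_normalized"]
    )


def seizure_burden(
    table: pd.DataFrame, baseline_mode: str = "last_week"
) -> tuple[pd.DataFrame, dict]:
    """Per-animal normalized post-treatment seizure burden + group comparison.

    Burden = (sum of post-treatment weekly counts) / baseline reference.
    Groups are compared with the exact two-sided Mann–Whitney U test.
    """
    _validate_table(table)
    weeks = table[(table.period_type == "week") & (~table.is_baseline)]
    if weeks.empty:
        raise ValueError("no post-treatment weeks in table")
    rows = []
    for animal, sub in weeks.groupby("animal_id", sort=True):
        ref = _baseline_reference(table, animal, baseline_mode)
        rows.append((animal, sub["group"].iloc[0], float(sub["count"].sum() / ref)))
    burden = pd.DataFrame(rows, columns=["animal_id", "group", "burden"])
    x = burden.loc[burden.group == "treated", "burden"].to_numpy()
    y = burden.loc[burden.group == "control", "burden"].to_numpy()
    if x.size and y.size:
        u, p = mann_whitney_exact(x, y)
    else:  # single-arm table: burden values only, no group comparison
        u = p = float("nan")
    return burden, {"U": u, "p_value": p, "n_treated": x.size, "n_control": y.size}


def fano_factor(counts: np.ndarray) -> float:
    """Fano factor = sample variance / mean of a series of counts.

    1 for Poisson counts, above 1 under clustering, 0 for constant counts.
    Variance uses the n−1 denominator. Typically applied to per-day
    post-treatment counts of one animal.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("Fano factor needs at least 2 periods")
    m = c.mean()
    if m == 0:
        raise ValueError("Fano factor undefined for all-zero counts")
    return float(c.var(ddof=1) / m)


def per_animal_fano(table: pd.DataFrame, period_type: str = "day") -> pd.DataFrame:
    """Post-treatment Fano factor per animal (daily bins by default).

    Animals whose post-treatment counts are all zero have an undefined Fano
    factor and are returned as NaN.
    """
    _validate_table(table)
    post = table[(table.period_type == period_type) & (~table.is_baseline)]
    rows = []
    for animal, sub in post.groupby("animal_id", sort=True):
        c = sub["count"].to_numpy()
        f = fano_factor(c) if c.sum() > 0 and c.size >= 2 else float("nan")
        rows.append((animal, sub["group"].iloc[0], f))
    return pd.DataFrame(rows, columns=["animal_id", "group", "fano"])


# ---------------------------------------------------------------------------
# Mann–Whitney U (exact enumeration for small samples)
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, with 0.5 credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_exact(
    x, y, alternative: str = "two-sided", exact_limit: int = 14
) -> tuple[float, float]:
    """Mann–Whitney U test with exact small-sample enumeration.

    For m + n ≤ ``exact_limit`` the p-value enumerates all C(m+n, n) group
    labelings of the pooled data (correct under ties as well); larger
    samples use the normal approximation with tie correction and continuity
    correction (scipy). Returns ``(U_x, p)`` with U computed for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    m, n = x.size, y.size

    if m + n <= exact_limit:
        pooled = np.concatenate([x, y])
        idx = range(m + n)
        mu = m * n / 2.0
        count = total = 0
        for chosen in combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if alternative == "two-sided":
                count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            elif alternative == "greater":
                count += u >= u_obs - 1e-12
            elif alternative == "less":
                count += u <= u_obs + 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return u_obs, count / total

    res = spstats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# Sample size and power for Poisson rates
# ---------------------------------------------------------------------------

@dataclass
class PowerDesign:
    """Rates and error levels for the Poisson sample-size calculation.

    λ1 and λ2 are the mean weekly seizure counts before and after treatment;
    defaults target 80% power at two-sided α = 0.05.
    """

    lambda1: float
    lambda2: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("rates must be positive")


def lehr_sample_size(design: PowerDesign) -> tuple[float, int]:
    """Per-group sample size from the modified Lehr formula for Poisson rates.

    The square-root transform stabilizes the Poisson variance at 1/4, so
    Lehr's 16/d² rule of thumb (80% power, two-sided α = 0.05) becomes

        n = 4 / (√λ1 − √λ2)²

    per group. Returns the real value and its ceiling. The classic worked
    case λ1 = 10 vs λ2 = 6 gives 7.87 → 8 animals per group.
    """
    l1, l2 = design.lambda1, design.lambda2
    if math.isclose(l1, l2):
        raise ValueError("λ1 = λ2 gives an infinite sample size")
    n = 4.0 / (math.sqrt(l1) - math.sqrt(l2)) ** 2
    return n, math.ceil(n)


def sqrt_z_test(x, y, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sample z-test on square-root transformed Poisson counts.

    √X has approximate variance 1/4 regardless of the rate, so
    ``z = (mean√x − mean√y) / √(1/(4m) + 1/(4n))`` is compared with the
    two-sided normal quantile. Returns ``(z, reject)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = (np.mean(np.sqrt(x)) - np.mean(np.sqrt(y))) / math.sqrt(
        0.25 / x.size + 0.25 / y.size
    )
    crit = spstats.norm.ppf(1 - alpha / 2)
    return float(z), bool(abs(z) > crit)


def power_simulation(
    design: PowerDesign, n_per_group: int, reps: int = 10_000, seed: int = 0
) -> dict:
    """Monte-Carlo power of the square-root-transform z-test.

    Draws ``reps`` trials of ``n_per_group`` Poisson(λ1) vs Poisson(λ2)
    weekly counts and reports the rejection fraction at two-sided α, with
    its binomial standard error.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.poisson(design.lambda1, size=(reps, n_per_group))
    y = rng.poisson(design.lambda2, size=(reps, n_per_group))
    se_diff = math.sqrt(0.5 / n_per_group)  # 1/(4n) + 1/(4n)
    z = (np.sqrt(x).mean(axis=1) - np.sqrt(y).mean(axis=1)) / se_diff
    crit = spstats.norm.ppf(1 - design.alpha / 2)
    rejections = np.abs(z) > crit
    power = float(rejections.mean())
    return {
        "power": power,
        "se": math.sqrt(power * (1 - power) / reps),
        "reps": reps,
        "n_per_group": n_per_group,
    }


def power_normal_approximation(design: PowerDesign, n_per_group: int) -> float:
    """Closed-form normal approximation to the sqrt-transform test's power."""
    delta = abs(math.sqrt(design.lambda1) - math.sqrt(design.lambda2))
    se = math.sqrt(0.5 / n_per_group)
    crit = spstats.norm.ppf(1 - design.alpha / 2)
    return float(
        spstats.norm.sf(crit - delta / se) + spstats.norm.cdf(-crit - delta / se)
    )


# ---------------------------------------------------------------------------
# Permutation interaction test
# ---------------------------------------------------------------------------

def _animal_slopes(normalized: pd.DataFrame, eps: float) -> pd.DataFrame:
    # All weeks enter the regression, including the baseline anchor (week -1
    # normalizes to 1): a treatment effect is a *change from baseline*, and
    # without the anchor a constant post-treatment rate ratio would alter the
    # level but not the slope.
    rows = []
    for animal, sub in normalized.groupby("animal_id", sort=True):
        if sub.shape[0] < 2:
            continue
        wk = sub["period_index"].to_numpy(dtype=float)
        yv = np.log(sub["normalized"].to_numpy() + eps)
        slope = np.polyfit(wk, yv, 1)[0]
        rows.append((animal, sub["group"].iloc[0], slope))
    return pd.DataFrame(rows, columns=["animal_id", "group", "slope"])


def permutation_interaction_test(
    normalized: pd.DataFrame, reps: int = 2000, seed: int = 0, eps: float = 0.5
) -> dict:
    """Permutation test for a treatment × week interaction.

    The statistic is the between-group difference in the mean animal-level
    slope of log(normalized frequency + ε) over post-treatment weeks — a
    design-free stand-in for the interaction term of a log-linear mixed
    model. The null distribution permutes group labels across animals;
    ``p = (1 + #as-extreme) / (1 + reps)``.
    """
    slopes = _animal_slopes(normalized, eps)
    if slopes.shape[0] == 0:
        raise ValueError("need at least 2 post-treatment weeks per animal")
    groups = slopes["group"].to_numpy()
    vals = slopes["slope"].to_numpy()
    if len(set(groups)) < 2:
        raise ValueError("both groups must be present")

    def stat(g):
        return vals[g == "treated"].mean() - vals[g == "control"].mean()

    observed = stat(groups)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(reps):
        perm = rng.permutation(groups)
        if abs(stat(perm)) >= abs(observed) - 1e-15:
            extreme += 1
    return {
        "statistic": float(observed),
        "p_value": (1 + extreme) / (1 + reps),
        "reps": reps,
        "n_animals": int(vals.size),
    }


def tidy_model_frame(table: pd.DataFrame, baseline_mode: str = "last_week") -> pd.DataFrame:
    """Long-format frame ready for an external mixed-model fit.

    One row per animal × post-treatment week with the raw count, normalized
    frequency, group and week — the shape a generalized log-linear mixed
    model with a random animal effect expects.
    """
    norm = normalize_frequency(table, baseline_mode)
    weeks = table[(table.period_type == "week")][
        ["animal_id", "period_index", "count"]
    ]
    out = norm.merge(weeks, on=["animal_id", "period_index"])
    out = out[out.period_index >= 0].reset_index(drop=True)
    return out.rename(columns={"period_index": "week"})
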