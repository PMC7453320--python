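"""Feasibility-trial design and endpoint statistics.

Two pieces: (i) power and sample size for a one-sided two-sample proportion
test - the design target was detecting a halving of early-warning-sign
frequency, 40% to 20%, over 12 weeks at one-sided alpha 0.2 (a deliberately
liberal level, as is conventional for feasibility trials), with the total
sample inflated for 10% dropout; (ii) the baseline-adjusted ANCOVA for the
symptom endpoint - follow-up score regressed on allocation group and site
with the baseline score as covariate, the group coefficient being the
adjusted mean difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PowerSpec",
    "EndpointRecord",
    "AncovaResult",
    "SingularDesignError",
    "power_two_proportions",
    "sample_size_two_proportions",
    "ancova_adjusted_difference",
    "simulate_endpoint_trial",
]

GROUPS = ("active", "control")


class SingularDesignError(ValueError):
    """The ANCOVA design matrix is rank-deficient (e.g. group confounded with site)."""


@dataclass(frozen=True)
class PowerSpec:
    p_control: float
    p_treatment: float
    alpha: float = 0.2
    n_total: int = 72
    dropout: float = 0.10

    def __post_init__(self) -> None:
        for name in ("p_control", "p_treatment", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.n_total < 4:
            raise ValueError("n_total must be at least 4")


@dataclass(frozen=True)
class EndpointRecord:
    participant_id: str
    group: str  # "active" | "control"
    site: str
    baseline_score: float
    followup_score: float


@dataclass(frozen=True)
class AncovaResult:
    adjusted_mean_difference: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    p_one_tailed: float
    se: float
    df_resid: int
    n_used: int
    n_dropped: int


def power_two_proportions(
    p_control: float,
    p_treatment: float,
    alpha: float = 0.2,
    n_total: int = 72,
    dropout: float = 0.10,
) -> float:
    """Power of the one-sided two-sample proportion z-test.

    Uses the unpooled-variance normal approximation without continuity
    correction.  The analyzable sample is ``n_total * (1 - dropout)``, split
    equally between arms and left fractional (no flooring): the design
    question is about expected information, not an integer headcount.
    Returns ``alpha`` in the null case ``p_control == p_treatment``.
    """
    spec = PowerSpec(p_control, p_treatment, alpha, n_total, dropout)
    n_arm = spec.n_total * (1.0 - spec.dropout) / 2.0
    if spec.p_control == spec.p_treatment:
        warnings.warn("null case p_control == p_treatment: power equals alpha", stacklevel=2)
        return spec.alpha
    se = np.sqrt(
        spec.p_control * (1 - spec.p_control) / n_arm
        + spec.p_treatment * (1 - spec.p_treatment) / n_arm
    )
    z_alpha = stats.norm.ppf(1.0 - spec.alpha)
    return float(stats.norm.cdf(abs(spec.p_control - spec.p_treatment) / se - z_alpha))


def sample_size_two_proportions(
    p_control: float,
    p_treatment: float,
    alpha: float = 0.2,
    target_power: float = 0.80,
    dropout: float = 0.10,
) -> int:
    """Smallest even total sample size whose power reaches ``target_power``."""
    if p_control == p_treatment:
        raise ValueError("cannot size a trial for a null effect")
    if not 0 < target_power < 1:
        raise ValueError(f"target_power must be in (0, 1), got {target_power}")
    lo, hi = 4, 8
    while power_two_proportions(p_control, p_treatment, alpha, hi, dropout) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:  # pragma: no cover - defensive
            raise ValueError("required sample size implausibly large")
    while hi - lo > 2:  # bisect over even n
        mid = (lo + hi) // 2
        mid -= mid % 2
        if power_two_proportions(p_control, p_treatment, alpha, mid, dropout) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in records],
                "group": [r.group for r in records],
                "site": [r.site for r in records],
                "baseline_score": [r.baseline_score for r in records],
                "followup_score": [r.followup_score for r in records],
            }
        )
    return df


def ancova_adjusted_difference(
    records,
    interaction: bool = False,
    favored_direction: str = "decrease",
) -> AncovaResult:
    """Baseline-adjusted treatment effect: OLS of follow-up on group + site + baseline.

    ``records`` is a list of :class:`EndpointRecord` or an equivalent
    DataFrame.  Rows with missing fields are listwise-deleted and counted in
    ``n_dropped``.  ``adjusted_mean_difference`` is the active-minus-control
    group coefficient; the 95% CI and two-tailed p come from the t
    distribution on the residual degrees of freedom.  The one-tailed p is
    half the two-tailed p when the estimate lies in the favored direction
    ("decrease" if lower follow-up scores favor the intervention) and
    ``1 - p/2`` otherwise.
    """
    df = _records_frame(records)
    n_input = len(df)
    df = df.dropna(subset=["group", "site", "baseline_score", "followup_score"])
    n_used = len(df)
    for g in df["group"].unique():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
    counts = df["group"].value_counts()
    if any(counts.get(g, 0) < 2 for g in GROUPS):
        raise ValueError("need at least 2 analyzable records per group")

    y = df["followup_score"].to_numpy(float)
    active = (df["group"] == "active").to_numpy(float)
    baseline = df["baseline_score"].to_numpy(float)
    cols = [np.ones(n_used), active]
    names = ["intercept", "active"]
    sites = sorted(df["site"].unique())
    if len(sites) < 2:
        warnings.warn("single site: site factor dropped from the model", stacklevel=2)
    else:
        for s in sites[1:]:
            cols.append((df["site"] == s).to_numpy(float))
            names.append(f"site[{s}]")
        if interaction:
            for s in sites[1:]:
                cols.append(active * (df["site"] == s).to_numpy(float))
                names.append(f"active:site[{s}]")
    cols.append(baseline)
    names.append("baseline")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if len(sites) >= 2 and all(df.groupby("site")["group"].nunique() == 1):
            raise SingularDesignError("allocation group is confounded with site")
        raise SingularDesignError(f"singular ANCOVA design (columns {names})")

    fit = sm.OLS(y, X).fit()
    i = names.index("active")
    est = float(fit.params[i])
    se = float(fit.bse[i])
    dfr = int(fit.df_resid)
    tcrit = stats.t.ppf(0.975, dfr)
    p2 = float(fit.pvalues[i])
    tss = float(np.sum((y - y.mean()) ** 2))
    if fit.ssr <= 1e-12 * max(tss, 1.0) or not np.isfinite(p2):
        # perfect fit: the t statistic degenerates; report the limit
        p2 = 1.0 if abs(est) <= 1e-8 * max(1.0, float(np.abs(y).max())) else 0.0
    favors = est < 0 if favored_direction == "decrease" else est > 0
    p1 = p2 / 2.0 if favors else 1.0 - p2 / 2.0
    return AncovaResult(
        adjusted_mean_difference=est,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        p_two_tailed=p2,
        p_one_tailed=p1,
        se=se,
        df_resid=dfr,
        n_used=n_used,
        n_dropped=n_input - n_used,
    )


def simulate_endpoint_trial(
    n_total: int = 72,
    effect: float = 0.0,
    seed: int | np.random.Generator = 0,
    sites: tuple[str, str] = ("manchester", "london"),
    baseline_mean: float = 15.0,
    baseline_sd: float = 4.0,
    baseline_slope: float = 0.6,
    site_shift: float = 1.5,
    residual_sd: float = 4.0,
) -> pd.DataFrame:
    """Synthetic endpoint table for the ANCOVA: balanced two-site, two-arm trial.

    Follow-up = intercept + baseline_slope * baseline + effect * active
    + site_shift * second-site + N(0, residual_sd).  ``effect`` is the true
    adjusted mean difference (negative favors the active arm).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_site = n_total // 2
    site_col = np.where(np.arange(n_total) < n_site, sites[0], sites[1])
    group_col = np.where(np.arange(n_total) % 2 == 0, "active", "control")
    for lo, hi in ((0, n_site), (n_site, n_total)):  # randomize within site
        rng.shuffle(group_col[lo:hi])
    b = rng.normal(baseline_mean, baseline_sd, n_total)
    f = (
        5.0
        + baseline_slope * b
        + np.where(group_col == "active", effect, 0.0)
        + np.where(site_col == sites[1], site_shift, 0.0)
        + rng.normal(0.0, residual_sd, n_total)
    )
    return pd.DataFrame(
        {
            "participant_id": [f"T{k + 1:03d}" for k in range(n_total)],
            "group": group_col,
            "site": site_col,
            "baseline_score": b,
            "followup_score": f,
        }
    )
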