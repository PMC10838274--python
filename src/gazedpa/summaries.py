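"""Window-level fixation summaries: trial proportions, effect sizes, power.

Proportions are computed per trial (percent of in-window samples on each
picture), then summarised per condition x AOI over trials.  Effect sizes use
the equal-weight pooled-SD form of Cohen's d,

    d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2),

which is the convention that reproduces published effect sizes from printed
mean/SD pairs of trial-level fixation percentages.  The a-priori power helper
inverts the noncentral-t power curve of a two-tailed paired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, TrialSet, WINDOW_LABELS


def window_proportions(ts: TrialSet, window: str = "anticipation",
                       include_filler: bool = False) -> pd.DataFrame:
    """Per-trial fixation percentages on the factual and illusory pictures.

    ``p_aoi = 100 * (samples on aoi in window) / (all samples in window)``.
    Trials with zero in-window samples are dropped with a warning.  Requires
    :func:`gazedpa.core.assign_windows` to have been applied.

    Returns a DataFrame with columns ``participant, condition, trial, window,
    p_factual, p_illusory, n_samples``.
    """
    if window not in WINDOW_LABELS:
        raise ConfigError(f"unknown window label {window!r}; expected one of {WINDOW_LABELS}")
    if "window" not in ts.samples.columns:
        raise ConfigError("samples carry no window labels; call assign_windows first")
    df = ts.samples
    if not include_filler:
        df = df[df["condition"] != "filler"]
    trials = df.drop_duplicates(["participant", "trial"])[["participant", "condition", "trial"]]
    win = df[df["window"] == window]
    agg = (win.assign(_f=(win["aoi"] == "factual").astype(int),
                      _i=(win["aoi"] == "illusory").astype(int))
           .groupby(["participant", "condition", "trial"], sort=True, observed=True)
           .agg(nf=("_f", "sum"), ni=("_i", "sum"), n_samples=("_f", "size"))
           .reset_index())
    n_dropped = len(trials) - len(agg)
    if n_dropped > 0:
        warnings.warn(f"{n_dropped} trial(s) have no samples in the {window!r} window "
                      "and were dropped", stacklevel=2)
    agg["p_factual"] = 100.0 * agg["nf"] / agg["n_samples"]
    agg["p_illusory"] = 100.0 * agg["ni"] / agg["n_samples"]
    agg["window"] = window
    return agg[["participant", "condition", "trial", "window",
                "p_factual", "p_illusory", "n_samples"]]


def summarize_condition(props: pd.DataFrame) -> pd.DataFrame:
    """Condition x AOI mean and sample SD of trial-level fixation percentages.

    Statistics are taken over trial-level observations, not participant means.
    With a single observation the SD is reported as NaN.
    """
    if not len(props):
        raise ValueError("empty proportion table")
    long = props.melt(id_vars=["participant", "condition", "trial"],
                      value_vars=["p_factual", "p_illusory"],
                      var_name="aoi", value_name="percent")
    long["aoi"] = long["aoi"].str.removeprefix("p_")
    out = (long.groupby(["condition", "aoi"], sort=True, observed=True)["percent"]
           .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                n_trials="size")
           .reset_index())
    return out


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the two groups' summary statistics (percent scale)."""

    d: float
    m1: float
    s1: float
    m2: float
    s2: float

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.d, ndigits)


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> EffectSize:
    """Cohen's d with the equal-weight pooled SD ``sqrt((s1^2 + s2^2)/2)``.

    d is 0 whenever the means agree; with both SDs zero and unequal means the
    statistic is undefined and a ValueError is raised.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if m1 == m2:
        return EffectSize(0.0, m1, s1, m2, s2)
    pooled = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if pooled == 0:
        raise ValueError("Cohen's d undefined: both SDs are zero with unequal means")
    return EffectSize(float((m1 - m2) / pooled), m1, s1, m2, s2)


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power specification for a two-tailed paired t test.

    ``dz`` is the standardized mean difference of the paired observations.
    """

    dz: float
    alpha: float = 0.05
    power: float = 0.8
    tails: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.tails != "two":
            raise ValueError("only two-tailed tests are supported")


def paired_t_power(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-tailed paired t test at sample size ``n``.

    Uses the noncentral t distribution with ``n - 1`` degrees of freedom and
    noncentrality ``dz * sqrt(n)``.
    """
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = dz * np.sqrt(n)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n >= 2 at which the paired t test attains the target power."""
    if spec.dz == 0:
        raise ValueError("power target unattainable at dz = 0")
    dz = abs(spec.dz)
    n = 2
    while paired_t_power(n, dz, spec.alpha) < spec.power:
        n += 1
        if n > n_max:
            raise ValueError(f"required sample size exceeds {n_max}")
    return n


__all__ = ["window_proportions", "summarize_condition", "EffectSize", "cohens_d",
           "PowerSpec", "paired_t_power", "required_sample_size"]
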