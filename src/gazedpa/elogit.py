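"""Weighted empirical-logit bin tests and the consecutive-bin onset rule.

For each 200-ms bin and condition, every contributing participant supplies two
observations: the empirical logit of their factual-look count and of their
illusory-look count, each against the participant's total sample count in the
bin.  A weighted linear model ``elog ~ intercept + is_factual`` (weights = the
reciprocal empirical-logit variance approximation) tests whether looks to the
factual exceed looks to the illusory; the divergence point is the left edge of
the first run of ``k`` consecutive significant bins.

Because the design is a two-group comparison, the weighted least-squares fit
has a closed form (difference of weighted group means); it is implemented as
vectorised normal equations so the bootstrap can evaluate thousands of bins
at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError


def empirical_logit(y, n):
    """Empirical logit and its variance weight for counts ``y`` of ``n``.

    elog = ln((y + 0.5) / (n - y + 0.5));  w = 1/(y + 0.5) + 1/(n - y + 0.5).

    Both are finite for any 0 <= y <= n with n >= 1.  Accepts scalars or
    arrays.  Cells with n = 0 are undefined; callers skip them.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("empirical_logit requires n >= 1")
    if np.any((y < 0) | (y > n)):
        raise ValueError("empirical_logit requires 0 <= y <= n")
    a = y + 0.5
    b = n - y + 0.5
    elog = np.log(a / b)
    w = 1.0 / a + 1.0 / b
    if elog.ndim == 0:
        return float(elog), float(w)
    return elog, w


@dataclass(frozen=True)
class OnsetRule:
    """Divergence-point detection rule.

    ``k`` consecutive bins must each show significantly more factual than
    illusory looks at the per-bin level ``alpha`` (one-sided by default).
    """

    k: int = 3
    alpha: float = 0.05
    tails: str = "one"  # "one" (factual > illusory) or "two"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ConfigError("tails must be 'one' or 'two'")


@dataclass(frozen=True)
class BinTest:
    """Result of the weighted per-bin factual-vs-illusory test."""

    bin_start_ms: int
    coefficient: float  # weighted elogit difference, factual - illusory
    t_value: float
    p_value: float
    significant: bool
    n_participants: int
    note: str | None = None  # e.g. "insufficient_data"


@dataclass(frozen=True)
class OnsetResult:
    """Detected divergence point for one condition (bin left edge, or None)."""

    condition: str | None
    onset_ms: int | None
    bin_tests: tuple = ()


def _wls_group_stats(yf, yi, n, alpha: float, tails: str):
    """Vectorised two-group weighted least squares over the participant axis.

    Parameters are arrays of shape (P, ...) — participants first, any number
    of trailing axes (condition, bin, bootstrap replicate...).  Cells with
    n == 0 contribute no rows.  Returns (coefficient, t, p, significant,
    n_participants) with the participant axis reduced.

    The model is ``elog ~ 1 + is_factual`` with weights 1/w; for a dummy-coded
    two-group design the WLS slope is the difference of the weighted group
    means and the normal equations collapse to the closed form used here.
    """
    yf = np.asarray(yf, dtype=float)
    yi = np.asarray(yi, dtype=float)
    n = np.asarray(n, dtype=float)
    mask = n > 0
    n_safe = np.where(mask, n, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.log((yf + 0.5) / (n_safe - yf + 0.5))
        wf = 1.0 / (yf + 0.5) + 1.0 / (n_safe - yf + 0.5)
        ei = np.log((yi + 0.5) / (n_safe - yi + 0.5))
        wi = 1.0 / (yi + 0.5) + 1.0 / (n_safe - yi + 0.5)
        of = np.where(mask, 1.0 / wf, 0.0)  # regression weights
        oi = np.where(mask, 1.0 / wi, 0.0)
        ef = np.where(mask, ef, 0.0)
        ei = np.where(mask, ei, 0.0)

        Wf = of.sum(axis=0)
        Wi = oi.sum(axis=0)
        npart = mask.sum(axis=0)
        mf = np.where(Wf > 0, (of * ef).sum(axis=0) / np.where(Wf > 0, Wf, 1.0), np.nan)
        mi = np.where(Wi > 0, (oi * ei).sum(axis=0) / np.where(Wi > 0, Wi, 1.0), np.nan)
        coef = mf - mi
        rss = (of * (ef - mf) ** 2).sum(axis=0) + (oi * (ei - mi) ** 2).sum(axis=0)
        dof = 2.0 * npart - 2.0
        sigma2 = np.where(dof > 0, rss / np.where(dof > 0, dof, 1.0), np.nan)
        var = sigma2 * (np.where(Wf > 0, 1.0 / np.where(Wf > 0, Wf, 1.0), np.nan)
                        + np.where(Wi > 0, 1.0 / np.where(Wi > 0, Wi, 1.0), np.nan))
        se = np.sqrt(var)
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0),
                     np.where(coef == 0, 0.0, np.sign(coef) * np.inf))
        if tails == "one":
            p = stats.t.sf(t, np.maximum(dof, 1.0))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(dof, 1.0))
        p = np.where(np.isinf(t), np.where(t > 0, 0.0, 1.0 if tails == "one" else 0.0), p)
        p = np.where(t == 0.0, 0.5 if tails == "one" else 1.0, p)
    sig = (coef > 0) & (p < alpha) & (npart >= 2)
    sig = np.where(np.isnan(coef) | np.isnan(p), False, sig).astype(bool)
    return coef, t, p, sig, npart


def bin_test(cells: pd.DataFrame, rule: OnsetRule = OnsetRule(),
             bin_start_ms: int | None = None) -> BinTest:
    """Weighted factual-vs-illusory test for one condition x bin.

    ``cells`` holds one row per participant with columns ``y_factual,
    y_illusory, n_total`` (and optionally ``bin_start_ms``).  Participants
    with ``n_total == 0`` contribute no rows.  With fewer than two
    contributing participants the bin is marked not significant with an
    ``insufficient_data`` note rather than raising, so the bootstrap loop
    never aborts on a thin resample.
    """
    if bin_start_ms is None:
        starts = cells["bin_start_ms"].unique() if "bin_start_ms" in cells.columns else [0]
        if len(starts) != 1:
            raise ValueError("cells must cover exactly one bin; pass bin_start_ms explicitly")
        bin_start_ms = int(starts[0])
    yf = cells["y_factual"].to_numpy(dtype=float)
    yi = cells["y_illusory"].to_numpy(dtype=float)
    n = cells["n_total"].to_numpy(dtype=float)
    coef, t, p, sig, npart = _wls_group_stats(yf, yi, n, rule.alpha, rule.tails)
    npart = int(npart)
    if npart < 2:
        return BinTest(bin_start_ms=bin_start_ms, coefficient=float(coef) if npart else np.nan,
                       t_value=np.nan, p_value=np.nan, significant=False,
                       n_participants=npart, note="insufficient_data")
    return BinTest(bin_start_ms=bin_start_ms, coefficient=float(coef), t_value=float(t),
                   p_value=float(p), significant=bool(sig), n_participants=npart)


def condition_bin_tests(binned: pd.DataFrame, condition: str,
                        rule: OnsetRule = OnsetRule()) -> list[BinTest]:
    """Per-bin tests for one condition of a :func:`gazedpa.core.bin_fixations` table."""
    sub = binned[binned["condition"] == condition]
    if not len(sub):
        raise ValueError(f"no bins for condition {condition!r}")
    return [bin_test(grp, rule, bin_start_ms=int(start))
            for start, grp in sub.groupby("bin_start_ms", sort=True)]


def detect_onset(tests, rule: OnsetRule = OnsetRule(),
                 condition: str | None = None) -> OnsetResult:
    """First bin starting a run of >= k significant bins (divergence point).

    ``tests`` must be ordered by ``bin_start_ms`` over contiguous bins.
    Returns an absent onset (``onset_ms=None``) when no such run exists.
    """
    tests = list(tests)
    if not tests:
        raise ValueError("empty bin-test sequence")
    starts = np.array([t.bin_start_ms for t in tests])
    if len(starts) > 1:
        steps = np.diff(starts)
        if (steps <= 0).any() or len(set(steps.tolist())) > 1:
            raise ValueError("bin tests must be ordered over contiguous, equal-width bins")
    sig = np.array([t.significant for t in tests], dtype=bool)
    onset = _first_run_start(sig, rule.k)
    return OnsetResult(condition=condition,
                       onset_ms=int(starts[onset]) if onset is not None else None,
                       bin_tests=tuple(tests))


def _first_run_start(sig: np.ndarray, k: int):
    """Index of the first position starting k consecutive True, else None."""
    if len(sig) < k:
        return None
    window = np.ones(k, dtype=int)
    runs = np.convolve(sig.astype(int), window, mode="valid") == k
    idx = np.flatnonzero(runs)
    return int(idx[0]) if len(idx) else None


__all__ = ["empirical_logit", "OnsetRule", "BinTest", "OnsetResult",
           "bin_test", "condition_bin_tests", "detect_onset"]
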