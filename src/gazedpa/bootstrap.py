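"""Nonparametric bootstrap of the divergence-point estimator.

Participants are resampled with replacement (stratified so every condition
keeps its design), the per-bin weighted empirical-logit tests and the
consecutive-bin onset rule are re-run on each replicate, and the resulting
onset distributions are summarised by their mean, percentile confidence
interval and highest density interval.  Between-condition contrasts subtract
one onset distribution from the other replicate-wise: each replicate uses the
same participant draw for every condition, so the pairing is coherent.

Reproducibility: one root seed; per-replicate generators are derived with
``numpy.random.SeedSequence(seed).spawn(B)``, so replicate ``b`` sees the same
draws regardless of the total replicate count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ANALYSIS_CONDITIONS, ConfigError
from .elogit import OnsetRule, _wls_group_stats


def percentile_ci(v, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval: the (1-level)/2 and 1-(1-level)/2
    empirical quantiles under linear interpolation (h = (n-1)p)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lo, hi = np.quantile(v, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def hdi(v, level: float = 0.95) -> tuple[float, float]:
    """Highest density interval from a sample.

    Among all windows of ``m = ceil(level * n)`` consecutive order statistics,
    returns the narrowest ``[x(i), x(i+m-1)]``; ties are broken by the
    smallest lower bound.  Can be narrower than the percentile interval for
    skewed or multimodal onset distributions.
    """
    v = np.sort(np.asarray(v, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = int(math.ceil(level * n))
    if m >= n:
        return float(v[0]), float(v[-1])
    widths = v[m - 1:] - v[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: earliest window
    return float(v[i]), float(v[i + m - 1])


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration: replicate count, CI level, seed, and the
    policy for replicates in which no onset is detected."""

    B: int = 2000
    level: float = 0.95
    seed: int = 0
    missing_onset_policy: str = "drop_and_warn"  # or "censor_at_window_end"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if not 0 < self.level < 1:
            raise ConfigError("level must be in (0, 1)")
        if self.missing_onset_policy not in ("drop_and_warn", "censor_at_window_end"):
            raise ConfigError("missing_onset_policy must be 'drop_and_warn' or "
                              "'censor_at_window_end'")


@dataclass
class BootstrapDistribution:
    """Bootstrap onset distribution for one condition.

    ``onsets`` holds the retained replicate onsets (ms, bin left edges);
    ``replicate_onsets`` the full length-B vector with NaN where no onset was
    detected (before the missing-onset policy), kept so difference
    distributions can pair replicates even under the drop policy.
    """

    condition: str
    onsets: np.ndarray
    n_missing: int
    mean_ms: float
    percentile_ci: tuple[float, float]
    hdi: tuple[float, float]
    B: int
    level: float = 0.95
    seed: int | None = None
    replicate_onsets: np.ndarray | None = None

    @classmethod
    def from_onsets(cls, condition: str, onsets, level: float = 0.95,
                    n_missing: int = 0, seed: int | None = None) -> "BootstrapDistribution":
        onsets = np.asarray(onsets, dtype=float)
        return cls(condition=condition, onsets=onsets, n_missing=n_missing,
                   mean_ms=float(np.mean(onsets)),
                   percentile_ci=percentile_ci(onsets, level),
                   hdi=hdi(onsets, level), B=len(onsets) + n_missing,
                   level=level, seed=seed)


@dataclass
class DifferenceDistribution:
    """Replicate-wise onset differences between two conditions (a - b)."""

    condition_pair: tuple[str, str]
    diffs: np.ndarray
    mean_ms: float
    percentile_ci: tuple[float, float]
    significant: bool
    n_dropped: int = 0

    @classmethod
    def from_diffs(cls, pair, diffs, level: float = 0.95,
                   n_dropped: int = 0) -> "DifferenceDistribution":
        diffs = np.asarray(diffs, dtype=float)
        lo, hi_ = percentile_ci(diffs, level)
        return cls(condition_pair=tuple(pair), diffs=diffs, mean_ms=float(np.mean(diffs)),
                   percentile_ci=(lo, hi_), significant=bool(lo > 0 or hi_ < 0),
                   n_dropped=n_dropped)


def resample_participants(cells: pd.DataFrame, rng) -> pd.DataFrame:
    """Resample participants with replacement from a binned-count table.

    Draws as many participants as the table contains; a participant drawn
    twice contributes two copies of its per-bin counts under distinct
    pseudo-identifiers (``<id>#<draw>``).  Condition structure is preserved:
    every drawn participant carries all of its conditions.
    """
    participants = np.array(sorted(cells["participant"].unique()))
    P = len(participants)
    idx = np.asarray(rng.integers(0, P, size=P))
    groups = {p: g for p, g in cells.groupby("participant", sort=True)}
    out = []
    for draw, i in enumerate(idx):
        g = groups[participants[i]].copy()
        g["participant"] = f"{participants[i]}#{draw}"
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _cells_to_arrays(cells: pd.DataFrame, conditions=None):
    """Pivot a binned-count table to arrays of shape (P, C, K)."""
    if conditions is None:
        conditions = [c for c in ANALYSIS_CONDITIONS if c in set(cells["condition"])]
        extra = sorted(set(cells["condition"]) - set(ANALYSIS_CONDITIONS) - {"filler"})
        conditions = list(conditions) + extra
    participants = sorted(cells["participant"].unique())
    bins = np.sort(cells["bin_start_ms"].unique())
    shape = (len(participants), len(conditions), len(bins))
    pi = {p: i for i, p in enumerate(participants)}
    ci = {c: i for i, c in enumerate(conditions)}
    bi = {b: i for i, b in enumerate(bins)}
    yf = np.zeros(shape)
    yi = np.zeros(shape)
    n = np.zeros(shape)
    sub = cells[cells["condition"].isin(conditions)]
    ip = sub["participant"].map(pi).to_numpy()
    ic = sub["condition"].map(ci).to_numpy()
    ib = sub["bin_start_ms"].map(bi).to_numpy()
    yf[ip, ic, ib] = sub["y_factual"].to_numpy(dtype=float)
    yi[ip, ic, ib] = sub["y_illusory"].to_numpy(dtype=float)
    n[ip, ic, ib] = sub["n_total"].to_numpy(dtype=float)
    return yf, yi, n, participants, list(conditions), bins


def _replicate_indices(seed: int, B: int, P: int) -> np.ndarray:
    """(B, P) participant draws; replicate b is stable under changes of B."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(B)
    out = np.empty((B, P), dtype=np.intp)
    for b, child in enumerate(children):
        out[b] = np.random.default_rng(child).integers(0, P, size=P)
    return out


def bootstrap_onsets(cells: pd.DataFrame,
                     rule: OnsetRule = OnsetRule(),
                     spec: BootstrapSpec = BootstrapSpec(),
                     conditions=None) -> dict[str, BootstrapDistribution]:
    """Bootstrap the divergence point of every condition in a binned table.

    For each replicate, participants are resampled with replacement (one draw
    shared by all conditions), the per-bin weighted empirical-logit tests are
    recomputed, and the consecutive-bin rule is applied; the B onsets are then
    summarised.  Fully reproducible given ``spec.seed``.

    Raises
    ------
    ValueError
        If every replicate of some condition fails to detect an onset.
    """
    yf, yi, n, participants, conds, bins = _cells_to_arrays(cells, conditions)
    P, C, K = yf.shape
    if P < 2:
        raise ValueError("bootstrap requires at least 2 participants")
    if K < rule.k:
        raise ConfigError(f"window has {K} bins but the rule needs k={rule.k}")
    bin_width = int(bins[1] - bins[0]) if K > 1 else 200
    window_end = float(bins[-1] + bin_width)

    idx = _replicate_indices(spec.seed, spec.B, P)          # (B, P)
    # gather resampled counts: (B, P, C, K), participant axis second
    coef, t, p, sig, npart = _wls_group_stats(
        np.swapaxes(yf[idx], 0, 1), np.swapaxes(yi[idx], 0, 1),
        np.swapaxes(n[idx], 0, 1), rule.alpha, rule.tails)   # -> (B, C, K)

    # first run of k consecutive significant bins, per replicate x condition
    sig_int = sig.astype(np.int8)
    run = np.ones_like(sig_int[..., : K - rule.k + 1], dtype=bool)
    for j in range(rule.k):
        run &= sig_int[..., j: j + K - rule.k + 1].astype(bool)
    any_run = run.any(axis=-1)
    first = run.argmax(axis=-1)
    onset = np.where(any_run, bins[0] + bin_width * first, np.nan)  # (B, C)

    out: dict[str, BootstrapDistribution] = {}
    for ci, cond in enumerate(conds):
        raw = onset[:, ci].astype(float)
        missing = int(np.isnan(raw).sum())
        if missing == spec.B and spec.missing_onset_policy == "drop_and_warn":
            raise ValueError(f"no replicate detected an onset for condition {cond!r}")
        if spec.missing_onset_policy == "censor_at_window_end":
            kept = np.where(np.isnan(raw), window_end, raw)
            n_missing = 0
            full = kept.copy()
        else:
            if missing:
                warnings.warn(f"condition {cond!r}: {missing} of {spec.B} replicates "
                              "detected no onset and were dropped", stacklevel=2)
            kept = raw[~np.isnan(raw)]
            n_missing = missing
            full = raw
        dist = BootstrapDistribution.from_onsets(cond, kept, level=spec.level,
                                                 n_missing=n_missing, seed=spec.seed)
        dist.replicate_onsets = full
        out[cond] = dist
    return out


def difference_distribution(a: BootstrapDistribution, b: BootstrapDistribution,
                            spec: BootstrapSpec | None = None) -> DifferenceDistribution:
    """Replicate-wise onset difference ``a - b`` with percentile CI.

    The contrast is judged significant when the CI excludes zero.  When both
    distributions carry full replicate vectors (as produced by
    :func:`bootstrap_onsets`), replicates missing in either condition are
    dropped pairwise; otherwise the retained onset vectors must have equal
    length, and a mismatch instructs switching to the
    ``censor_at_window_end`` policy.
    """
    level = spec.level if spec is not None else a.level
    ra, rb = a.replicate_onsets, b.replicate_onsets
    if ra is not None and rb is not None and len(ra) == len(rb):
        ok = ~(np.isnan(ra) | np.isnan(rb))
        diffs = ra[ok] - rb[ok]
        n_dropped = int(len(ra) - ok.sum())
        if diffs.size == 0:
            raise ValueError("no replicate has an onset in both conditions")
    else:
        if len(a.onsets) != len(b.onsets):
            raise ValueError(
                "onset vectors differ in length after missing-onset handling; rerun the "
                "bootstrap with missing_onset_policy='censor_at_window_end' to keep "
                "replicate pairing")
        diffs = np.asarray(a.onsets, dtype=float) - np.asarray(b.onsets, dtype=float)
        n_dropped = 0
    return DifferenceDistribution.from_diffs((a.condition, b.condition), diffs,
                                             level=level, n_dropped=n_dropped)


__all__ = ["percentile_ci", "hdi", "BootstrapSpec", "BootstrapDistribution",
           "DifferenceDistribution", "resample_participants", "bootstrap_onsets",
           "difference_distribution"]
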