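"""Trial-level gaze data model: experiment windows, correctness filtering, binning.

The unit of raw data is the *gaze sample*: one row per tracker sample with a
participant, item, condition, trial, time since trial onset (ms), an
area-of-interest (AOI) label and the trial's response correctness.  Samples are
held in a :class:`TrialSet` (a validated pandas DataFrame plus a
:class:`WindowConfig` describing the trial timeline).  Downstream onset
inference works on :func:`bin_fixations` output: per participant x condition x
200-ms bin counts of samples on the factual and illusory pictures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: closed set of condition labels; ``filler`` is parsed but excluded from analyses
CONDITIONS = ("negative", "nobody", "positive", "filler")
#: conditions entering onset / summary analyses
ANALYSIS_CONDITIONS = ("negative", "nobody", "positive")
#: closed set of area-of-interest labels
AOIS = ("factual", "illusory", "elsewhere")
#: canonical logical column names for gaze samples
SAMPLE_COLUMNS = ("participant", "item", "condition", "trial", "t_ms", "aoi", "correct")
#: window labels produced by :func:`assign_windows`
WINDOW_LABELS = ("pre_window", "preview", "anticipation", "integration")


class SchemaError(ValueError):
    """Input table does not have the required shape (column or label mapping missing)."""


class ValidationError(ValueError):
    """Input values violate the data model (unknown label, inconsistent trial)."""


class ConfigError(ValueError):
    """Analysis configuration is internally inconsistent."""


@dataclass(frozen=True)
class WindowConfig:
    """Trial-timeline windows, half-open ``[lo, hi)`` in ms from trial onset.

    Defaults follow a blank-screen trial of fixation cross (0-1500 ms),
    picture preview (1500-4000 ms), auditory input on a blank screen
    (4000-7000 ms, the *anticipation* window) and picture reappearance
    until button press (7000 ms onward, the *integration* window).
    """

    preview: tuple[float, float] = (1500.0, 4000.0)
    anticipation: tuple[float, float] = (4000.0, 7000.0)
    integration: tuple[float, float] = (7000.0, math.inf)

    def __post_init__(self) -> None:
        p, a, i = self.preview, self.anticipation, self.integration
        for name, (lo, hi) in (("preview", p), ("anticipation", a), ("integration", i)):
            if not lo < hi:
                raise ConfigError(f"window {name!r} has lo >= hi: [{lo}, {hi})")
        if not (p[1] <= a[0] and a[1] <= i[0]):
            raise ConfigError("windows must be disjoint and ordered preview < anticipation < integration")

    def bounds(self, label: str) -> tuple[float, float]:
        """Return ``[lo, hi)`` for a window label (``pre_window`` is ``[0, preview.lo)``)."""
        if label == "pre_window":
            return (0.0, self.preview[0])
        try:
            return getattr(self, label)
        except AttributeError:
            raise ConfigError(f"unknown window label {label!r}; expected one of {WINDOW_LABELS}") from None

    def label_times(self, t_ms: np.ndarray) -> np.ndarray:
        """Vectorised window label for each time point."""
        t = np.asarray(t_ms, dtype=float)
        out = np.where(
            t < self.preview[0], "pre_window",
            np.where(t < self.anticipation[0], "preview",
                     np.where(t < self.integration[0], "anticipation", "integration")),
        )
        return out

    def to_dict(self) -> dict:
        def _pair(p):
            return [p[0], None if math.isinf(p[1]) else p[1]]
        return {"preview": _pair(self.preview),
                "anticipation": _pair(self.anticipation),
                "integration": _pair(self.integration)}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowConfig":
        def _pair(p):
            lo, hi = p
            return (float(lo), math.inf if hi is None else float(hi))
        return cls(preview=_pair(d["preview"]), anticipation=_pair(d["anticipation"]),
                   integration=_pair(d["integration"]))


@dataclass
class TrialSet:
    """A validated collection of gaze samples with its window configuration.

    ``samples`` holds one row per gaze sample with the canonical columns
    (:data:`SAMPLE_COLUMNS`) and, after :func:`assign_windows`, a ``window``
    column.  ``metadata`` is free-form (language group, sampling interval, ...).
    """

    samples: pd.DataFrame
    window_config: WindowConfig = field(default_factory=WindowConfig)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"samples missing required columns: {missing}")
        if len(df):
            bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
            if bad_cond:
                raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
            bad_aoi = set(df["aoi"].unique()) - set(AOIS)
            if bad_aoi:
                raise ValidationError(f"unknown AOI labels: {sorted(bad_aoi)}")
            t = df["t_ms"].to_numpy()
            if (t < 0).any():
                raise ValidationError("t_ms must be >= 0")
            nun = df.groupby(["participant", "trial"], sort=False)[["condition", "correct"]].nunique()
            bad = nun[(nun > 1).any(axis=1)]
            if len(bad):
                raise ValidationError(
                    f"trials with more than one condition or correctness value: {list(bad.index[:5])}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_trials(self) -> int:
        if not len(self.samples):
            return 0
        return self.samples.groupby(["participant", "trial"], sort=False).ngroups

    def trials(self) -> pd.DataFrame:
        """One row per trial: participant, trial, item, condition, correct."""
        return (self.samples
                .drop_duplicates(["participant", "trial"])
                [["participant", "trial", "item", "condition", "correct"]]
                .reset_index(drop=True))

    def with_samples(self, samples: pd.DataFrame) -> "TrialSet":
        return TrialSet(samples=samples.reset_index(drop=True),
                        window_config=self.window_config,
                        metadata=dict(self.metadata))


@dataclass(frozen=True)
class AccuracySummary:
    """Per-condition response accuracy over participants, in percent."""

    condition: str
    mean_percent_correct: float
    sd_percent: float  # NaN when only one participant
    n_participants: int


def assign_windows(ts: TrialSet) -> TrialSet:
    """Label every sample with its trial window (idempotent).

    Windows are half-open ``[lo, hi)``: a sample exactly at a boundary belongs
    to the later window (t=4000 -> anticipation, t=7000 -> integration).
    """
    df = ts.samples.copy()
    df["window"] = ts.window_config.label_times(df["t_ms"].to_numpy()) if len(df) else \
        pd.Series([], dtype=object)
    return ts.with_samples(df)


def filter_correct(ts: TrialSet) -> tuple[TrialSet, list[AccuracySummary]]:
    """Keep only correct-response trials; summarise accuracy per condition.

    Accuracy is computed per participant (percent of that participant's trials
    answered correctly, per condition) and then summarised across participants
    (mean and sample SD).  Conditions left with zero correct trials are
    reported with a warning; they simply vanish from the returned samples.
    Applying the filter twice equals applying it once.
    """
    trials = ts.trials()
    summaries: list[AccuracySummary] = []
    if len(trials):
        per_part = (trials.assign(correct=trials["correct"].astype(float))
                    .groupby(["condition", "participant"], sort=True, observed=True)["correct"]
                    .mean() * 100.0)
        for cond, grp in per_part.groupby(level="condition", sort=True, observed=True):
            vals = grp.to_numpy()
            summaries.append(AccuracySummary(
                condition=str(cond),
                mean_percent_correct=float(np.mean(vals)),
                sd_percent=float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                n_participants=int(len(vals)),
            ))
        empty = [s.condition for s in summaries if s.mean_percent_correct == 0.0]
        for cond in empty:
            warnings.warn(f"condition {cond!r} has no correct trials and is dropped "
                          "from downstream analyses", stacklevel=2)
    kept = ts.samples[ts.samples["correct"].astype(bool)]
    return ts.with_samples(kept), summaries


def bin_fixations(ts: TrialSet,
                  window: tuple[float, float] | None = None,
                  bin_width_ms: int = 200,
                  include_filler: bool = False) -> pd.DataFrame:
    """Aggregate samples into per participant x condition x time-bin counts.

    Parameters
    ----------
    ts : TrialSet
        Input samples (typically after :func:`filter_correct`).
    window : (lo, hi), optional
        Half-open analysis window in ms; defaults to the TrialSet's
        anticipation window.  ``bin_width_ms`` must divide ``hi - lo``.
    bin_width_ms : int
        Bin width; 200 ms by default.
    include_filler : bool
        Filler trials are excluded unless set.

    Returns
    -------
    DataFrame with columns ``participant, condition, bin_start_ms, y_factual,
    y_illusory, n_total``.  Every (participant, condition) pair present in the
    input appears with every bin of the window, zero-filled where no samples
    fall; the per-pair sum of ``n_total`` over bins equals that pair's
    in-window sample count.
    """
    if window is None:
        window = ts.window_config.anticipation
    lo, hi = float(window[0]), float(window[1])
    if not math.isfinite(hi):
        raise ConfigError("binning needs a finite window; pass an explicit (lo, hi)")
    width = int(bin_width_ms)
    if width <= 0:
        raise ConfigError("bin_width_ms must be positive")
    span = hi - lo
    if abs(span / width - round(span / width)) > 1e-9:
        raise ConfigError(f"bin width {width} ms does not divide the window length {span} ms")

    df = ts.samples
    if not include_filler:
        df = df[df["condition"] != "filler"]
    pairs = df[["participant", "condition"]].drop_duplicates()
    n_bins = int(round(span / width))
    bin_starts = (lo + width * np.arange(n_bins)).astype(int)

    inwin = df[(df["t_ms"] >= lo) & (df["t_ms"] < hi)]
    if len(inwin):
        b = (lo + width * np.floor((inwin["t_ms"].to_numpy(dtype=float) - lo) / width)).astype(int)
        counts = (inwin.assign(bin_start_ms=b,
                               _f=(inwin["aoi"] == "factual").astype(int),
                               _i=(inwin["aoi"] == "illusory").astype(int))
                  .groupby(["participant", "condition", "bin_start_ms"], sort=True, observed=True)
                  .agg(y_factual=("_f", "sum"), y_illusory=("_i", "sum"), n_total=("_f", "size")))
    else:
        counts = pd.DataFrame(columns=["y_factual", "y_illusory", "n_total"],
                              index=pd.MultiIndex.from_arrays(
                                  [[], [], []], names=["participant", "condition", "bin_start_ms"]))

    full = pd.MultiIndex.from_frame(
        pairs.merge(pd.DataFrame({"bin_start_ms": bin_starts}), how="cross")
    )
    out = counts.reindex(full, fill_value=0).reset_index()
    out[["y_factual", "y_illusory", "n_total"]] = out[["y_factual", "y_illusory", "n_total"]].astype(int)
    return out.sort_values(["condition", "participant", "bin_start_ms"], kind="mergesort",
                           ignore_index=True)


__all__ = [
    "CONDITIONS", "ANALYSIS_CONDITIONS", "AOIS", "SAMPLE_COLUMNS", "WINDOW_LABELS",
    "SchemaError", "ValidationError", "ConfigError",
    "WindowConfig", "TrialSet", "AccuracySummary",
    "assign_windows", "filter_correct", "bin_fixations",
]
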