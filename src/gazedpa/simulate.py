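"""Generative model of blank-screen fixation timecourses with known onsets.

The simulator emulates a blank-screen negation experiment: each trial shows a
fixation cross (1500 ms) and a two-picture preview (2500 ms), plays a sentence
over a blank screen (3000 ms, the anticipation window), then redisplays the
pictures.  Gaze is sampled on a fixed grid (50 ms by default) and every sample
lands on the factual picture's location, the illusory picture's location, or
elsewhere.

Latent structure.  Each condition ``c`` has a true divergence onset ``tau_c``
(ms from trial onset); each participant ``p`` draws a single normal offset
``delta_p``, giving trial onsets ``tau_pc = tau_c + delta_p``.  During the
anticipation window an *engaged, ordinary* trial's on-picture sample at time
``t`` falls on the factual picture with conditional share

    phi(t) = phi0                                          for t <  tau_pc
    phi(t) = phi0 + (phi1 - phi0)*(2*logistic((t - tau_pc)/s) - 1)  for t >= tau_pc,

with ``phi0 = b/(1 - e)`` and ``phi1 = a/(1 - e)``, so at the population
elsewhere rate ``e`` the unconditional factual probability ramps continuously
from the baseline ``b`` to the asymptote ``a`` starting exactly at the latent
onset: the configured ``tau_c`` is the ground-truth divergence time, and
before it factual and illusory looks are exchangeable whenever
``b = (1 - e)/2`` (the default).

Blank-screen gaze is famously lumpy at the trial level: many trials never
leave the blank centre, others park on a single (empty) picture location for
the whole sentence.  The simulator reproduces this with two trial-level
mechanisms:

* *Disengagement* — with participant-specific probability ``d_p`` (mean set
  so the population elsewhere rate is ``e``), a non-capture trial's
  anticipation samples are entirely elsewhere.  The propensity is drawn once
  per participant: individuals differ far more in whether they launch
  anticipatory fixations at all than in where those fixations go, and this
  shared component moves both targets' empirical logits together.
* *Capture* — exactly ``round(q * I)`` trials per participant x condition
  lock onto a single picture.  Pre-onset lock targets are counterbalanced
  within the cell (an unpaired lock would bias every pre-onset bin of that
  participant coherently, mirroring what side counterbalancing prevents in
  the real design).  After the latent onset — with a lag of two logistic time
  constants, once the latent preference has largely risen — each capture
  trial re-locks with probability ``capture_relock_prob``, onto the factual
  with probability ``capture_post_factual``; the rest keep their balanced
  pre-onset lock for the whole window.

Together these produce the near-0/near-100 trial-level fixation percentages
(and hence the very large trial-level SDs) characteristic of blank-screen
data, while keeping every pre-onset bin exchangeable between factual and
illusory so the configured onsets remain recoverable.

Preview looks are unbiased between the two pictures; pre-cross samples are
``elsewhere``; after picture reappearance looks favour the factual.  Response
correctness is Bernoulli per trial.  All randomness flows from one seed, and
an identical seed yields a byte-identical exported TrialSet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import TrialSet, WindowConfig


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Full generative description of a synthetic blank-screen experiment.

    Defaults emulate a 42-participant, 20-item, three-condition design with
    condition onsets at 4200 (positive), 5600 (nobody) and 6000 ms (negative)
    from trial onset, all inside the 4000-7000 ms anticipation window.
    """

    n_participants: int = 42
    n_items: int = 20
    true_onsets: dict = field(default_factory=lambda: {
        "positive": 4200.0, "nobody": 5600.0, "negative": 6000.0})
    onset_sd: float = 50.0           # SD of the per-participant onset offset, ms
    baseline: float = 0.4            # factual probability before the onset (b)
    asymptote: float = 0.72          # factual probability the ramp approaches (a)
    slope: float = 100.0             # logistic time scale of the ramp, ms (s)
    p_elsewhere: float = 0.2         # mean elsewhere probability during anticipation (e)
    elsewhere_sd: float = 0.12       # SD of the per-participant disengagement propensity
    engaged_elsewhere: float = 0.05  # residual per-sample elsewhere rate in engaged trials
    capture_prob: float = 0.3        # fraction of trials locked onto one picture (q)
    capture_relock_prob: float = 0.5   # capture trials that re-lock after the onset
    capture_post_factual: float = 0.9  # re-lock lands on the factual with this probability
    capture_relock_delay_ms: float = 200.0  # re-lock lag after the latent onset
    #   (two logistic time constants: the lock flips once the latent
    #    preference has largely risen, not at its first instant)
    integration_factual: float = 0.7   # factual probability after pictures reappear
    sample_interval_ms: int = 50
    accuracy: float = 0.99           # per-trial correct-response probability (theta)
    cross_ms: int = 1500
    preview_ms: int = 2500
    audio_ms: int = 3000
    reappear_ms: int = 1000          # simulated span after picture reappearance
    seed: int = 0

    def __post_init__(self) -> None:
        b, a, e = self.baseline, self.asymptote, self.p_elsewhere
        if not 0 <= b <= a <= 1:
            raise ValueError("need 0 <= baseline <= asymptote <= 1")
        if not 0 <= e < 1:
            raise ValueError("p_elsewhere must be in [0, 1)")
        if b + e > 1 or a + e > 1:
            raise ValueError("picture and elsewhere probabilities exceed 1")
        for name in ("capture_prob", "accuracy", "capture_post_factual",
                     "capture_relock_prob", "engaged_elsewhere"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elsewhere_sd < 0:
            raise ValueError("elsewhere_sd must be nonnegative")
        if not 0 <= self.disengage_mean <= 0.85:
            raise ValueError(
                "inconsistent elsewhere configuration: the implied trial-level "
                f"disengagement rate is {self.disengage_mean:.3f}; lower p_elsewhere "
                "or capture_prob, or raise engaged_elsewhere")
        lo, hi = self.anticipation_window
        for cond, tau in self.true_onsets.items():
            if not lo <= tau < hi:
                raise ValueError(f"true onset for {cond!r} ({tau} ms) is outside the "
                                 f"anticipation window [{lo}, {hi})")
        if self.slope <= 0 or self.onset_sd < 0:
            raise ValueError("slope must be positive and onset_sd nonnegative")

    @property
    def disengage_mean(self) -> float:
        """Mean trial-level disengagement rate among non-capture trials,
        chosen so the population anticipation elsewhere rate equals ``e``:
        ``e = (1 - q) * (d + (1 - d) * e0)`` with ``e0`` the engaged residual."""
        q, e0 = self.capture_prob, self.engaged_elsewhere
        if q >= 1.0:
            return 0.0
        target = self.p_elsewhere / (1.0 - q)
        return (target - e0) / (1.0 - e0)

    @property
    def anticipation_window(self) -> tuple[float, float]:
        lo = float(self.cross_ms + self.preview_ms)
        return lo, lo + float(self.audio_ms)

    def window_config(self) -> WindowConfig:
        lo, hi = self.anticipation_window
        return WindowConfig(preview=(float(self.cross_ms), lo), anticipation=(lo, hi))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent parameters of one simulated experiment, recorded as drawn."""

    true_onsets: dict                 # condition -> tau_c (ms)
    participant_offsets: pd.Series    # participant -> delta_p (ms)


def simulate_dataset(cfg: SimConfig) -> tuple[TrialSet, GroundTruth]:
    """Draw one experiment from the generative model.

    Returns the TrialSet (long-format samples over the whole trial timeline)
    and the GroundTruth holding the condition onsets and participant offsets.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    conds = sorted(cfg.true_onsets)          # deterministic order
    P, C, I = cfg.n_participants, len(conds), cfg.n_items
    lo, hi = cfg.anticipation_window
    total_ms = cfg.cross_ms + cfg.preview_ms + cfg.audio_ms + cfg.reappear_ms
    t = np.arange(0, total_ms, cfg.sample_interval_ms, dtype=float)   # (T,)
    T = len(t)

    participants = np.array([f"p{i + 1:02d}" for i in range(P)])
    delta = rng.normal(0.0, cfg.onset_sd, size=P)                     # (P,)
    d_p = np.clip(rng.normal(cfg.disengage_mean, cfg.elsewhere_sd, size=P), 0.0, 0.9)
    tau_c = np.array([cfg.true_onsets[c] for c in conds])             # (C,)
    tau = tau_c[None, :] + delta[:, None]                             # (P, C)

    # conditional factual share among on-picture looks, ramping after tau_pc
    e, e0 = cfg.p_elsewhere, cfg.engaged_elsewhere
    phi0 = cfg.baseline / (1.0 - e)
    phi1 = cfg.asymptote / (1.0 - e)
    x = t[None, None, :] - tau[:, :, None]                            # (P, C, T)
    ramp = np.where(x >= 0, 2.0 * _logistic(x / cfg.slope) - 1.0, 0.0)
    phi_anticip = phi0 + (phi1 - phi0) * ramp

    anticipation = (t >= lo) & (t < hi)
    preview = (t >= cfg.cross_ms) & (t < lo)
    reappear = t >= hi

    phi = np.zeros((P, C, T))                                         # factual | on-picture
    pe = np.zeros(T)                                                  # per-sample elsewhere
    phi[:, :, preview] = 0.5
    pe[preview] = e
    phi[:, :, anticipation] = phi_anticip[:, :, anticipation]
    pe[anticipation] = e0
    phi[:, :, reappear] = min(cfg.integration_factual / (1.0 - e), 1.0)
    pe[reappear] = e
    # pre-cross samples: fixation cross, i.e. elsewhere
    pe[t < cfg.cross_ms] = 1.0

    # baseline per-sample draw for every trial: (P, C, I, T)
    u = rng.random((P, C, I, T))
    pf4 = (1.0 - pe[None, None, None, :]) * phi[:, :, None, :]
    pe4 = np.broadcast_to(pe[None, None, None, :], (P, C, I, T))
    aoi = np.full((P, C, I, T), 2, dtype=np.int8)                     # elsewhere
    aoi[u < pf4] = 0                                                  # factual
    aoi[(u >= pf4) & (u < pf4 + (1.0 - pe4 - pf4))] = 1               # illusory

    # capture trials: exact count per cell, counterbalanced pre-onset locks
    k_cap = int(round(cfg.capture_prob * I))
    is_capture = np.zeros((P, C, I), dtype=bool)
    pre_lock = np.zeros((P, C, I), dtype=np.int8)                     # 0=factual, 1=illusory
    for p in range(P):
        for c in range(C):
            which = rng.permutation(I)[:k_cap]
            is_capture[p, c, which] = True
            locks = np.repeat([0, 1], [(k_cap + 1) // 2, k_cap // 2]).astype(np.int8)
            if k_cap % 2:  # odd cell: the unpaired lock goes to either side at random
                locks[0] = np.int8(rng.random() < 0.5)
            rng.shuffle(locks)
            pre_lock[p, c, which] = locks
    does_relock = rng.random((P, C, I)) < cfg.capture_relock_prob
    post_lock = np.where(does_relock,
                         (rng.random((P, C, I)) >= cfg.capture_post_factual).astype(np.int8),
                         pre_lock)
    relock_t = tau + cfg.capture_relock_delay_ms
    before = anticipation[None, None, None, :] & (t[None, None, None, :] < relock_t[:, :, None, None])
    after = anticipation[None, None, None, :] & ~(t[None, None, None, :] < relock_t[:, :, None, None])
    cap4 = np.broadcast_to(is_capture[:, :, :, None], (P, C, I, T))
    aoi = np.where(cap4 & before, pre_lock[:, :, :, None], aoi)
    aoi = np.where(cap4 & after, post_lock[:, :, :, None], aoi)

    # trial-level disengagement of non-capture trials: anticipation all elsewhere
    disengaged = (rng.random((P, C, I)) < d_p[:, None, None]) & ~is_capture
    aoi = np.where(disengaged[:, :, :, None] & anticipation[None, None, None, :],
                   np.int8(2), aoi)

    correct = rng.random((P, C, I)) < cfg.accuracy

    # assemble long-format samples
    aoi_labels = np.array(["factual", "illusory", "elsewhere"])
    part_col = np.repeat(participants, C * I * T)
    cond_col = np.tile(np.repeat(np.array(conds), I * T), P)
    items = np.array([f"i{j + 1:02d}" for j in range(I)])
    item_col = np.tile(np.repeat(items, T), P * C)
    trial_col = np.char.add(np.char.add(cond_col.astype(str), "-"), item_col.astype(str))
    df = pd.DataFrame({
        "participant": part_col,
        "item": item_col,
        "condition": cond_col,
        "trial": trial_col,
        "t_ms": np.tile(t, P * C * I),
        "aoi": aoi_labels[aoi.ravel()],
        "correct": np.repeat(correct.ravel(), T),
    })
    ts = TrialSet(samples=df, window_config=cfg.window_config(),
                  metadata={"generator": "gazedpa.simulate", "seed": cfg.seed,
                            "sample_interval_ms": cfg.sample_interval_ms})
    gt = GroundTruth(true_onsets=dict(cfg.true_onsets),
                     participant_offsets=pd.Series(delta, index=participants,
                                                   name="delta_ms"))
    return ts, gt


def truth_table(gt: GroundTruth) -> pd.DataFrame:
    """Tidy export of the latent parameters: one row per condition (tau_c)
    and one per participant (delta_p)."""
    rows = [{"kind": "condition", "name": c, "value_ms": float(v)}
            for c, v in sorted(gt.true_onsets.items())]
    rows += [{"kind": "participant", "name": str(p), "value_ms": float(v)}
             for p, v in gt.participant_offsets.items()]
    return pd.DataFrame(rows, columns=["kind", "name", "value_ms"])


__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "truth_table"]
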