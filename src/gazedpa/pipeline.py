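"""End-to-end orchestration: read -> windows -> filter -> bin -> bootstrap ->
contrasts -> summaries, with bit-stable JSON/CSV artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (BootstrapSpec, bootstrap_onsets, difference_distribution)
from .core import (ANALYSIS_CONDITIONS, TrialSet, WindowConfig, assign_windows,
                   bin_fixations, filter_correct)
from .elogit import OnsetRule, condition_bin_tests, detect_onset
from .io import read_trials_with_sidecar
from .summaries import cohens_d, summarize_condition, window_proportions

log = logging.getLogger("gazedpa")


@dataclass
class RunConfig:
    """Configuration of a full divergence-point analysis run.

    Defaults are the field-standard constants: 200-ms bins, k = 3 consecutive
    significant bins at one-sided alpha = 0.05, B = 2000 bootstrap replicates,
    95% intervals.
    """

    input: str | Path
    out_dir: str | Path
    window_config: WindowConfig = field(default_factory=WindowConfig)
    bin_width_ms: int = 200
    rule: OnsetRule = field(default_factory=OnsetRule)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    pairs: tuple = (("negative", "nobody"), ("negative", "positive"), ("nobody", "positive"))
    column_map: dict | None = None
    delimiter: str = ","

    @classmethod
    def from_yaml_dict(cls, doc: dict, input=None, out_dir=None) -> "RunConfig":
        doc = dict(doc or {})
        kwargs: dict = {}
        if "windows" in doc:
            kwargs["window_config"] = WindowConfig.from_dict(doc["windows"])
        if "bin_width_ms" in doc:
            kwargs["bin_width_ms"] = int(doc["bin_width_ms"])
        rule = doc.get("onset_rule", {})
        if rule:
            kwargs["rule"] = OnsetRule(**rule)
        boot = doc.get("bootstrap", {})
        if boot:
            kwargs["bootstrap"] = BootstrapSpec(**boot)
        if "pairs" in doc:
            kwargs["pairs"] = tuple(tuple(p) for p in doc["pairs"])
        for k in ("column_map", "delimiter"):
            if k in doc:
                kwargs[k] = doc[k]
        return cls(input=input if input is not None else doc["input"],
                   out_dir=out_dir if out_dir is not None else doc["out_dir"], **kwargs)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=_json_default,
                               allow_nan=True) + "\n", encoding="utf-8")


def timecourse_table(binned: pd.DataFrame) -> pd.DataFrame:
    """Per condition x bin mean fixation percentages across participants."""
    d = binned[binned["n_total"] > 0].copy()
    d["p_factual"] = 100.0 * d["y_factual"] / d["n_total"]
    d["p_illusory"] = 100.0 * d["y_illusory"] / d["n_total"]
    return (d.groupby(["condition", "bin_start_ms"], sort=True, observed=True)
            [["p_factual", "p_illusory"]].mean().round(6).reset_index())


def run_pipeline(cfg: RunConfig, trials: TrialSet | None = None) -> dict:
    """Execute the full analysis and write results under ``cfg.out_dir``.

    Returns the results document (also written as ``results.json``); sibling
    CSVs hold the per-bin test table, raw bootstrap onset vectors, the
    trial-proportion table for external model fitting, and the binned
    timecourse.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if trials is None:
        log.info("reading %s", cfg.input)
        trials = read_trials_with_sidecar(cfg.input, column_map=cfg.column_map,
                                          delimiter=cfg.delimiter)
        if cfg.window_config is not None:
            trials.window_config = cfg.window_config
    log.info("input: %d samples, %d trials", trials.n_samples, trials.n_trials)

    ts = assign_windows(trials)
    ts, accuracy = filter_correct(ts)
    log.info("after correctness filter: %d trials", ts.n_trials)

    binned = bin_fixations(ts, window=ts.window_config.anticipation,
                           bin_width_ms=cfg.bin_width_ms)
    present = [c for c in ANALYSIS_CONDITIONS if c in set(binned["condition"])]
    dropped = [c for c in ANALYSIS_CONDITIONS if c not in present]
    for c in dropped:
        log.warning("condition %r has no data after filtering and is dropped", c)

    # point estimates on the observed data
    point_onsets = {}
    bin_rows = []
    for cond in present:
        tests = condition_bin_tests(binned, cond, cfg.rule)
        res = detect_onset(tests, cfg.rule, condition=cond)
        point_onsets[cond] = res.onset_ms
        for bt in tests:
            bin_rows.append({"condition": cond, "bin_start_ms": bt.bin_start_ms,
                             "coefficient": bt.coefficient, "t_value": bt.t_value,
                             "p_value": bt.p_value, "significant": bt.significant,
                             "n_participants": bt.n_participants})
    pd.DataFrame(bin_rows).to_csv(out / "bin_tests.csv", index=False, float_format="%.10g")

    dists = bootstrap_onsets(binned, cfg.rule, cfg.bootstrap, conditions=present)
    onset_rows = []
    for cond, d in dists.items():
        onset_rows += [{"condition": cond, "replicate": i, "onset_ms": v}
                       for i, v in enumerate(d.replicate_onsets)]
    pd.DataFrame(onset_rows).to_csv(out / "bootstrap_onsets.csv", index=False,
                                    float_format="%.10g")

    diffs = {}
    for a, b in cfg.pairs:
        if a in dists and b in dists:
            dd = difference_distribution(dists[a], dists[b], cfg.bootstrap)
            diffs[f"{a}_vs_{b}"] = dd

    props = window_proportions(ts, "anticipation")
    props.to_csv(out / "trial_proportions.csv", index=False, float_format="%.10g")
    summ = summarize_condition(props)
    effects = {}
    for cond in present:
        row_f = summ[(summ["condition"] == cond) & (summ["aoi"] == "factual")]
        row_i = summ[(summ["condition"] == cond) & (summ["aoi"] == "illusory")]
        if len(row_f) and len(row_i) and not row_f["sd"].isna().all():
            es = cohens_d(float(row_f["mean"].iloc[0]), float(row_f["sd"].iloc[0]),
                          float(row_i["mean"].iloc[0]), float(row_i["sd"].iloc[0]))
            effects[cond] = {"d": round(es.d, 6), "m_factual": round(es.m1, 6),
                             "sd_factual": round(es.s1, 6), "m_illusory": round(es.m2, 6),
                             "sd_illusory": round(es.s2, 6)}

    timecourse = timecourse_table(binned)
    timecourse.to_csv(out / "timecourse.csv", index=False, float_format="%.10g")

    results = {
        "version": __version__,
        "config": {
            "bin_width_ms": cfg.bin_width_ms,
            "onset_rule": {"k": cfg.rule.k, "alpha": cfg.rule.alpha, "tails": cfg.rule.tails},
            "bootstrap": {"B": cfg.bootstrap.B, "level": cfg.bootstrap.level,
                          "seed": cfg.bootstrap.seed,
                          "missing_onset_policy": cfg.bootstrap.missing_onset_policy},
            "windows": (trials.window_config.to_dict()),
        },
        "counts": {"n_samples": trials.n_samples, "n_trials_input": trials.n_trials,
                   "n_trials_correct": ts.n_trials},
        "accuracy": {s.condition: {"mean_percent_correct": round(s.mean_percent_correct, 6),
                                   "sd_percent": (None if np.isnan(s.sd_percent)
                                                  else round(s.sd_percent, 6)),
                                   "n_participants": s.n_participants}
                     for s in accuracy},
        "dropped_conditions": dropped,
        "point_onsets_ms": point_onsets,
        "divergence_points": {
            cond: {"mean_ms": round(d.mean_ms, 6),
                   "percentile_ci": [round(x, 6) for x in d.percentile_ci],
                   "hdi": [round(x, 6) for x in d.hdi],
                   "n_missing": d.n_missing, "B": d.B, "seed": d.seed}
            for cond, d in dists.items()},
        "differences": {
            key: {"mean_ms": round(dd.mean_ms, 6),
                  "percentile_ci": [round(x, 6) for x in dd.percentile_ci],
                  "significant": dd.significant, "n_dropped": dd.n_dropped}
            for key, dd in diffs.items()},
        "effect_sizes_anticipation": effects,
    }
    _dump_json(results, out / "results.json")
    log.info("results written to %s", out / "results.json")
    return results


def render_report(results_dir) -> str:
    """Plain-text/markdown summary of a results directory."""
    out = Path(results_dir)
    doc = json.loads((out / "results.json").read_text(encoding="utf-8"))
    lines = [f"# Divergence-point analysis report", "",
             f"gazedpa {doc['version']}; B = {doc['config']['bootstrap']['B']}, "
             f"seed = {doc['config']['bootstrap']['seed']}, "
             f"bins = {doc['config']['bin_width_ms']} ms, "
             f"rule: k = {doc['config']['onset_rule']['k']}, "
             f"alpha = {doc['config']['onset_rule']['alpha']} "
             f"({doc['config']['onset_rule']['tails']}-sided)", ""]
    lines += ["## Response accuracy", "",
              "| condition | mean % correct | SD | n |", "|---|---|---|---|"]
    for cond, a in sorted(doc["accuracy"].items()):
        sd = "-" if a["sd_percent"] is None else f"{a['sd_percent']:.2f}"
        lines.append(f"| {cond} | {a['mean_percent_correct']:.2f} | {sd} | "
                     f"{a['n_participants']} |")
    lines += ["", "## Divergence points", "",
              "| condition | mean DP (ms) | 95% CI | 95% HDI | missing |",
              "|---|---|---|---|---|"]
    for cond, d in sorted(doc["divergence_points"].items()):
        lines.append(f"| {cond} | {d['mean_ms']:.0f} | "
                     f"{d['percentile_ci'][0]:.0f}-{d['percentile_ci'][1]:.0f} | "
                     f"{d['hdi'][0]:.0f}-{d['hdi'][1]:.0f} | {d['n_missing']}/{d['B']} |")
    lines += ["", "## Onset differences", "",
              "| contrast | mean (ms) | 95% CI | significant |", "|---|---|---|---|"]
    for key, d in sorted(doc["differences"].items()):
        lines.append(f"| {key} | {d['mean_ms']:.0f} | "
                     f"{d['percentile_ci'][0]:.0f} to {d['percentile_ci'][1]:.0f} | "
                     f"{'yes' if d['significant'] else 'no'} |")
    if doc.get("effect_sizes_anticipation"):
        lines += ["", "## Anticipation-window effect sizes (factual vs illusory)", "",
                  "| condition | d | M fact | SD fact | M illus | SD illus |",
                  "|---|---|---|---|---|---|"]
        for cond, e in sorted(doc["effect_sizes_anticipation"].items()):
            lines.append(f"| {cond} | {e['d']:.2f} | {e['m_factual']:.2f} | "
                         f"{e['sd_factual']:.2f} | {e['m_illusory']:.2f} | "
                         f"{e['sd_illusory']:.2f} |")
    tc = out / "timecourse.csv"
    if tc.exists():
        t = pd.read_csv(tc)
        lines += ["", "## Binned timecourse (mean % fixations across participants)", "",
                  "| condition | bin (ms) | factual | illusory |", "|---|---|---|---|"]
        for _, r in t.iterrows():
            lines.append(f"| {r['condition']} | {int(r['bin_start_ms'])} | "
                         f"{r['p_factual']:.1f} | {r['p_illusory']:.1f} |")
    return "\n".join(lines) + "\n"


__all__ = ["RunConfig", "run_pipeline", "render_report", "timecourse_table"]
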