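"""Experiment driver: run replicates, write tables, compare schemes.

An experiment directory contains a reproducibility manifest (all resolved
parameters plus per-replicate child seeds), per-replicate frequency and
summary CSVs, replicate-averaged trajectories with their analytic
expectations, per-replicate regression slopes, and (optionally) trajectory
plots of observed versus expected frequency per locus.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    compare_slopes,
    expected_frequency_lethal,
    expected_frequency_neutral,
    frequency_slope,
)
from .lifecycle import ReplicateResult, replicate_seeds, run_replicates
from .scenarios import Scenario, save_scenario_config

__all__ = ["run_experiment", "compare_schemes", "expected_series_frame"]

log = logging.getLogger("herdmate")


def expected_series_frame(scenario: Scenario) -> pd.DataFrame:
    """Analytic expected trajectory per locus (lethal recursion or HW)."""
    rows = []
    for locus in scenario.loci:
        series = (
            expected_frequency_lethal(locus.maf, scenario.years)
            if locus.lethal
            else expected_frequency_neutral(locus.maf, scenario.years)
        )
        for year, freq in enumerate(series.values):
            rows.append({"year": year, "locus": locus.name, "frequency": freq})
    return pd.DataFrame(rows)


def _slope_frame(scenario: Scenario, results: list[ReplicateResult]) -> pd.DataFrame:
    rows = []
    for r, result in enumerate(results):
        freq = result.frequency_frame()
        for locus in scenario.locus_names:
            y = freq.loc[freq["locus"] == locus].sort_values("year")["frequency"].to_numpy()
            b0, b1, _ = frequency_slope(y)
            rows.append({"replicate": r, "locus": locus, "intercept": b0, "slope": b1})
    return pd.DataFrame(rows)


def run_experiment(
    scenario: Scenario,
    out_dir: str | Path,
    plots: bool = False,
    keep_final_plan: bool = False,
) -> Path:
    """Run all replicates of ``scenario`` and write the experiment directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = replicate_seeds(scenario.seed, scenario.replicates)
    manifest = {
        "package": "herdmate",
        "version": __version__,
        "scenario": _scenario_doc(scenario),
        "master_seed": scenario.seed,
        "replicate_seeds": seeds,
        "started": _now(),
        "finished": None,
        "outputs": [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_scenario_config(scenario, out / "scenario.yaml")

    def progress(summary):
        log.info(
            "year %d: %d bulls, %d cows live; %d matings, %d embryo deaths",
            summary.year, summary.n_bulls, summary.n_cows,
            summary.n_matings, summary.n_embryo_deaths,
        )

    results = run_replicates(scenario, keep_final_plan=keep_final_plan, progress=progress)

    outputs = ["manifest.json", "scenario.yaml"]
    all_freq = []
    for r, result in enumerate(results):
        rep_dir = out / f"replicate_{r}"
        rep_dir.mkdir(exist_ok=True)
        freq = result.frequency_frame()
        freq.to_csv(rep_dir / "frequencies.csv", index=False)
        result.summary_frame().to_csv(rep_dir / "summary.csv", index=False)
        outputs += [f"replicate_{r}/frequencies.csv", f"replicate_{r}/summary.csv"]
        if result.final_plan is not None:
            result.final_plan.write_csv(rep_dir / "final_matings.csv")
            outputs.append(f"replicate_{r}/final_matings.csv")
        all_freq.append(freq.assign(replicate=r))

    freq_all = pd.concat(all_freq, ignore_index=True)
    mean_freq = (
        freq_all.groupby(["year", "locus"], as_index=False)["frequency"].mean()
    )
    mean_freq.to_csv(out / "frequencies.csv", index=False)
    expected = expected_series_frame(scenario)
    expected.to_csv(out / "expected_frequencies.csv", index=False)
    slopes = _slope_frame(scenario, results)
    slopes.to_csv(out / "slopes.csv", index=False)
    outputs += ["frequencies.csv", "expected_frequencies.csv", "slopes.csv"]

    if plots:
        outputs += _plot_trajectories(scenario, mean_freq, expected, out / "plots")

    manifest["finished"] = _now()
    manifest["outputs"] = outputs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _plot_trajectories(scenario, mean_freq, expected, plot_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(exist_ok=True)
    written = []
    for locus in scenario.locus_names:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        obs = mean_freq.loc[mean_freq["locus"] == locus].sort_values("year")
        exp = expected.loc[expected["locus"] == locus].sort_values("year")
        ax.plot(obs["year"], obs["frequency"], "o-", label="observed (mean)")
        ax.plot(exp["year"], exp["frequency"], "--", label="expected")
        ax.set_xlabel("year")
        ax.set_ylabel("minor-allele frequency")
        ax.set_title(f"{locus} — {scenario.scheme}")
        ax.legend()
        fig.tight_layout()
        safe = locus.replace(" ", "_").replace("/", "_")
        fig.savefig(plot_dir / f"{safe}.png", dpi=100)
        plt.close(fig)
        written.append(f"plots/{safe}.png")
    return written


def compare_schemes(
    run_dirs: list[str | Path], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-locus slope comparisons between completed experiment directories.

    For every pair of runs and every locus, the replicate slope samples are
    compared with a Welch t test; within each run, observed slopes are also
    compared against the (deterministic) expected-trajectory slope. The
    Bonferroni family is all comparisons in this call.
    """
    if len(run_dirs) < 2:
        raise ValueError("need at least 2 run directories")
    runs = []
    for d in run_dirs:
        d = Path(d)
        manifest = json.loads((d / "manifest.json").read_text())
        slopes = pd.read_csv(d / "slopes.csv")
        expected = pd.read_csv(d / "expected_frequencies.csv")
        runs.append((d, manifest, slopes, expected))

    loci0 = sorted(runs[0][2]["locus"].unique())
    for d, _, slopes, _ in runs[1:]:
        if sorted(slopes["locus"].unique()) != loci0:
            raise ValueError(f"locus sets differ between {runs[0][0]} and {d}")

    comparisons = []
    # observed vs expected within each run
    for d, manifest, slopes, expected in runs:
        scheme = manifest["scenario"]["scheme"]
        for locus in loci0:
            obs = slopes.loc[slopes["locus"] == locus, "slope"].to_numpy()
            exp_y = (
                expected.loc[expected["locus"] == locus]
                .sort_values("year")["frequency"].to_numpy()
            )
            _, exp_slope, _ = frequency_slope(exp_y)
            comparisons.append(
                (f"{scheme}:observed", f"{scheme}:expected", locus,
                 obs, np.full(len(obs), exp_slope))
            )
    # observed vs observed across runs
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            si = runs[i][1]["scenario"]["scheme"]
            sj = runs[j][1]["scenario"]["scheme"]
            for locus in loci0:
                a = runs[i][2].loc[runs[i][2]["locus"] == locus, "slope"].to_numpy()
                b = runs[j][2].loc[runs[j][2]["locus"] == locus, "slope"].to_numpy()
                comparisons.append((f"{si}:observed", f"{sj}:observed", locus, a, b))

    m = len(comparisons)
    rows = []
    for name_a, name_b, locus, a, b in comparisons:
        c = compare_slopes(a, b, n_comparisons=m)
        rows.append(
            {
                "group_a": name_a,
                "group_b": name_b,
                "locus": locus,
                "slope_a": c.mean_a,
                "slope_b": c.mean_b,
                "t": c.t,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_bonferroni": c.p_bonferroni,
                "significant": c.p_bonferroni < alpha,
            }
        )
    return pd.DataFrame(rows)


def _scenario_doc(scenario: Scenario) -> dict:
    doc = dataclasses.asdict(scenario)
    doc["loci"] = [dataclasses.asdict(loc) for loc in scenario.loci]
    return doc


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
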