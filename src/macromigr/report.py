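"""Superplot aggregation, group comparisons and pipeline orchestration.

Per-cell values are tagged with a condition and an experimental run.
Superplot summaries report the mean ± SEM of every run and the grand
mean of run means per condition; hypothesis tests are run on the pooled
per-cell values (matching how n is reported for track/cell metrics, with
the usual pseudo-replication caveat — run-level summaries are shown
alongside). Available designs: Kruskal–Wallis with Dunn's multiple
comparisons (used when normality cannot be assumed, >= 2 groups),
Mann–Whitney (two groups, non-parametric), Welch's unpaired t test and
one-way ANOVA (normal data).

Dunn's post-hoc test is computed from the pooled mid-ranks with the
standard tie correction:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1))

with two-sided normal p-values, Holm-adjusted by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "SuperplotSummary",
    "ComparisonResult",
    "summarize_superplot",
    "dunn_test",
    "compare_groups",
    "superplot_figure",
    "run_pipeline",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("value", "condition", "run", "cell_id", "metric")


@dataclass
class GroupedMeasurements:
    """Tidy per-cell measurements tagged by condition, run and metric."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("no measurements")

    @classmethod
    def from_records(cls, records) -> "GroupedMeasurements":
        return cls(pd.DataFrame(records, columns=list(REQUIRED_COLUMNS)))

    def select(self, metric: str) -> "GroupedMeasurements":
        sub = self.data[self.data["metric"] == metric]
        if len(sub) == 0:
            raise ValueError(f"no measurements for metric {metric!r}")
        return GroupedMeasurements(sub.reset_index(drop=True))

    def metrics(self) -> list[str]:
        return sorted(self.data["metric"].unique())

    def groups(self, metric: str | None = None) -> dict[str, np.ndarray]:
        """Pooled values per condition (across runs)."""
        df = self.select(metric).data if metric else self.data
        return {
            str(cond): grp["value"].to_numpy(dtype=float)
            for cond, grp in df.groupby("condition", sort=True)
        }


@dataclass
class SuperplotSummary:
    """Per-run means ± SEM and per-condition grand means (of run means)."""

    runs: pd.DataFrame        # condition, run, mean, sem, n
    conditions: pd.DataFrame  # condition, grand_mean, n_runs, n_cells


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    group_ns: dict
    pairwise: pd.DataFrame | None = None  # symmetric adjusted-p matrix
    adjust: str | None = None


def summarize_superplot(data: GroupedMeasurements, metric: str | None = None) -> SuperplotSummary:
    """Superplot summary: run means ± SEM, condition grand means.

    SEM = sd / sqrt(n) with n = cells in that run (sample sd, ddof=1);
    a run with a single cell reports SEM as missing. The condition grand
    mean is the mean of its run means, not the pooled per-cell mean.
    """
    df = data.select(metric).data if metric else data.data
    rows = []
    for (cond, run), grp in df.groupby(["condition", "run"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else float("nan")
        rows.append((cond, run, float(v.mean()), sem, len(v)))
    runs = pd.DataFrame(rows, columns=["condition", "run", "mean", "sem", "n"])
    conds = (
        runs.groupby("condition", sort=True)
        .agg(grand_mean=("mean", "mean"), n_runs=("run", "count"), n_cells=("n", "sum"))
        .reset_index()
    )
    return SuperplotSummary(runs=runs, conditions=conds)


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise post-hoc z-test on pooled mid-ranks.

    Returns a symmetric matrix of two-sided p-values, adjusted across
    all pairs by ``adjust`` ('holm', 'bonferroni' or 'none').
    """
    names = sorted(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie

    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        r = ranks[start : start + len(v)]
        mean_ranks[name] = r.mean()
        sizes[name] = len(v)
        start += len(v)

    pairs = list(combinations(names, 2))
    pvals = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pvals.append(2.0 * sps.norm.sf(abs(z)))
    pvals = _adjust_pvalues(np.array(pvals), adjust)

    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, pvals):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return np.minimum(p, 1.0)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "holm":
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment: {method!r}")


DESIGNS = ("kruskal_dunn", "mann_whitney", "welch_t", "anova")


def compare_groups(
    data: GroupedMeasurements | dict,
    design: str,
    metric: str | None = None,
    adjust: str = "holm",
) -> ComparisonResult:
    """Run the named statistical comparison on per-cell values.

    ``design`` is one of ``kruskal_dunn`` (Kruskal–Wallis omnibus plus
    Dunn pairwise p-values), ``mann_whitney`` (two-sided, two groups),
    ``welch_t`` (unpaired t with Welch correction) or ``anova``
    (one-way). Tests are delegated to scipy; only Dunn's post-hoc is
    computed here.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    groups = data.groups(metric) if isinstance(data, GroupedMeasurements) else {
        str(k): np.asarray(v, dtype=float) for k, v in data.items()
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    values = [groups[k] for k in sorted(groups)]
    ns = {k: len(groups[k]) for k in sorted(groups)}

    if design in ("mann_whitney", "welch_t") and len(groups) != 2:
        raise ValueError(f"{design} requires exactly 2 groups")

    pairwise = None
    if design == "kruskal_dunn":
        stat, p = sps.kruskal(*values)
        pairwise = dunn_test(groups, adjust=adjust)
    elif design == "mann_whitney":
        # two-sided with the normal approximation and tie correction, so
        # identical groups report p ~= 1
        res = sps.mannwhitneyu(values[0], values[1], alternative="two-sided",
                               method="asymptotic")
        stat, p = res.statistic, res.pvalue
    elif design == "welch_t":
        stat, p = sps.ttest_ind(values[0], values[1], equal_var=False)
    else:  # anova
        stat, p = sps.f_oneway(*values)
    return ComparisonResult(
        test=design, statistic=float(stat), pvalue=float(p),
        group_ns=ns, pairwise=pairwise, adjust=adjust if pairwise is not None else None,
    )


def superplot_figure(data: GroupedMeasurements, metric: str, ax=None):
    """Basic superplot: all per-cell values, color-coded by run, with
    per-run mean ± SEM overlaid in black."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    df = data.select(metric).data
    conditions = sorted(df["condition"].unique())
    runs = sorted(df["run"].unique())
    cmap = plt.get_cmap("tab10")
    rng = np.random.default_rng(0)
    for ci, cond in enumerate(conditions):
        for ri, run in enumerate(runs):
            v = df[(df["condition"] == cond) & (df["run"] == run)]["value"]
            if len(v) == 0:
                continue
            jitter = rng.uniform(-0.18, 0.18, len(v))
            ax.scatter(ci + jitter, v, s=8, alpha=0.5, color=cmap(ri % 10))
            sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) >= 2 else 0.0
            ax.errorbar(ci + (ri - len(runs) / 2) * 0.06, v.mean(), yerr=sem,
                        fmt="o", color="black", ms=5, capsize=2)
    ax.set_xticks(range(len(conditions)), conditions)
    ax.set_ylabel(metric)
    return ax


# ---------------------------------------------------------------------------
# pipeline

DEMO_CONFIG = {
    "seed": 0,
    "calibration": {"microns_per_pixel": 1.0, "minutes_per_frame": 10.0},
    "conditions": [
        {"name": "FN", "preset": "fn_like", "n_runs": 3, "n_cells": 20},
        {"name": "LAM", "preset": "lam_like", "n_runs": 3, "n_cells": 20},
    ],
    "n_frames": 97,
    "shape": {"window_frames": 31, "slingshot_threshold": 0.4},
    "comparisons": [
        {"metric": "mean_speed_um_min", "test": "mann_whitney"},
        {"metric": "persistence", "test": "mann_whitney"},
        {"metric": "mean_shape_change", "test": "mann_whitney"},
        {"metric": "slingshot_count", "test": "mann_whitney"},
    ],
}


def run_pipeline(config, outdir=None):
    """Run the simulate/load → metrics → shape → stats pipeline.

    ``config`` is a dict or a path to a YAML file. Each condition either
    names a simulator preset (``fn_like``/``lam_like``) with ``n_runs``
    and ``n_cells``, or lists per-run track CSV paths under ``tracks``.
    Writes metrics.csv, dynamics.csv, summary.csv, stats.json and
    manifest.json to ``outdir`` when given; deterministic for a fixed
    config (seeds derived from the config seed). Returns a result bundle
    dict.
    """
    from . import __version__, morpho, motility, simkit
    from .core import Calibration
    from . import trackio

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    try:
        cal = Calibration(**config.get("calibration", {}))
        conditions = config["conditions"]
        seed = int(config.get("seed", 0))
        n_frames = int(config.get("n_frames", 97))
        shape_cfg = config.get("shape", {})
        window = int(shape_cfg.get("window_frames", morpho.DEFAULT_WINDOW_FRAMES))
        threshold = float(shape_cfg.get("slingshot_threshold", morpho.SLINGSHOT_THRESHOLD))
        comparisons = config.get("comparisons", [])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    presets = {"fn_like": simkit.FN_LIKE, "lam_like": simkit.LAM_LIKE}
    records = []
    counts = {}
    for ci, cond in enumerate(conditions):
        name = cond["name"]
        if "preset" in cond:
            mode = presets.get(cond["preset"])
            if mode is None:
                raise ConfigError(f"unknown preset {cond['preset']!r}")
            run_data = []
            for run in range(int(cond.get("n_runs", 1))):
                params = simkit.SimParams(
                    n_cells=int(cond.get("n_cells", 20)),
                    n_frames=n_frames,
                    calibration=cal,
                    mode=mode,
                    seed=seed + 1000 * ci + run,
                )
                truth = simkit.simulate_tracks(params)
                run_data.append((f"run{run}", truth.tracks, truth.shapes))
        elif "tracks" in cond:
            run_data = []
            for run, path in enumerate(cond["tracks"]):
                if not Path(path).exists():
                    raise InputError(f"track file not found: {path}")
                run_data.append((f"run{run}", trackio.read_tracks(path, cal), None))
        else:
            raise ConfigError(f"condition {name!r} needs 'preset' or 'tracks'")

        n_tracks = 0
        for run_name, tracks, shapes in run_data:
            n_tracks += len(tracks)
            for t in tracks:
                m = motility.track_metrics(t)
                records.append((m.mean_speed_um_min, name, run_name, t.track_id,
                                "mean_speed_um_min"))
                records.append((m.persistence, name, run_name, t.track_id,
                                "persistence"))
            if shapes is not None:
                for s in shapes:
                    s.window_frames = window
                    dyn = morpho.shape_change(s, threshold=threshold)
                    records.append((dyn.mean_shape_change, name, run_name,
                                    s.cell_id, "mean_shape_change"))
                    records.append((dyn.slingshot_count, name, run_name,
                                    s.cell_id, "slingshot_count"))
        counts[name] = n_tracks
        log.info("condition %s: %d tracks", name, n_tracks)

    data = GroupedMeasurements.from_records(records)
    summaries = {m: summarize_superplot(data, m) for m in data.metrics()}
    stats_out = {}
    for comp in comparisons:
        metric, test = comp["metric"], comp.get("test", "mann_whitney")
        res = compare_groups(data, test, metric=metric)
        stats_out[metric] = {
            "test": res.test, "statistic": res.statistic, "p": res.pvalue,
            "group_ns": res.group_ns,
            "pairwise": None if res.pairwise is None else res.pairwise.to_dict(),
            "adjust": res.adjust,
        }

    bundle = {
        "measurements": data,
        "summaries": summaries,
        "stats": stats_out,
        "counts": counts,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        data.data.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
        pd.concat(
            [s.runs.assign(metric=m) for m, s in summaries.items()]
        ).to_csv(outdir / "summary.csv", index=False, float_format="%.6f")
        dyn = data.data[data.data["metric"].isin(["mean_shape_change", "slingshot_count"])]
        dyn.to_csv(outdir / "dynamics.csv", index=False, float_format="%.6f")
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True)
        manifest = {
            "package": "macromigr", "version": __version__,
            "seed": seed, "n_frames": n_frames,
            "calibration": {"microns_per_pixel": cal.microns_per_pixel,
                            "minutes_per_frame": cal.minutes_per_frame},
            "window_frames": window, "slingshot_threshold": threshold,
            "conditions": {c["name"]: counts.get(c["name"], 0) for c in conditions},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class InputError(FileNotFoundError):
    """Missing pipeline input (CLI exit code 3)."""
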