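"""File formats: tap logs, lag-pattern tables, cluster and fit artifacts.

All tabular outputs are CSV with headers; all metadata is JSON.  A tap log
is the raw exchange format for empirical or synthetic tapping data: one row
per tap with columns ``dyad_id``, ``member`` (1 or 2) and ``tap_time_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterResult, PatternSet
from .fitting import FitResult, TargetPattern
from .taps import ITISeries, InsufficientEventsError, TapSeries, lagged_crosscorr

TAP_LOG_COLUMNS = ["dyad_id", "member", "tap_time_s"]


def save_tap_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_tap_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TAP_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tap log missing columns: {missing}")
    return df


def target_from_tap_log(df: pd.DataFrame, label: str = "empirical") -> TargetPattern:
    """One lag-pattern sample per dyad, computed from its two tap series."""
    samples = []
    for dyad_id, group in df.groupby("dyad_id"):
        series = []
        for member in (1, 2):
            taps = np.sort(group.loc[group["member"] == member, "tap_time_s"].to_numpy())
            if taps.size < 4:
                raise InsufficientEventsError(
                    f"dyad {dyad_id} member {member}: too few taps"
                )
            series.append(ITISeries(member, np.diff(taps)))
        pattern = lagged_crosscorr(series[0], series[1])
        if pattern.is_defined:
            samples.append(pattern.as_array())
    if not samples:
        raise ValueError("no dyad yielded a defined lag pattern")
    return TargetPattern(label=label, samples=np.array(samples))


def save_target(target: TargetPattern, path) -> None:
    Path(path).write_text(json.dumps(target.to_dict(), indent=2))


def load_target(path) -> TargetPattern:
    return TargetPattern.from_dict(json.loads(Path(path).read_text()))


def save_tap_series(series: TapSeries, path, dyad_id: int = 1) -> None:
    pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "unit": series.unit_id,
            "tap_time_s": series.tap_times,
        }
    ).to_csv(path, index=False)


def save_iti_series(series: ITISeries, path, dyad_id: int = 1) -> None:
    pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "unit": series.unit_id,
            "interval_s": series.intervals,
        }
    ).to_csv(path, index=False)


def pattern_table(patterns: PatternSet, n_trials: int, condition: str = "") -> pd.DataFrame:
    """Lag-pattern table with one row per coupling combination."""
    rows = []
    for label, row in zip(patterns.labels, patterns.patterns):
        rows.append(
            {
                "label": str(label),
                "r_minus1": row[0],
                "r_0": row[1],
                "r_plus1": row[2],
                "n_trials": n_trials,
                "condition": condition,
            }
        )
    return pd.DataFrame(rows)


def save_cluster_result(
    result: ClusterResult, patterns: PatternSet, outdir, prefix: str = "clusters"
) -> None:
    """CSV partition (label, weights, cluster id) plus a JSON summary."""
    outdir = Path(outdir)
    rows = []
    for label, pat, cid in zip(patterns.labels, patterns.patterns, result.assignments):
        row = {"label": str(label)}
        if isinstance(label, tuple):
            names = ["i1", "e1", "i2", "e2"] if len(label) == 4 else ["e1", "e2"]
            row.update(dict(zip(names, label)))
        row.update(
            {
                "r_minus1": pat[0],
                "r_0": pat[1],
                "r_plus1": pat[2],
                "cluster": int(cid),
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / f"{prefix}_partition.csv", index=False)
    summary = {
        "n_significant": result.n_significant,
        "alpha": result.alpha,
        "n_permutations": list(result.n_permutations),
        "cluster_sizes": None
        if result.cluster_sizes is None
        else result.cluster_sizes.tolist(),
        "cluster_means": None
        if result.cluster_means is None
        else result.cluster_means.tolist(),
    }
    (outdir / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
    np.savetxt(
        outdir / f"{prefix}_linkage.csv",
        result.linkage,
        delimiter=",",
        header="left,right,height,count",
        comments="",
    )


def save_fit_result(result: FitResult, outdir, prefix: str = "fit") -> None:
    outdir = Path(outdir)
    (outdir / f"{prefix}.json").write_text(result.to_json(indent=2))
    if result.coarse_ranking is not None:
        result.coarse_ranking.to_csv(outdir / f"{prefix}_coarse_ranking.csv", index=False)
    if result.refine_ranking is not None:
        result.refine_ranking.to_csv(outdir / f"{prefix}_refine_ranking.csv", index=False)
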