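"""Aggregate per-vacuole results into summary tables, plots and statistics.

Consumes the CSVs written by earlier pipeline stages (``classes.csv``,
``fits.csv``, ``ci.csv``) from a run directory and produces a report bundle:
class-distribution percentages, half-time comparisons with letter groups,
CI comparisons, simple figures, and one machine-readable JSON holding every
statistic.  QC-flagged CI values and non-converged fits are excluded from
the statistics (their counts are reported), matching the rule that
non-recovering vacuoles enter class percentages but not half-time summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as fstats
from .connectivity import MOBILE_FRACTION_MIN

__all__ = ["report", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "ci_cutoff": 0.1,
    "denominator": "pre_frame",
    "equal_var": True,
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the defaults (missing file -> defaults)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None and Path(path).exists():
        import yaml

        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update(user)
    return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report(
    run_dir: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    config: dict | None = None,
    make_plots: bool = True,
) -> dict:
    """Build the report bundle for one run directory.

    Expects ``classes.csv`` (series_id, group, t_half_s, mobile_fraction,
    class) and optionally ``ci.csv`` (series_id, group, ..., ci, qc_flag).
    Writes ``class_percentages.csv``, ``stats.json`` and PNG figures into
    ``out_dir`` and returns the statistics dict.  Output is deterministic
    given identical inputs.
    """
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    cfg["alpha"] = alpha

    classes_path = run_dir / "classes.csv"
    if not classes_path.exists():
        raise FileNotFoundError(
            f"missing classes.csv in {run_dir} (classification stage not run)"
        )
    classes = pd.read_csv(classes_path)
    results: dict = {"config": cfg, "excluded": {}}

    # --- class distributions -------------------------------------------
    grouped_classes = {
        str(g): list(sub["class"]) for g, sub in classes.groupby("group", sort=True)
    }
    pct = fstats.summarize_classes(grouped_classes)
    pct.to_csv(out_dir / "class_percentages.csv", index_label="group")
    results["class_percentages"] = {
        g: {k: float(v) for k, v in row.items()} for g, row in pct.iterrows()
    }

    # --- half-time comparisons (recovering vacuoles only) ---------------
    recovering = classes[
        (classes["class"] != "no_recovery")
        & classes["t_half_s"].notna()
        & (classes["mobile_fraction"] >= MOBILE_FRACTION_MIN)
    ]
    results["excluded"]["non_recovering_from_t_half"] = int(
        len(classes) - len(recovering)
    )
    t_groups = {
        str(g): list(sub["t_half_s"])
        for g, sub in recovering.groupby("group", sort=True)
        if len(sub) >= 3
    }
    if len(t_groups) >= 2:
        rs = fstats.ranksum_compare(t_groups, alpha=cfg["alpha"])
        results["t_half"] = {
            "groups": {
                g: {"n": len(v), "median_s": float(np.median(v))}
                for g, v in t_groups.items()
            },
            "ranksum_p": {
                a: {b: float(rs.p_values.loc[a, b]) for b in rs.p_values.columns}
                for a in rs.p_values.index
            },
            "letters": rs.letters,
        }

    # --- connectivity-index comparisons ---------------------------------
    ci_path = run_dir / "ci.csv"
    if ci_path.exists():
        ci = pd.read_csv(ci_path)
        ok = ci[ci["qc_flag"] == "ok"]
        results["excluded"]["qc_flagged_ci"] = int(len(ci) - len(ok))
        ci_groups = {
            str(g): list(sub["ci"]) for g, sub in ok.groupby("group", sort=True)
            if len(sub) >= 2
        }
        if len(ci_groups) >= 2:
            tt = fstats.ttest_compare(ci_groups, equal_var=cfg["equal_var"])
            results["ci"] = {
                "groups": {
                    g: {
                        "n": len(v),
                        "mean": float(np.mean(v)),
                        "fraction_above_cutoff": float(
                            np.mean(np.asarray(v) >= cfg["ci_cutoff"])
                        ),
                    }
                    for g, v in ci_groups.items()
                },
                "ttest_p": {
                    a: {b: float(tt.p_values.loc[a, b]) for b in tt.p_values.columns}
                    for a in tt.p_values.index
                },
                "cutoff": cfg["ci_cutoff"],
            }
    else:
        ci = None

    if make_plots:
        _plots(pct, recovering, ci, out_dir, cfg)

    payload = _round_floats(results)
    (out_dir / "stats.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return payload


def _plots(pct: pd.DataFrame, recovering: pd.DataFrame, ci, out_dir: Path, cfg: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    pct[fstats.CLASS_ORDER].plot.bar(stacked=True, ax=ax, width=0.7)
    ax.set_ylabel("% of vacuoles")
    ax.set_title("Fluorescence recovery classes")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "class_distribution.png", dpi=120)
    plt.close(fig)

    if len(recovering):
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(recovering["group"].unique())
        data = [recovering.loc[recovering["group"] == g, "t_half_s"] for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_ylabel("recovery half-time $t_{1/2}$ (s)")
        fig.tight_layout()
        fig.savefig(out_dir / "t_half_boxplot.png", dpi=120)
        plt.close(fig)

    if ci is not None and len(ci):
        ok = ci[ci["qc_flag"] == "ok"]
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(ok["group"].unique())
        rng = np.random.default_rng(0)  # jitter for display only
        for i, g in enumerate(groups):
            vals = ok.loc[ok["group"] == g, "ci"].to_numpy()
            ax.scatter(
                np.full(len(vals), i) + rng.uniform(-0.12, 0.12, len(vals)),
                vals,
                s=14,
                alpha=0.7,
            )
        ax.axhline(cfg["ci_cutoff"], color="red", ls="--", lw=1, label="cut-off")
        ax.set_xticks(range(len(groups)), groups)
        ax.set_ylabel("connectivity index")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "ci_strip.png", dpi=120)
        plt.close(fig)
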