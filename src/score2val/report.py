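"""Study-style outputs: forest plot, calibration plots, C table, flowchart.

Renders a :class:`~score2val.subgroups.SubgroupReport` into files:
a forest plot of OE-ratios by stratum and region model (log axis,
reference line at 1), calibration plots with their LOESS smooths,
a discrimination table by subgroup, a flowchart report and a run
manifest. Every plotted value also lands in a companion CSV, written
deterministically (fixed row order, fixed float format) so re-renders
of the same results are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from score2val import __version__

__all__ = ["RunManifest", "render"]


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int | None
    package_version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    timestamp: str = ""

    @staticmethod
    def create(config_obj, seed: int | None, inputs: dict[str, Path] | None = None):
        blob = json.dumps(repr(config_obj), sort_keys=True).encode()
        checksums = {}
        for name, path in (inputs or {}).items():
            checksums[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        return RunManifest(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            input_checksums=checksums,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    @property
    def hash(self) -> str:
        key = f"{self.config_hash}|{self.seed}|{self.package_version}"
        return hashlib.sha256(key.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _forest_plot(results: pd.DataFrame, manifest_hash: str, path: Path) -> None:
    rows = results[results["evaluable"]].copy()
    rows["stratum"] = (
        rows["sex"].astype(str)
        + " | SES " + rows["ses_quintile"].astype(str)
        + " | " + rows["ethnicity"].astype(str)
    )
    strata = list(dict.fromkeys(rows["stratum"]))
    regions = list(dict.fromkeys(rows["region"]))
    fig, axes = plt.subplots(
        1, len(regions), figsize=(3.2 * len(regions) + 2, 0.35 * len(strata) + 1.5),
        sharey=True, squeeze=False,
    )
    for ax, region in zip(axes[0], regions):
        sub = rows[rows["region"] == region].set_index("stratum").reindex(strata)
        y = np.arange(len(strata))
        oe = sub["oe"].to_numpy(dtype=float)
        lo = sub["oe_lo"].to_numpy(dtype=float)
        hi = sub["oe_hi"].to_numpy(dtype=float)
        ax.errorbar(
            oe, y, xerr=[oe - lo, hi - oe],
            fmt="o", color="0.2", ecolor="0.5", capsize=2, markersize=4,
        )
        ax.axvline(1.0, color="firebrick", lw=0.8)
        ax.set_xscale("log")
        ax.set_title(f"{region}-risk model", fontsize=9)
        ax.set_xlabel("OE-ratio")
    axes[0][0].set_yticks(np.arange(len(strata)), strata, fontsize=7)
    axes[0][0].invert_yaxis()
    fig.suptitle("OE-ratio by stratum and region model", fontsize=11)
    fig.text(0.99, 0.01, f"run {manifest_hash}", ha="right", fontsize=6, color="0.6")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _calibration_plot(label: str, curve, manifest_hash: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    b = curve.bins
    ax.errorbar(
        b["mean_predicted"], b["observed"],
        yerr=[b["observed"] - b["ci_lo"], b["ci_hi"] - b["observed"]],
        fmt="o", color="0.2", ecolor="0.6", capsize=2, label="deciles",
    )
    ax.plot(curve.loess["predicted"], curve.loess["observed"], color="steelblue", label="LOESS")
    lim = max(b["mean_predicted"].max(), b["observed"].max()) * 1.1
    ax.plot([0, lim], [0, lim], ls="--", color="0.7", lw=0.8)
    ax.set_xlabel("mean predicted 10-year risk")
    ax.set_ylabel("observed 10-year risk (Aalen–Johansen)")
    ax.set_title(f"Calibration — {label}", fontsize=10)
    ax.legend(fontsize=8)
    fig.text(0.99, 0.01, f"run {manifest_hash}", ha="right", fontsize=6, color="0.6")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render(report, out_dir, manifest: RunManifest | None = None) -> list[Path]:
    """Write figures, tidy CSVs, flowchart and manifest; returns the paths.

    Missing/non-evaluable strata appear in the CSVs with empty estimate
    fields and are left as gaps in the figures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = RunManifest.create("unspecified", None)
    written: list[Path] = []

    results = report.results.copy()
    results = results.sort_values(
        ["sex", "ses_quintile", "ethnicity", "region"], kind="stable"
    ).reset_index(drop=True)
    p = out / "oe_forest_data.csv"
    _write_csv(results, p)
    written.append(p)
    if results["evaluable"].any():
        p = out / "oe_forest.svg"
        _forest_plot(results, manifest.hash, p)
        written.append(p)

    c_rows = results[results["region"] == results["region"].iloc[0]][
        ["sex", "ses_quintile", "ethnicity", "n", "events", "evaluable", "c", "c_lo", "c_hi"]
    ]
    p = out / "c_statistic_table.csv"
    _write_csv(c_rows, p)
    written.append(p)
    lines = ["| stratum | n | events | C (95% CI) |", "|---|---|---|---|"]
    for _, r in c_rows.iterrows():
        cell = (
            f"{r['c']:.3f} ({r['c_lo']:.3f}–{r['c_hi']:.3f})"
            if r["evaluable"] and pd.notna(r["c"])
            else "—"
        )
        lines.append(
            f"| {r['sex']} / SES {r['ses_quintile']} / {r['ethnicity']} "
            f"| {int(r['n'])} | {int(r['events'])} | {cell} |"
        )
    p = out / "c_statistic_table.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    for label, curve in (report.curves or {}).items():
        safe = label.replace("|", "_").replace("=", "-")
        p = out / f"calibration_{safe}.csv"
        _write_csv(curve.bins.assign(stratum=label), p)
        written.append(p)
        p = out / f"calibration_{safe}.svg"
        _calibration_plot(label, curve, manifest.hash, p)
        written.append(p)

    p = out / "flowchart.json"
    p.write_text(json.dumps(report.flowchart, indent=2, sort_keys=True) + "\n")
    written.append(p)
    flow = report.flowchart
    txt = [f"records in: {flow['input']}"]
    for reason, cnt in sorted(flow.get("dropped", {}).items()):
        txt.append(f"  dropped ({reason}): {cnt}")
    txt.append(f"analysis cohort: {flow['kept']}")
    p = out / "flowchart.txt"
    p.write_text("\n".join(txt) + "\n")
    written.append(p)

    p = out / "manifest.json"
    p.write_text(
        json.dumps(
            {
                "config_hash": manifest.config_hash,
                "seed": manifest.seed,
                "package_version": manifest.package_version,
                "input_checksums": manifest.input_checksums,
                "timestamp": manifest.timestamp,
                "hash": manifest.hash,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    written.append(p)

    summary = [
        "# Validation summary",
        "",
        f"run `{manifest.hash}` — {report.n} persons in the analysis cohort.",
        "",
        "Best-fitting region model per stratum (pooled OE nearest 1):",
        "",
    ]
    for key, region in sorted(report.best_region.items(), key=lambda kv: kv[0].label()):
        summary.append(f"- {key.label()}: **{region}**")
    summary += ["", "Treatment eligibility (% at/above the upper threshold):", ""]
    for sex, vals in sorted(report.eligibility.items()):
        summary.append(
            f"- {sex}: {vals['before_pct']:.1f}% under the low-risk model → "
            f"{vals['after_pct']:.1f}% under the best-fitting assignment"
        )
    p = out / "summary.md"
    p.write_text("\n".join(summary) + "\n")
    written.append(p)
    return written
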