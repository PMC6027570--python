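"""End-to-end study driver: simulate -> segment -> quantify -> group stats.

`run_study` reproduces the full synthetic study design: a resting baseline
cohort, a paired rest/stress cohort, and three post-infarct cohorts; it
quantifies every scan, assembles the long-format cohort table, runs the
group statistics with the per-arm exclusion policy (tSNR exclusion for the
rest/stress arm, no exclusion for the cross-sectional post-infarct
comparison), and writes CSV results, a JSON stats summary, a markdown
report and figure-style plots.  Everything is reproducible from
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as gstats
from .io import RESULT_COLUMNS, write_results
from .quantify import mbf_map, quantify_slice
from .synth import SCENARIOS, SliceRecord, scenario_config, simulate_cohort, truth_table

log = logging.getLogger("myoasl")

__all__ = ["RunConfig", "run_study", "cohort_table", "render_outputs"]

# stable per-scenario seed offsets so adding a scenario never reshuffles others
_SCENARIO_SEED_ID = {"baseline": 0, "stress": 1, "ami_day1": 2, "ami_week1": 3, "ami_week4": 4}


@dataclass
class RunConfig:
    """Configuration of one study run."""

    seed: int = 7
    out_dir: str = "study_out"
    scenarios: list[str] = field(
        default_factory=lambda: ["baseline", "stress", "ami_day1", "ami_week1", "ami_week4"]
    )
    scenario_overrides: dict = field(default_factory=dict)  # name -> {field: value}
    tsnr_threshold: float = 2.0
    map_spatial_radius: float = 1.0
    render: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "scenarios": self.scenarios,
                    "scenario_overrides": self.scenario_overrides,
                    "tsnr_threshold": self.tsnr_threshold,
                    "map_spatial_radius": self.map_spatial_radius,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:12]


def cohort_table(records: list[SliceRecord], exclusion_enabled: bool = True,
                 tsnr_threshold: float = 2.0) -> pd.DataFrame:
    """Quantify every scan of a simulated cohort into the long-format table."""
    rows = []
    for rec in records:
        for seg in quantify_slice(rec.series, rec.labels, exclusion_enabled, tsnr_threshold):
            rows.append(
                {
                    "subject": rec.subject,
                    "slice": rec.slice_id,
                    "segment": seg.segment,
                    "region": seg.region,
                    "condition": rec.condition,
                    "timepoint": rec.timepoint,
                    "mbf": seg.mbf_mean,
                    "pn": seg.pn,
                    "tsnr": seg.tsnr,
                    "included": seg.included,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def scenario_seed(base_seed: int, scenario: str) -> int:
    sid = _SCENARIO_SEED_ID.get(scenario, 97)
    return int(np.random.SeedSequence((base_seed, sid)).generate_state(1)[0] % (2**31))


def run_study(config: RunConfig) -> Path:
    """Run the full synthetic study; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_study config=%s seed=%d out=%s", config.digest(), config.seed, out)

    all_records: dict[str, list[SliceRecord]] = {}
    tables = []
    truths = []
    for name in config.scenarios:
        try:
            cfg = scenario_config(name, **config.scenario_overrides.get(name, {}))
            records = simulate_cohort(cfg, scenario_seed(config.seed, name))
            all_records[name] = records
            tables.append(cohort_table(records, True, config.tsnr_threshold))
            truths.append(truth_table(records))
        except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
            raise RuntimeError(f"stage 'simulate/quantify' failed for scenario {name!r}: {exc}") from exc

    table = pd.concat(tables, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    write_results(table, out / "results.csv")
    truth.to_csv(out / "truth.csv", index=False)

    stats_summary = _run_stats(table, config)
    (out / "stats.json").write_text(json.dumps(stats_summary, indent=1, default=float))

    summary = gstats.regional_summary(table[table["timepoint"] == "baseline"])
    summary_all = gstats.regional_summary(table, use_all_rows=True)
    summary.to_csv(out / "summary_baseline_included.csv", index=False)
    summary_all.to_csv(out / "summary_all_rows.csv", index=False)

    _write_report(out, config, table, stats_summary)
    if config.render:
        render_outputs(table, _example_maps(all_records, config), out)
    return out


def _run_stats(table: pd.DataFrame, config: RunConfig) -> dict:
    result: dict = {"config_digest": config.digest(), "seed": config.seed}

    stress_rows = table[table["slice"].str.startswith("stress")]
    if {"rest", "stress"} <= set(stress_rows["condition"]):
        paired = gstats.filter_paired(stress_rows, "rest", "stress")
        if paired.n_kept >= 2:
            t, p = gstats.paired_ttest(paired.b, paired.a)  # stress - rest
            reserve = gstats.mpr(paired.a, paired.b)
            result["rest_stress"] = {
                "n_kept": paired.n_kept,
                "n_dropped": paired.n_dropped,
                "rest_mean": float(paired.a.mean()),
                "rest_sd": float(paired.a.std(ddof=1)),
                "stress_mean": float(paired.b.mean()),
                "stress_sd": float(paired.b.std(ddof=1)),
                "t": t,
                "p": p,
                "mpr_mean": reserve.mean,
                "mpr_sd": reserve.sd,
                "mpr_n": reserve.n,
                "mpr_undefined": reserve.n_undefined,
                "percent_increase": 100.0 * (paired.b.mean() - paired.a.mean()) / paired.a.mean(),
            }

    cross = table[table["condition"] == "rest"]
    has_post = set(cross["timepoint"]) - {"baseline"}
    if "baseline" in set(cross["timepoint"]) and has_post:
        for region in ("infarct", "remote"):
            try:
                res = gstats.cross_sectional_compare(cross, region)
            except ValueError as exc:
                log.warning("cross-sectional %s skipped: %s", region, exc)
                continue
            result[f"cross_sectional_{region}"] = {
                "anova_f": res.anova_f,
                "anova_p": res.anova_p,
                "group_means": res.group_means,
                "group_ns": res.group_ns,
                "comparisons": res.comparisons.to_dict(orient="records"),
            }
    return result


def _write_report(out: Path, config: RunConfig, table: pd.DataFrame, stats_summary: dict) -> None:
    lines = [
        "# Synthetic ASL-CMR study report",
        "",
        f"- config digest: `{config.digest()}`",
        f"- seed: {config.seed}",
        f"- scenarios: {', '.join(config.scenarios)}",
        "",
        "## Exclusions (tSNR < {:.1f}) per arm".format(config.tsnr_threshold),
        "",
    ]
    for timepoint, grp in table.groupby("timepoint"):
        n = len(grp)
        nx = int((~grp["included"]).sum())
        lines.append(f"- {timepoint}: {nx} of {n} segments flagged excluded")
    lines.append("")
    if "rest_stress" in stats_summary:
        rs = stats_summary["rest_stress"]
        lines += [
            "## Rest vs stress (baseline-arm exclusion: dropped if excluded in either condition)",
            "",
            f"- kept {rs['n_kept']} segment pairs, dropped {rs['n_dropped']}",
            f"- rest MBF {rs['rest_mean']:.2f} +/- {rs['rest_sd']:.2f}, "
            f"stress MBF {rs['stress_mean']:.2f} +/- {rs['stress_sd']:.2f} ml/g/min",
            f"- paired t = {rs['t']:.2f}, p = {rs['p']:.2e}",
            f"- MPR {rs['mpr_mean']:.2f} +/- {rs['mpr_sd']:.2f} "
            f"({rs['percent_increase']:.0f}% MBF increase)",
            "",
        ]
    for region in ("infarct", "remote"):
        key = f"cross_sectional_{region}"
        if key in stats_summary:
            cs = stats_summary[key]
            lines += [
                f"## Cross-sectional resting MBF, {region} region (no exclusion)",
                "",
                f"- ANOVA F = {cs['anova_f']:.2f}, p = {cs['anova_p']:.2e}",
            ]
            for cmp_row in cs["comparisons"]:
                star = " (*)" if cmp_row["significant"] else ""
                lines.append(
                    f"- {cmp_row['timepoint']} vs baseline: diff = {cmp_row['mean_diff']:.2f}, "
                    f"adjusted p = {cmp_row['p_adjusted']:.3g}{star}"
                )
            lines.append("")
    (out / "report.md").write_text("\n".join(lines))


def _example_maps(all_records: dict[str, list[SliceRecord]], config: RunConfig) -> dict[str, np.ndarray]:
    """Pixelwise MBF maps for the first paired slice (rest/stress), if present."""
    maps: dict[str, np.ndarray] = {}
    if "stress" in all_records:
        for rec in all_records["stress"][:2]:
            maps[rec.condition] = mbf_map(
                rec.series, rec.labels.mask, spatial_radius=config.map_spatial_radius
            )
    return maps


def render_outputs(results: pd.DataFrame, maps: dict[str, np.ndarray], out_dir) -> list[Path]:
    """Figure-style outputs: rest/stress MBF maps (shared color scale),
    rest/stress box plot, regional bar chart with SD error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if maps:
        vmax = max(float(np.nanmax(m)) for m in maps.values())
        vmin = min(0.0, min(float(np.nanmin(m)) for m in maps.values()))
        fig, axes = plt.subplots(1, len(maps), figsize=(5 * len(maps), 4))
        axes = np.atleast_1d(axes)
        for ax, (name, m) in zip(axes, maps.items()):
            im = ax.imshow(m, vmin=vmin, vmax=vmax, cmap="hot")
            ax.set_title(f"{name} MBF (ml/g/min)")
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(out / "mbf_maps.png", dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "mbf_maps.png")

    paired = results[results["slice"].str.startswith("stress") & results["included"]]
    if {"rest", "stress"} <= set(paired["condition"]):
        data = [
            paired.loc[paired["condition"] == c, "mbf"].to_numpy() for c in ("rest", "stress")
        ]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot(data, tick_labels=["rest", "stress"])
        ax.set_ylabel("regional MBF (ml/g/min)")
        fig.savefig(out / "rest_stress_boxplot.png", dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "rest_stress_boxplot.png")

    rest = results[results["condition"] == "rest"]
    reg = gstats.regional_summary(rest[rest["region"].isin(["infarct", "remote"])], use_all_rows=True)
    if not reg.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        width = 0.35
        timepoints = [t for t in gstats.TIMEPOINT_ORDER if t in set(reg["timepoint"])]
        xs = np.arange(len(timepoints))
        for k, region in enumerate(("remote", "infarct")):
            sub = reg[reg["region"] == region].set_index("timepoint")
            means = [sub["mbf_mean"].get(t, np.nan) for t in timepoints]
            sds = [sub["mbf_sd"].get(t, 0.0) for t in timepoints]
            ax.bar(xs + (k - 0.5) * width, means, width, yerr=sds, capsize=3, label=region)
        ax.set_xticks(xs, timepoints)
        ax.set_ylabel("resting MBF (ml/g/min)")
        ax.legend()
        fig.savefig(out / "regional_bars.png", dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "regional_bars.png")
    return written
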