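"""End-to-end emulated study: simulate, measure, summarise, test, render.

``run_emulated_study`` drives the whole pipeline: it generates a synthetic
study (all animals, levels and modalities), runs every measurement chain on
the noisy raw data (%DHI, zonal 3D-DHI, T2 ROI means, histology and cell
summaries), applies the statistical battery, and writes tidy CSV tables,
figures (trajectory curves, the five-zone bin grid, a colour T2 map) and a
truth-vs-estimate recovery report to an output directory.  Everything is
deterministic under the master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse, Wedge

from . import disc3d, radiograph, stats, synthetic, t2map
from .study_design import StudyDesign, default_design

logger = logging.getLogger("discdegen")

__all__ = [
    "RunConfig",
    "run_emulated_study",
    "analyze_radiographs",
    "analyze_endplates",
    "analyze_mri",
    "analyze_cells",
    "render_zone_bin_grid",
    "zero_noise_table",
]

BIN_COLORS = {"<70": "#b2182b", "70-<80": "#ef8a62", "80-<90": "#fddbc7", ">=90": "#1a9850"}


@dataclass
class RunConfig:
    """Configuration of one emulated-study run."""

    master_seed: int = 42
    outdir: str | Path = "discdegen_out"
    preset_path: str | None = None
    design: StudyDesign | None = None
    stages: tuple[str, ...] = ("radiograph", "microct", "mri", "histology", "stats")
    np_fraction: float = 0.5
    zero_noise: bool = False
    make_figures: bool = True


def zero_noise_table(table: synthetic.PresetTable) -> synthetic.PresetTable:
    """Copy of a preset table with every noise source switched off."""
    noise = dict(table.noise)
    noise.update(radiograph_sd_mm=0.0, mr_noise_frac=0.0, t2_disc_jitter_frac=0.0)
    geom = replace(table.geometry, surface_roughness_sd_mm=0.0)
    return dataclasses.replace(table, noise=noise, geometry=geom)


# ---------------------------------------------------------------------------
# measurement chains on a synthetic study
# ---------------------------------------------------------------------------


def analyze_radiographs(study: synthetic.StudyData) -> pd.DataFrame:
    """Pixel measurements -> calibrated DH -> DHI -> %DHI."""
    if study.radiographs.empty:
        return pd.DataFrame()
    return radiograph.process_measurements(study.radiographs, study.design)


def analyze_endplates(study: synthetic.StudyData, np_fraction: float = 0.5) -> pd.DataFrame:
    """Directed least-distance zonal pipeline for every micro-CT disc.

    Returns one row per (animal, level, zone) with the measured height,
    zone-matched 3D-DHI against the same animal's reference disc, and bin;
    zone='whole' rows carry the whole-disc values.
    """
    design = study.design
    ref_level = design.reference_level
    tables: dict[tuple[int, str], disc3d.ZoneHeightTable] = {}
    for (animal, level), (inf, sup, _gaps) in study.endplates.items():
        frame = disc3d.fit_disc_frame(inf, sup)
        part = disc3d.partition_zones(inf, frame, np_fraction=np_fraction)
        tables[(animal, level)] = disc3d.zone_heights(inf, sup, part)
    rows = []
    for (animal, level), tab in tables.items():
        if level == ref_level:
            continue
        ref = tables.get((animal, ref_level))
        if ref is None:
            raise ValueError(f"no reference disc for animal {animal}")
        full = disc3d.three_d_dhi(tab, ref)
        week = design.week_of_animal(animal)
        treatment = design.level_map[level].label
        for z in disc3d.ZONES:
            rows.append(
                {"animal": animal, "level": level, "treatment": treatment, "week": week,
                 "zone": z, "height_mm": full.zone_height_mm[z],
                 "dhi_pct": full.zone_dhi_pct[z], "bin": full.zone_bin.get(z)}
            )
        rows.append(
            {"animal": animal, "level": level, "treatment": treatment, "week": week,
             "zone": "whole", "height_mm": full.whole_height_mm,
             "dhi_pct": full.whole_dhi_pct, "bin": None}
        )
    return pd.DataFrame(rows)


def analyze_mri(study: synthetic.StudyData, method: str = "loglinear_weighted") -> pd.DataFrame:
    """Fit T2 maps and extract ROI means for every MRI disc."""
    rows = []
    for (animal, level), item in study.echo_stacks.items():
        m = t2map.fit_t2_map(item["stack"], method=method)
        disc_roi = t2map.ROI(item["disc_mask"], "disc")
        np_roi = t2map.ROI(item["np_mask"], "np")
        rows.append(
            {
                "animal": animal,
                "level": level,
                "treatment": study.design.level_map[level].label,
                "week": study.design.week_of_animal(animal),
                "t2_disc_ms": t2map.roi_mean_t2(m, disc_roi),
                "t2_np_ms": t2map.roi_mean_t2(m, np_roi),
                "true_np_t2_ms": item["true_np_t2_ms"],
            }
        )
    return pd.DataFrame(rows)


def analyze_cells(study: synthetic.StudyData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Surviving-cell percentages (vs the same animal's CA disc) and clone
    prevalence per treatment x week."""
    cells = study.cells
    design = study.design
    ca_level = design.level_for_treatment("CA")
    ctrl = cells[cells["level"] == ca_level][["animal", "total_alive"]].rename(
        columns={"total_alive": "control_alive"}
    )
    merged = cells.merge(ctrl, on="animal")
    treated = merged[merged["treatment"].str.startswith("MIA")].copy()
    treated["survived_pct"] = 100.0 * treated["total_alive"] / treated["control_alive"]
    prevalence = (
        cells.groupby(["treatment", "week"], observed=True)["clone_present"]
        .agg(n_positive="sum", n_total="count")
        .reset_index()
    )
    prevalence["clone_pct"] = (
        100.0 * prevalence["n_positive"] / prevalence["n_total"]
    ).round(1)
    return treated, prevalence


# ---------------------------------------------------------------------------
# statistics battery on the measured tables
# ---------------------------------------------------------------------------


def run_statistics(
    dhi: pd.DataFrame, zones: pd.DataFrame, mri: pd.DataFrame, histo: pd.DataFrame
) -> dict[str, object]:
    """The study's statistical comparisons on the pipeline outputs."""
    out: dict[str, object] = {}
    # %DHI: treatment x week, both within-animal, on the longest-observed cohort
    if not dhi.empty:
        full = dhi.dropna(subset=["pct_DHI"]).copy()
        last_week = full["week"].max()
        cohort = full.groupby("animal")["week"].max()
        keep = cohort[cohort == last_week].index
        sub = full[full["animal"].isin(keep) & (full["week"] > 0)]
        try:
            out["rm_anova_pct_dhi"] = stats.rm_anova_two_way(
                sub, dv="pct_DHI", subject="animal", factors=("level", "week")
            )
            out["posthoc_pct_dhi"] = stats.posthoc(
                sub[sub["week"] == last_week], dv="pct_DHI", group="level",
                method="bonferroni", paired_on="animal",
            )
        except ValueError as exc:  # pragma: no cover - unbalanced real inputs
            logger.warning("rm-anova skipped: %s", exc)
    if not histo.empty:
        last = histo["week"].max()
        groups = [
            g["total"].to_numpy(float)
            for _, g in histo[histo["week"] == last].groupby("treatment", observed=True)
        ]
        out["kruskal_total_score"] = stats.kruskal_wallis(groups)
        blocks = histo.pivot_table(index="treatment", columns="week", values="total", observed=True)
        out["friedman_total_score"] = stats.friedman(blocks.to_numpy(float))
    if not mri.empty and not histo.empty:
        merged = mri.merge(histo[["animal", "level", "total"]], on=["animal", "level"])
        if len(merged) >= 3:
            r_s, p_s = stats.correlate(merged["t2_disc_ms"], merged["total"], "spearman")
            r_p, p_p = stats.correlate(merged["t2_disc_ms"], merged["total"], "pearson")
            out["correlation_t2_histology"] = {
                "spearman_r": r_s, "spearman_p": p_s, "pearson_r": r_p, "pearson_p": p_p,
                "n": len(merged),
            }
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def render_zone_bin_grid(zones: pd.DataFrame, path=None):
    """Levels x weeks grid of five-zone schematics coloured by 3D-DHI bin.

    Each cell draws the disc footprint: four annulus quadrants (anterior
    up) plus the central NP ellipse.  Missing cells are left blank with a
    warning.  Bins are averaged over animals via the median dhi_pct.
    """
    data = zones[zones["zone"] != "whole"]
    levels = sorted(data["level"].unique())
    weeks = sorted(data["week"].unique())
    fig, axes = plt.subplots(
        len(levels), len(weeks), figsize=(2.0 * len(weeks), 2.0 * len(levels)), squeeze=False
    )
    wedge_angles = {"anterior": 45, "l_lateral": 135, "posterior": 225, "r_lateral": 315}
    for i, lv in enumerate(levels):
        for j, wk in enumerate(weeks):
            ax = axes[i][j]
            ax.set_xlim(-1.2, 1.2)
            ax.set_ylim(-1.2, 1.2)
            ax.set_aspect("equal")
            ax.axis("off")
            if i == 0:
                ax.set_title(f"week {wk}", fontsize=9)
            if j == 0:
                ax.text(-1.4, 0, lv, rotation=90, va="center", fontsize=9)
            cell = data[(data["level"] == lv) & (data["week"] == wk)]
            if cell.empty:
                logger.warning("zone-bin grid: no data for %s week %s", lv, wk)
                continue
            med = cell.groupby("zone", observed=True)["dhi_pct"].median()
            for zone, start in wedge_angles.items():
                color = BIN_COLORS[disc3d.dhi_bin(float(med[zone]))]
                ax.add_patch(Wedge((0, 0), 1.0, start, start + 90, width=0.5, facecolor=color, edgecolor="k"))
            np_color = BIN_COLORS[disc3d.dhi_bin(float(med["np"]))]
            ax.add_patch(Ellipse((0, 0), 1.0, 1.0, facecolor=np_color, edgecolor="k"))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _plot_trajectories(dhi: pd.DataFrame, design: StudyDesign, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sub = dhi.dropna(subset=["pct_DHI"])
    for level in design.levels:
        if level == design.reference_level:
            continue
        g = sub[sub["level"] == level].groupby("week")["pct_DHI"]
        mean, sem = g.mean(), g.sem()
        ax.errorbar(mean.index, mean, yerr=sem, marker="o", capsize=2,
                    label=f"{level} ({design.level_map[level].label})")
    ax.set_xlabel("weeks post-injection")
    ax.set_ylabel("%DHI")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _recovery_report(study, dhi, zones, mri, cells_pct) -> pd.DataFrame:
    """Truth-vs-estimate table for every generator parameter the pipeline
    measures."""
    truth = study.truth
    design = study.design
    rows = []
    if not dhi.empty:
        final = dhi.merge(
            truth[["animal", "level", "week", "treatment", "dhi_pct_final"]],
            on=["animal", "level", "week"],
        ).dropna(subset=["pct_DHI"])
        for _, r in final.iterrows():
            rows.append(("radiograph_pct_dhi", r["animal"], r["level"], r["week"],
                         r["dhi_pct_final"], r["pct_DHI"]))
    if not zones.empty:
        gap_cols = {z: f"true_gap_{z}_mm" for z in disc3d.ZONES}
        ref_level = design.reference_level
        ref_truth = truth[truth["level"] == ref_level].set_index("animal")
        merged = zones[zones["zone"] != "whole"].merge(
            truth[["animal", "level"] + list(gap_cols.values())], on=["animal", "level"]
        )
        for _, r in merged.iterrows():
            ref_gap = ref_truth.loc[r["animal"], gap_cols[r["zone"]]]
            true_dhi = 100.0 * r[gap_cols[r["zone"]]] / ref_gap
            rows.append((f"zone_dhi_{r['zone']}", r["animal"], r["level"], r["week"],
                         true_dhi, r["dhi_pct"]))
    if not mri.empty:
        for _, r in mri.iterrows():
            rows.append(("np_t2_ms", r["animal"], r["level"], r["week"],
                         r["true_np_t2_ms"], r["t2_np_ms"]))
    if cells_pct is not None and not cells_pct.empty:
        merged = cells_pct.merge(
            truth[["animal", "level", "cell_survival_fraction"]], on=["animal", "level"]
        )
        for _, r in merged.iterrows():
            rows.append(("cell_survival_pct", r["animal"], r["level"], r["week"],
                         100.0 * r["cell_survival_fraction"], r["survived_pct"]))
    rep = pd.DataFrame(rows, columns=["quantity", "animal", "level", "week", "truth", "estimate"])
    rep["rel_error"] = np.abs(rep["estimate"] - rep["truth"]) / np.abs(rep["truth"])
    return rep


def run_emulated_study(config: RunConfig, presets: synthetic.PresetTable | None = None) -> dict:
    """Run the whole emulated study; returns the result bundle in memory
    and writes CSV tables, figures and the recovery report under
    ``config.outdir``."""
    design = config.design or default_design()
    table = presets if presets is not None else synthetic.load_presets(config.preset_path)
    if config.zero_noise:
        table = zero_noise_table(table)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("emulated study: seed=%s outdir=%s stages=%s",
                config.master_seed, outdir, config.stages)

    modalities = tuple(s for s in config.stages if s in ("radiograph", "microct", "mri", "histology"))
    study = synthetic.generate_study(design, config.master_seed, table, modalities)

    dhi = analyze_radiographs(study) if "radiograph" in config.stages else pd.DataFrame()
    zones = analyze_endplates(study, config.np_fraction) if "microct" in config.stages else pd.DataFrame()
    mri = analyze_mri(study) if "mri" in config.stages else pd.DataFrame()
    cells_pct, clones = (None, None)
    if "histology" in config.stages:
        cells_pct, clones = analyze_cells(study)

    results: dict[str, object] = {
        "study": study, "dhi": dhi, "zones": zones, "mri": mri,
        "cells": cells_pct, "clones": clones,
    }
    if "stats" in config.stages:
        results["stats"] = run_statistics(dhi, zones, mri, study.histology)

    report = _recovery_report(study, dhi, zones, mri, cells_pct)
    results["recovery"] = report

    for name, frame in (("dhi", dhi), ("zones", zones), ("mri", mri),
                        ("cells", cells_pct), ("clones", clones),
                        ("histology", study.histology), ("truth", study.truth),
                        ("recovery", report)):
        if frame is not None and not frame.empty:
            frame.to_csv(outdir / f"{name}.csv", index=False)
    if config.make_figures:
        if not dhi.empty:
            _plot_trajectories(dhi, design, outdir / "pct_dhi_trajectories.png")
        if not zones.empty:
            render_zone_bin_grid(zones, outdir / "zone_bin_grid.png")
        if study.echo_stacks:
            key = sorted(study.echo_stacks)[0]
            m = t2map.fit_t2_map(study.echo_stacks[key]["stack"])
            rgb = t2map.render_t2_colormap(m, np.array([20, 40, 60, 80, 100, 120]))
            plt.imsave(outdir / "t2_map_example.png", np.clip(rgb, 0, 1))
    return results
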