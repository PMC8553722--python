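"""End-to-end reproducible runs: simulate → measure → stats → model fit.

A run is described by a plain dict (usually loaded from YAML):

.. code-block:: yaml

    seed: 0
    phantom: {cell_length: 60, cell_width: 16, cell_depth: 8, n_nuclei: 2}
    render: {photons_per_punctum: 500, background_rate: 5}
    groups:
      - name: control
        n_cells: 4
        placement: {kind: gradient, n_puncta: 600, D: 0.05, a: 0.5}
      - name: colchicine
        n_cells: 4
        fix_a_zero: true
        placement: {kind: gradient, n_puncta: 600, D: 0.05, a: 0.0}
    periodicity: false

Each cell gets its own derived seed, per-cell puncta tables are written as
CSV (and reloaded on rerun, making runs resumable and idempotent), and the
report aggregates per-cell d50 and densities, per-group CDF summaries,
pairwise KS / Bonferroni-Wilcoxon tests and trafficking-model fits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .localization import (
    DetectionParams,
    DetectionResult,
    combine_segmentation,
    compute_distance_map,
    detect_puncta,
    partition_regions,
    puncta_count_density,
    assign_regions,
    segment_cell,
    segment_nuclei,
)
from .periodicity import detect_period, extract_axial_profile, power_spectrum
from .phantom import PhantomSpec, PlacementModel, RenderSpec, generate_cell_phantom, place_puncta, render_volume
from .spatial_stats import (
    bonferroni,
    d50,
    empirical_cdf,
    ks_two_sample,
    reference_cdfs,
    summarize_cdfs,
    wilcoxon_rank_sum,
)
from .trafficking import TraffickingParams, fit_params

logger = logging.getLogger("myomol")

__all__ = ["RunReport", "load_config", "validate_config", "run_pipeline", "make_figures"]


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    config: dict
    per_cell: pd.DataFrame
    summaries: dict = field(default_factory=dict)
    references: dict = field(default_factory=dict)
    tests: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    version: str = ""

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"cannot serialize {type(o)}")

        payload = {
            "config": self.config,
            "version": self.version,
            "per_cell": self.per_cell.to_dict(orient="records"),
            "summaries": {
                g: {k: np.asarray(v).tolist() for k, v in
                    dataclasses.asdict(s).items() if k != "n_cells"} | {"n_cells": s.n_cells}
                for g, s in self.summaries.items()
            },
            "tests": [dataclasses.asdict(t) for t in self.tests],
            "fits": {g: {"D": f.params.D, "a": f.params.a, "F": f.params.F,
                         "d": f.params.d, "residual": f.residual,
                         "converged": f.converged} for g, f in self.fits.items()},
        }
        return json.dumps(payload, default=enc, indent=2)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    """Fail fast on malformed configs and missing input paths."""
    if "groups" not in config or not config["groups"]:
        raise ValueError("config needs a non-empty 'groups' list")
    for key in ("mask", "image"):
        for grp in config["groups"]:
            p = grp.get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} path does not exist: {p}")
    for grp in config["groups"]:
        if "placement" not in grp:
            raise ValueError(f"group {grp.get('name')} lacks a placement block")


def _placement_from_config(block: dict, n_cell_seed: int) -> PlacementModel:
    block = dict(block)
    kind = block.pop("kind")
    n_puncta = int(block.pop("n_puncta"))
    tp = None
    if kind == "gradient":
        tp = TraffickingParams(D=float(block.pop("D", 0.05)),
                               a=float(block.pop("a", 0.5)),
                               F=1.0, d=float(block.pop("d", 1.0)))
    return PlacementModel(kind=kind, n_puncta=n_puncta, seed=n_cell_seed,
                          params=tp, **block)


def run_pipeline(config: dict, out_dir) -> RunReport:
    """Execute the full pipeline for every group and cell in the config.

    Stages per cell: phantom → puncta placement → rendering → nucleus
    segmentation → cell mask (ground-truth pass-through by default) →
    distance map → region partition → puncta detection → region/distance
    assignment.  Group level: CDF summaries, reference CDFs, pairwise KS
    and Bonferroni-corrected Wilcoxon (on per-cell d50), trafficking-model
    fits to pooled distances, optional striation spectra.
    """
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    spec = PhantomSpec(**config.get("phantom", {}), seed=seed)
    render_spec_base = config.get("render", {})
    det = DetectionParams(**config.get("detection", {}))
    grid_step = float(config.get("grid_step", 0.1))

    rows = []
    group_cdfs: dict[str, list] = {}
    group_pooled: dict[str, np.ndarray] = {}
    report = RunReport(config=config, per_cell=pd.DataFrame(), version="myomol 0.1.0")

    labels_true = generate_cell_phantom(spec)
    dmap_true = compute_distance_map(labels_true)

    for gi, grp in enumerate(config["groups"]):
        gname = grp["name"]
        group_cdfs[gname] = []
        pooled = []
        for ci in range(int(grp.get("n_cells", 1))):
            t0 = time.perf_counter()
            cell_seed = seed * 100_000 + gi * 1_000 + ci
            cell_id = f"{gname}_{ci:02d}"
            puncta_csv = out_dir / f"puncta_{cell_id}.csv"
            if puncta_csv.exists():
                table = mio.read_puncta(puncta_csv)
                logger.info("resumed %s from %s", cell_id, puncta_csv)
            else:
                model = _placement_from_config(grp["placement"], cell_seed)
                truth = place_puncta(labels_true, model, dmap_true, cell_id=cell_id)
                render = RenderSpec(**render_spec_base, seed=cell_seed + 7)
                volume = render_volume(labels_true, truth, render)
                nuclei = segment_nuclei(volume, "nuclei")
                cell = segment_cell(mask=labels_true.cell_mask,
                                    voxel_size=labels_true.voxel_size)
                seg = combine_segmentation(cell, nuclei)
                dmap = compute_distance_map(seg)
                part = partition_regions(seg)
                detected: DetectionResult = detect_puncta(volume, "puncta", seg,
                                                          det, cell_id=cell_id)
                table = assign_regions(detected.table, part, dmap)
                mio.write_puncta(puncta_csv, table)
                if config.get("periodicity") and ci == 0:
                    profile = extract_axial_profile(volume, "puncta",
                                                    seg.cell_mask, cell_id)
                    report.spectra[gname] = detect_period(power_spectrum(profile))
            cyto = table[table["region"] != "nucleus"]
            dists = cyto["distance_um"].to_numpy()
            if dists.size:
                cdf = empirical_cdf(dists, grid_step=grid_step)
                group_cdfs[gname].append(cdf)
                pooled.append(dists)
                cell_d50 = d50(cdf)
            else:
                cell_d50 = np.nan
            rows.append({
                "group": gname, "cell_id": cell_id,
                "n_puncta": len(table), "n_cytosolic": len(cyto),
                "d50_um": cell_d50,
                "density_per_um3": puncta_count_density(
                    len(cyto), labels_true.cytosol_mask, labels_true.voxel_size),
            })
            logger.info("measured %s: %d puncta in %.2f s", cell_id,
                        len(table), time.perf_counter() - t0)
        group_pooled[gname] = np.concatenate(pooled) if pooled else np.empty(0)
        if group_cdfs[gname]:
            report.summaries[gname] = summarize_cdfs(group_cdfs[gname])

    part_true = partition_regions(labels_true)
    cyt_ref, per_ref = reference_cdfs(dmap_true, part_true, grid_step=grid_step)
    report.references = {"cytosol": cyt_ref, "periphery": per_ref}

    tests = []
    per_cell = pd.DataFrame(rows)
    for ga, gb in combinations(group_pooled, 2):
        if group_pooled[ga].size >= 2 and group_pooled[gb].size >= 2:
            tests.append(ks_two_sample(group_pooled[ga], group_pooled[gb],
                                       comparison=f"{ga} vs {gb} (pooled distances)"))
    wil = []
    for ga, gb in combinations(group_pooled, 2):
        da = per_cell.loc[per_cell.group == ga, "d50_um"].dropna()
        db = per_cell.loc[per_cell.group == gb, "d50_um"].dropna()
        if len(da) and len(db):
            wil.append(wilcoxon_rank_sum(da, db, comparison=f"{ga} vs {gb} (d50)"))
    tests.extend(bonferroni(wil) if wil else [])
    report.tests = tests
    report.per_cell = per_cell

    length_scale = float(np.quantile(dmap_true.values[labels_true.cytosol_mask], 0.95))
    for gname, dists in group_pooled.items():
        if dists.size < 50:
            continue
        counts, edges = np.histogram(np.minimum(dists, length_scale), bins=30,
                                     range=(0.0, length_scale))
        fix_a = bool(next(g for g in config["groups"] if g["name"] == gname)
                     .get("fix_a_zero", False))
        report.fits[gname] = fit_params(edges, counts, length_scale=length_scale,
                                        fix_a_zero=fix_a, seed=seed)

    report_path = out_dir / "report.json"
    report_path.write_text(report.to_json())
    per_cell.to_csv(out_dir / "per_cell.csv", index=False)
    logger.info("report written to %s", report_path)
    return report


def make_figures(report: RunReport, out_dir) -> list[Path]:
    """Render summary figures: CDF bands with reference curves, d50 bars,
    model-vs-data CDF overlays, and spectra when available."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not report.summaries:
        raise ValueError("report holds no group summaries to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for gname, s in report.summaries.items():
        line, = ax.plot(s.grid, s.mean, label=f"{gname} (mean of {s.n_cells} cells)")
        ax.fill_between(s.grid, np.clip(s.mean - s.sd, 0, 1),
                        np.clip(s.mean + s.sd, 0, 1), alpha=0.25,
                        color=line.get_color())
    if report.references:
        cy = report.references["cytosol"]
        pe = report.references["periphery"]
        ax.plot(cy.grid, cy.values, "k--", label="all cytosolic voxels")
        ax.plot(pe.grid, pe.values, "k:", label="cell periphery")
    ax.set_xlabel("distance from nuclear perimeter (µm)")
    ax.set_ylabel("cumulative fraction of signal")
    ax.legend(fontsize=8)
    p = out_dir / "cdfs.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    if len(report.per_cell):
        fig, ax = plt.subplots(figsize=(4, 4))
        agg = report.per_cell.groupby("group")["d50_um"]
        ax.bar(agg.median().index, agg.median().values,
               yerr=agg.apply(lambda s: float(np.median(np.abs(s - s.median())))),
               capsize=4)
        ax.set_ylabel("d50 (µm)")
        p = out_dir / "d50.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    if report.fits and report.summaries:
        from .trafficking import model_distance_cdf, steady_state
        fig, ax = plt.subplots(figsize=(6, 4))
        for gname, fit in report.fits.items():
            if gname not in report.summaries:
                continue
            s = report.summaries[gname]
            line, = ax.plot(s.grid, s.global_cdf, "-", label=f"{gname} data")
            sol = steady_state(fit.params)
            xs, cdf = model_distance_cdf(sol, length_scale=float(s.grid[-1]))
            ax.plot(xs, cdf, "--", color=line.get_color(), label=f"{gname} model")
        ax.set_xlabel("distance from nuclear perimeter (µm)")
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=8)
        p = out_dir / "model_fits.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    for gname, res in report.spectra.items():
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(res.frequencies, res.power)
        if res.peak_frequency:
            ax.axvline(res.peak_frequency, color="r", ls=":",
                       label=f"peak {res.peak_frequency:.3f} µm⁻¹")
            ax.legend(fontsize=8)
        ax.set_xlabel("spatial frequency (µm⁻¹)")
        ax.set_ylabel("power")
        ax.set_xlim(0, 1.2)
        p = out_dir / f"spectrum_{gname}.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
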