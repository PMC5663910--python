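"""Configuration-driven end-to-end pipeline.

A YAML config lists the FOV files (reporter/tracer TIFF pairs) with
their animal/group mapping and acquisition covariates, selects the
segmentation algorithm (``voronoi`` or ``contrast``) and the endpoint
(``fraction_active`` or ``mean_uptake``), and overrides algorithm
parameters.  :func:`run_pipeline` chains segmentation -> background ->
uptake -> classification -> (optional chaining and de-trend) ->
per-animal aggregation -> group statistics, writes every intermediate
table, and logs the parameters actually used.  Fixed seed implies
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantification as quant
from . import segmentation as seg
from . import stats as gstats
from .io import FOV, read_fov

logger = logging.getLogger("synquant")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]

_DEFAULTS = {
    "algorithm": "voronoi",          # or "contrast"
    "endpoint": "fraction_active",   # or "mean_uptake"
    "k_sd_segment": None,            # detection threshold in SDs; None = per-algorithm default
    "k_sd_active": 1.0,              # active-synapse rule, SDs above background
    "area_range": [4, 200],
    "roundness_min": 0.4,
    "radius_range": [1.0, 8.0],
    "median_size": 3,
    "chained_only": False,
    "chain_d_max_um": 5.0,
    "chain_min": 3,
    "detrend_covariate": None,       # "detector_gain" or "gain_x_laser"
    "n_perm": 10_000,
    "annulus_gap": 2,
    "annulus_width": 4,
}


@dataclass
class PipelineConfig:
    fovs: list[dict]                       # path_gz, path_sb, fov_id, animal_id, group_label, gain, laser
    params: dict = dataclass_field(default_factory=dict)
    seed: int = 0
    outdir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(fovs=raw.get("fovs", []), params=raw.get("params", {}),
                  seed=int(raw.get("seed", 0)),
                  outdir=Path(raw["outdir"]) if "outdir" in raw else None)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.fovs:
            raise ValueError("empty FOV manifest")
        merged = {**_DEFAULTS, **self.params}
        if merged["algorithm"] not in ("voronoi", "contrast"):
            raise ValueError(f"unknown algorithm {merged['algorithm']!r}")
        if merged["endpoint"] not in ("fraction_active", "mean_uptake"):
            raise ValueError(f"unknown endpoint {merged['endpoint']!r}")
        for entry in self.fovs:
            for key in ("path_gz", "path_sb"):
                if key in entry and not Path(entry[key]).exists():
                    raise FileNotFoundError(f"{entry[key]} does not exist")


@dataclass
class PipelineResult:
    roi_table: pd.DataFrame
    fov_table: pd.DataFrame
    animal_table: pd.DataFrame
    stats_table: pd.DataFrame
    params: dict
    errors: list[dict]


def _load_fovs(config: PipelineConfig) -> list[FOV]:
    fovs = []
    for entry in config.fovs:
        fovs.append(read_fov(
            entry["path_gz"], entry["path_sb"],
            fov_id=str(entry.get("fov_id", Path(entry["path_gz"]).stem)),
            pixel_size=float(entry.get("pixel_size", 1.0)),
            detector_gain=float(entry.get("detector_gain", 1.0)),
            laser_power=float(entry.get("laser_power", 1.0)),
            animal_id=str(entry.get("animal_id", "")),
            group_label=str(entry.get("group_label", "")),
        ))
    return fovs


def process_fov(fov: FOV, params: dict) -> tuple[pd.DataFrame, quant.FOVSummary]:
    """Segment, measure and quantify a single FOV."""
    k_sd = params["k_sd_segment"]
    if params["algorithm"] == "voronoi":
        rois = seg.segment_voronoi(
            fov.gz_image, k_sd=2.0 if k_sd is None else k_sd,
            area_range=tuple(params["area_range"]),
            roundness_min=params["roundness_min"])
    else:
        rois = seg.segment_contrast(
            fov.gz_image, median_size=params["median_size"],
            radius_range=tuple(params["radius_range"]),
            k_sd=2.5 if k_sd is None else k_sd)
    seg.measure_rois(rois, fov.gz_image, fov.sb_image,
                     gap=params["annulus_gap"], width=params["annulus_width"])
    if params["chained_only"]:
        seg.link_axonal_chains(rois, d_max=params["chain_d_max_um"],
                               pixel_size=fov.pixel_size,
                               min_chain=params["chain_min"])
    records = quant.records_from_rois(
        rois, k_active=params["k_sd_active"], fov_id=fov.fov_id,
        animal_id=fov.animal_id, group_label=fov.group_label,
        detector_gain=fov.detector_gain, laser_power=fov.laser_power,
        chained_only=params["chained_only"])
    if not records:
        raise RuntimeError("no ROIs retained for quantification")
    gz_means = [r.mean_gz - r.bg_gz_mean for r in rois
                if not params["chained_only"] or r.chain_id is not None]
    summary = quant.fraction_active(records, gz_means=gz_means)
    table = seg.rois_to_frame(rois)
    table.insert(0, "fov_id", fov.fov_id)
    table["uptake_index"] = [quant.uptake_index(r)[0] for r in rois]
    table["active"] = [quant.classify_active(r, params["k_sd_active"]) for r in rois]
    return table, summary


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages over the config's FOV manifest.

    A failing FOV is recorded (stage + message) and the remaining FOVs
    are still processed.
    """
    config.validate()
    params = {**_DEFAULTS, **config.params}
    logger.info("pipeline parameters: %s", params)
    fovs = _load_fovs(config)

    roi_tables, summaries, errors = [], [], []
    for fov in fovs:
        try:
            table, summary = process_fov(fov, params)
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("FOV %s failed: %s", fov.fov_id, exc)
            errors.append({"fov_id": fov.fov_id, "stage": "process_fov",
                           "error": str(exc)})
            continue
        roi_tables.append(table)
        summaries.append(summary)

    roi_table = (pd.concat(roi_tables, ignore_index=True)
                 if roi_tables else pd.DataFrame())
    fov_table = pd.DataFrame([{
        "fov_id": s.fov_id, "animal_id": s.animal_id,
        "group_label": s.group_label, "n_synapses": s.n_synapses,
        "fraction_active": s.fraction_active, "mean_uptake": s.mean_uptake,
        "mean_gz_expression": s.mean_gz_expression,
    } for s in summaries])

    endpoint = params["endpoint"]
    animal_table = (quant.aggregate_per_animal(summaries, value=endpoint)
                    if summaries else pd.DataFrame())

    if params["detrend_covariate"] and len(fov_table):
        cov_by_fov = {}
        for fov in fovs:
            cov = fov.detector_gain
            if params["detrend_covariate"] == "gain_x_laser":
                cov *= fov.laser_power
            cov_by_fov[fov.fov_id] = cov
        fov_table["covariate"] = fov_table["fov_id"].map(cov_by_fov)
        fov_table[endpoint] = quant.detrend_index(
            fov_table[endpoint], fov_table["covariate"],
            fov_table["group_label"])
        summaries2 = [quant.FOVSummary(
            fov_id=r.fov_id, n_synapses=r.n_synapses,
            fraction_active=r.fraction_active, mean_uptake=r.mean_uptake,
            mean_gz_expression=r.mean_gz_expression, animal_id=r.animal_id,
            group_label=r.group_label)
            for r in fov_table.itertuples()]
        animal_table = quant.aggregate_per_animal(summaries2, value=endpoint)

    if len(animal_table) and animal_table["group_label"].nunique() > 1:
        stats_table = gstats.compare_groups(
            animal_table["value"].to_numpy(),
            animal_table["group_label"].to_numpy(),
            n_perm=params["n_perm"], seed=config.seed)
    else:
        stats_table = pd.DataFrame()

    result = PipelineResult(roi_table=roi_table, fov_table=fov_table,
                            animal_table=animal_table,
                            stats_table=stats_table, params=params,
                            errors=errors)
    if config.outdir is not None:
        _write_outputs(result, config.outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.roi_table.to_csv(outdir / "rois.csv", index=False)
    result.fov_table.to_csv(outdir / "fovs.csv", index=False)
    result.animal_table.to_csv(outdir / "animals.csv", index=False)
    result.stats_table.to_csv(outdir / "stats.csv", index=False)
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(result.params, fh)


def write_report(result: PipelineResult, outdir: str | Path,
                 make_figures: bool = True) -> Path:
    """Human-readable summary: group means ± sem, test results with
    Holm-adjusted p, effect sizes; uptake histogram and cumulative
    distribution figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["Group summaries (per animal)", "=" * 32]
    at = result.animal_table
    for g, sub in at.groupby("group_label"):
        v = sub["value"].to_numpy()
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else float("nan")
        lines.append(f"{g}: {v.mean():.4g} ± {sem:.3g} (mean ± sem, n={len(v)})")
    lines += ["", "Comparisons", "=" * 32]
    for row in result.stats_table.itertuples():
        p_holm = getattr(row, "p_holm", row.p_raw)
        lines.append(
            f"{row.group_a} vs {row.group_b}: diff={row.statistic:.4g}, "
            f"p={row.p_raw:.4g}, p(Holm)={p_holm:.4g}, d={row.cohens_d:.3g} "
            f"[{row.method}]")
    if result.errors:
        lines += ["", "Errors", "=" * 32]
        lines += [f"{e['fov_id']} ({e['stage']}): {e['error']}" for e in result.errors]
    report = outdir / "report.txt"
    report.write_text("\n".join(lines) + "\n")

    if make_figures and len(result.roi_table):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for g, sub in result.roi_table.merge(
                result.fov_table[["fov_id", "group_label"]],
                on="fov_id").groupby("group_label"):
            vals = sub["mean_sb"] - sub["bg_sb_mean"]
            axes[0].hist(vals, bins=30, alpha=0.5, label=str(g))
            xs = np.sort(vals)
            axes[1].plot(xs, np.arange(1, len(xs) + 1) / len(xs), label=str(g))
        axes[0].set_xlabel("tracer excess (a.u.)")
        axes[0].set_ylabel("synapse count")
        axes[1].set_xlabel("tracer excess (a.u.)")
        axes[1].set_ylabel("cumulative fraction")
        for ax in axes:
            ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "uptake_distributions.png", dpi=120)
        plt.close(fig)
    return report
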