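"""End-to-end orchestration: simulate -> generate -> segment -> analyze.

A run is fully described by a :class:`RunConfig` (loadable from a TOML
file; CLI flags override file values).  Per-item randomness is derived
by hashing the master seed with stable string labels, so re-running with
the same config reproduces every output byte-identically and adding
conditions never perturbs existing ones.

Outputs under ``output_dir``::

    images/               rendered slice photographs and truth masks (PNG)
    results/truth.csv     generator ground truth, one row per image
    results/measured.csv  segmentation measurements, one row per image
    results/table.csv     wide per-(voltage, rep) measurement table
    results/correlations.csv
    results/electrical.csv
    results/summary.json  monotonicity check, recovery slope, t-test
    figures/*.png         correlation heat map, measured-vs-truth scatter
    manifest.json         file list with SHA-256 digests and the seed
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import electrical as elec_mod
from . import segmentation as seg_mod
from . import stats as stats_mod
from .field_model import GridSpec
from .synthetic_staining import (
    DEFAULT_VOLTAGES,
    ExperimentBundle,
    KineticsParams,
    RenderParams,
    default_conditions,
    generate_experiment,
)

__all__ = ["RunConfig", "RunReport", "run_full"]

logger = logging.getLogger("tuberfield")


@dataclass
class RunConfig:
    """Complete configuration of one reproducible run."""

    voltages: tuple[float, ...] = DEFAULT_VOLTAGES
    reps: int = 3
    ire_threshold: float = 250.0
    re_threshold: float = 100.0
    grid: GridSpec = field(default_factory=GridSpec)
    render: RenderParams = field(default_factory=RenderParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    electrical: elec_mod.ElectricalParams = field(
        default_factory=elec_mod.ElectricalParams
    )
    master_seed: int = 0
    output_dir: Path = Path("tuberfield_run")

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if len(self.voltages) == 0:
            raise ValueError("voltages must be non-empty")
        if self.re_threshold >= self.ire_threshold:
            raise ValueError("re_threshold must be below ire_threshold")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides take precedence."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {}
        if "voltages" in raw:
            kwargs["voltages"] = tuple(float(v) for v in raw["voltages"])
        for key in ("reps", "ire_threshold", "re_threshold", "master_seed",
                    "output_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "grid" in raw:
            kwargs["grid"] = GridSpec(**raw["grid"])
        if "render" in raw:
            kwargs["render"] = RenderParams(**raw["render"])
        if "kinetics" in raw:
            kwargs["kinetics"] = KineticsParams(**raw["kinetics"])
        if "electrical" in raw:
            kwargs["electrical"] = elec_mod.ElectricalParams(**raw["electrical"])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class RunReport:
    """What a finished run produced."""

    config: RunConfig
    truth: pd.DataFrame
    measured: pd.DataFrame
    table: pd.DataFrame
    correlations: pd.DataFrame | None
    summary: dict
    manifest: dict
    output_dir: Path


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending item."""

    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on '{item}': {cause}")
        self.stage = stage
        self.item = item
        self.__cause__ = cause


def _save_png(array: np.ndarray, path: Path) -> None:
    if array.dtype == bool:
        array = array.astype(np.uint8) * 255
    Image.fromarray(array).save(path)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _bundle_stem(bundle) -> str:
    voltage, modality, time_h = bundle.condition
    return f"{voltage:g}Vcm_{modality}_{time_h:g}h_seed{bundle.seed}"


def _measure_bundles(experiment: ExperimentBundle,
                     image_dir: Path) -> pd.DataFrame:
    """Segment every rendered image; one measured row per image."""
    rows = []
    for bundle, (_, truth_row) in zip(
        experiment.bundles, experiment.truth_table.iterrows()
    ):
        stem = f"{_bundle_stem(bundle)}_rep{truth_row['rep']}"
        try:
            calib = seg_mod.calibrate_scale(bundle.image)
            modality = bundle.condition[1]
            if modality == "ttc":
                result = seg_mod.segment_ttc(bundle.image, calib)
                measured = {
                    "measured_white_cm2": result.areas["white"],
                    "measured_red_cm2": result.areas["red"],
                    "measured_melanin_cm2": np.nan,
                }
            else:
                result = seg_mod.segment_melanin(bundle.image, calib)
                measured = {
                    "measured_white_cm2": np.nan,
                    "measured_red_cm2": np.nan,
                    "measured_melanin_cm2": result.areas["melanin"],
                }
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("segment", stem, exc) from exc
        rows.append({
            "image_id": stem,
            "condition_id": truth_row["condition_id"],
            "voltage_vcm": truth_row["voltage_vcm"],
            "modality": truth_row["modality"],
            "time_h": truth_row["time_h"],
            "rep": truth_row["rep"],
            **measured,
            "pixels_per_mm_est": calib.pixels_per_mm,
            "qc_flags": ";".join(result.qc_flags),
        })
        if image_dir is not None:
            _save_png(bundle.image, image_dir / f"{stem}.png")
            for name, mask in bundle.truth_masks.items():
                _save_png(mask, image_dir / f"{stem}_truth_{name}.png")
            for name, mask in result.masks.items():
                _save_png(mask, image_dir / f"{stem}_seg_{name}.png")
    return pd.DataFrame(rows)


def _wide_table(truth: pd.DataFrame, measured: pd.DataFrame) -> pd.DataFrame:
    """Per-(voltage, rep) wide table combining both modalities, measured areas."""
    ttc = measured[measured["modality"] == "ttc"]
    mel = measured[measured["modality"] == "melanin"]
    ttc_truth = truth[truth["modality"] == "ttc"]
    keys = ["voltage_vcm", "rep"]
    wide = (
        ttc[keys + ["measured_white_cm2", "measured_red_cm2"]]
        .rename(columns={"measured_white_cm2": "ttc_white_area_cm2",
                         "measured_red_cm2": "ttc_red_area_cm2"})
        .merge(
            mel[keys + ["measured_melanin_cm2"]]
            .rename(columns={"measured_melanin_cm2": "melanin_area_cm2"}),
            on=keys, how="outer",
        )
        .merge(
            ttc_truth[keys + ["current_A", "conductivity_ratio"]],
            on=keys, how="left",
        )
        .sort_values(keys)
        .reset_index(drop=True)
    )
    wide.insert(0, "condition_id",
                wide["voltage_vcm"].map(lambda v: f"{v:g}Vcm"))
    return wide


def run_full(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts.

    Stages: field simulation (one linear solve, rescaled per voltage),
    synthetic image + electrical generation, ruler calibration and
    segmentation of every image, statistics (correlation heat map and a
    paired t-test of melanin vs TTC-white areas), monotonicity and
    recovery summaries, and a manifest of every written file.
    """
    out = Path(config.output_dir)
    for sub in ("images", "results", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    logger.info("generating experiment (seed=%d)", config.master_seed)
    try:
        experiment = generate_experiment(
            conditions=default_conditions(config.voltages),
            reps=config.reps,
            kin=config.kinetics,
            params=config.render,
            electrical_params=config.electrical,
            master_seed=config.master_seed,
            grid=config.grid,
            ire_threshold=config.ire_threshold,
            re_threshold=config.re_threshold,
        )
    except Exception as exc:
        raise StageError("generate", "experiment", exc) from exc

    truth = experiment.truth_table
    measured = _measure_bundles(experiment, out / "images")
    table = _wide_table(truth, measured)

    # statistics
    correlations: pd.DataFrame | None = None
    ttest: dict | None = None
    n_points = len(table.dropna())
    if n_points >= 3:
        try:
            correlations = stats_mod.correlation_heatmap(table.dropna())
            stats_mod.heatmap_to_png(correlations, out / "figures" / "heatmap.png")
        except stats_mod.DegenerateDataError as exc:
            logger.warning("correlation skipped: %s", exc)
    else:
        logger.warning("correlation skipped: only %d complete rows", n_points)
    if config.reps >= 2 and n_points >= 2:
        try:
            res = stats_mod.paired_ttest(
                table.dropna()["melanin_area_cm2"],
                table.dropna()["ttc_white_area_cm2"],
            )
            ttest = {"t": res.t, "p": res.p, "stars": res.stars, "n": res.n}
        except stats_mod.DegenerateDataError as exc:
            logger.warning("t-test skipped: %s", exc)
    else:
        logger.info("t-test skipped: insufficient replication")

    # summaries: voltage monotonicity of truth IRE area, recovery slope
    ttc_truth = truth[truth["modality"] == "ttc"]
    mean_by_v = ttc_truth.groupby("voltage_vcm")["truth_ire_cm2"].mean()
    monotone = bool(np.all(np.diff(mean_by_v.to_numpy()) > 0))

    merged = measured.merge(
        truth[["condition_id", "rep", "truth_ire_cm2"]],
        on=["condition_id", "rep"],
    )
    ttc_rows = merged[merged["modality"] == "ttc"].dropna(
        subset=["measured_white_cm2"]
    )
    if len(ttc_rows) >= 2 and ttc_rows["truth_ire_cm2"].var() > 0:
        slope = float(np.polyfit(ttc_rows["truth_ire_cm2"],
                                 ttc_rows["measured_white_cm2"], 1)[0])
    else:
        slope = float("nan")

    summary = {
        "master_seed": config.master_seed,
        "n_images": len(experiment.bundles),
        "ire_area_monotone_in_voltage": monotone,
        "mean_truth_ire_cm2_by_voltage": {
            f"{v:g}": float(a) for v, a in mean_by_v.items()
        },
        "white_recovery_slope": slope,
        "melanin_vs_ttc_paired_ttest": ttest,
    }

    # scatter figure: measured vs truth, white class
    _scatter_figure(ttc_rows, out / "figures" / "recovery_scatter.png")

    results = out / "results"
    truth.to_csv(results / "truth.csv", index=False)
    measured.to_csv(results / "measured.csv", index=False)
    table.to_csv(results / "table.csv", index=False)
    experiment.electrical_table.to_csv(results / "electrical.csv", index=False)
    if correlations is not None:
        correlations.to_csv(results / "correlations.csv", index=False)
    with open(results / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = _build_manifest(out, config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunReport(
        config=config, truth=truth, measured=measured, table=table,
        correlations=correlations, summary=summary, manifest=manifest,
        output_dir=out,
    )


def _scatter_figure(ttc_rows: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if len(ttc_rows):
        ax.scatter(ttc_rows["truth_ire_cm2"], ttc_rows["measured_white_cm2"],
                   s=25, alpha=0.8)
        lim = max(float(ttc_rows["truth_ire_cm2"].max()),
                  float(ttc_rows["measured_white_cm2"].max())) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=1, label="identity")
        ax.legend()
    ax.set_xlabel("generator truth IRE area (cm$^2$)")
    ax.set_ylabel("segmented white area (cm$^2$)")
    ax.set_title("Area recovery, TTC white class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _build_manifest(out: Path, config: RunConfig) -> dict:
    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(out))] = {
                "sha256": _sha256(path),
                "bytes": path.stat().st_size,
            }
    cfg = asdict(config)
    cfg["output_dir"] = str(cfg["output_dir"])
    return {"master_seed": config.master_seed, "config": cfg, "files": files}
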