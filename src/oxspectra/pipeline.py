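"""End-to-end orchestration: simulate or load, preprocess, analyze, report.

``run_pipeline`` sequences the fixed stage order — normalize →
second-derivative → (markers | crop → PCA) → group statistics — and
writes every result as plain CSV plus one YAML manifest that records all
parameters and the seed, so a run can be reproduced exactly from its
manifest. Stages communicate only through in-memory objects and the
declared output files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra_io import AssayTable, SpectraCollection, read_assay_csv, read_spectra_csv
from .preprocess import SGFilterSpec, preprocess_collection
from .markers import marker_panel, panels_to_frame, relative_to_control, MARKER_NAMES
from .chemometrics import group_centroids, pca
from .assays import assay_table_results, fit_tbars_calibration
from .stats_compare import compare_groups
from .synthetic_data import SyntheticConfig, generate_experiment

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    With ``simulate=True`` the synthetic generator provides spectra and
    assay tables (``seed`` applies); otherwise ``spectra_csv`` (and
    optionally the assay CSVs) are read. ``control_label`` and
    ``stress_label`` must name groups present in the data.
    """

    output_dir: str | Path = "oxspectra_out"
    simulate: bool = True
    seed: int = 0
    spectra_csv: str | None = None
    spectra_layout: str = "wide"
    sidecar: str | None = None
    cd_csv: str | None = None
    tbars_csv: str | None = None
    tbars_standards_csv: str | None = None
    control_label: str = "control"
    stress_label: str = "H2O2"
    sg_window: int = 21
    sg_polyorder: int = 2
    halfwidth: float = 8.0
    pca_regions: tuple[str, ...] = ("full", "fingerprint", "lipid")
    n_components: int = 2
    alpha: float = 0.05
    n_per_group: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pca_regions" in raw:
            raw["pca_regions"] = tuple(raw["pca_regions"])
        return cls(**raw)


def _stats_csv(result: dict, out: Path, stem: str) -> None:
    a = result["anova"]
    pd.DataFrame(
        [{"F": a.F, "df_between": a.df_between, "df_within": a.df_within, "p": a.p}]
    ).to_csv(out / f"{stem}_anova.csv", index=False)
    result["tukey"].to_csv(out / f"{stem}_tukey.csv", index=False)
    pd.DataFrame(
        sorted(result["letters"].items()), columns=["treatment", "letters"]
    ).to_csv(out / f"{stem}_letters.csv", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict with the in-memory results (marker frame, PCA models,
    assay frames, statistics) and the list of files written.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    # ---- load or simulate -------------------------------------------------
    cd_table = tbars_table = None
    tbars_standards = None
    if cfg.simulate:
        logger.info("simulating experiment (seed=%d)", cfg.seed)
        sim_cfg = SyntheticConfig(seed=cfg.seed, n_per_group=cfg.n_per_group)
        exp = generate_experiment(sim_cfg)
        collection = exp.spectra
        cd_table, tbars_table = exp.cd_table, exp.tbars_table
        tbars_standards = exp.tbars_standards
    else:
        if not cfg.spectra_csv:
            raise ValueError("spectra_csv is required when simulate=False")
        collection = read_spectra_csv(cfg.spectra_csv, cfg.spectra_layout,
                                      sidecar=cfg.sidecar)
        if cfg.cd_csv:
            cd_table = read_assay_csv(cfg.cd_csv)
        if cfg.tbars_csv:
            tbars_table = read_assay_csv(cfg.tbars_csv)
        if cfg.tbars_standards_csv:
            std = pd.read_csv(cfg.tbars_standards_csv)
            tbars_standards = tuple(
                zip(std["concentration_um"], std["absorbance"])
            )

    for label in (cfg.control_label, cfg.stress_label):
        if label not in collection.groups:
            raise ValueError(
                f"required group {label!r} missing from the data "
                f"(found {sorted(collection.groups)})"
            )

    # ---- preprocess -------------------------------------------------------
    sg = SGFilterSpec(window=cfg.sg_window, polyorder=cfg.sg_polyorder, deriv=2)
    logger.info("preprocessing %d spectra (SG %d/%d/2)", len(collection),
                cfg.sg_window, cfg.sg_polyorder)
    derived = preprocess_collection(collection, sg)

    # ---- markers ----------------------------------------------------------
    panels = [marker_panel(s) for s in derived]
    rel = relative_to_control(panels, cfg.control_label)
    frame = panels_to_frame(panels)
    frame = frame.merge(
        panels_to_frame(rel).rename(columns={"value": "value_rel_control"}),
        on=["sample_id", "treatment", "marker"],
    )
    frame.to_csv(out / "markers.csv", index=False)
    written.append("markers.csv")

    marker_stats = {}
    for m in MARKER_NAMES:
        res = compare_groups(frame[frame["marker"] == m], "value", alpha=cfg.alpha)
        marker_stats[m] = res
        _stats_csv(res, out, f"stats_marker_{m}")
        written += [f"stats_marker_{m}_anova.csv", f"stats_marker_{m}_tukey.csv",
                    f"stats_marker_{m}_letters.csv"]

    # ---- PCA --------------------------------------------------------------
    pca_models = {}
    for region in cfg.pca_regions:
        model = pca(derived, region=region, n_components=cfg.n_components)
        pca_models[region] = model
        scores = pd.DataFrame(
            model.scores,
            columns=[f"PC{i+1}" for i in range(model.n_components)],
        )
        scores.insert(0, "sample_id", model.sample_ids)
        scores.insert(
            1, "treatment",
            [next(t for t, mem in model.groups.items() if sid in mem)
             for sid in model.sample_ids],
        )
        scores.to_csv(out / f"pca_{region}_scores.csv", index=False)
        loadings = pd.DataFrame(
            model.loadings.T,
            columns=[f"PC{i+1}" for i in range(model.n_components)],
        )
        loadings.insert(0, "wavenumber", model.wavenumbers)
        loadings.to_csv(out / f"pca_{region}_loadings.csv", index=False)
        pd.DataFrame(
            {
                "component": np.arange(1, model.n_components + 1),
                "explained_variance_fraction": model.explained_variance_fraction,
            }
        ).to_csv(out / f"pca_{region}_variance.csv", index=False)
        written += [f"pca_{region}_scores.csv", f"pca_{region}_loadings.csv",
                    f"pca_{region}_variance.csv"]
        logger.info("PCA %s: %d components explain %.1f%% of variance",
                    region, model.n_components,
                    100 * model.cumulative_variance())

    # ---- assays -----------------------------------------------------------
    assay_stats = {}
    assay_frames = {}
    if cd_table is not None:
        cd = assay_table_results(cd_table, "CD")
        cd.to_csv(out / "assay_cd.csv", index=False)
        written.append("assay_cd.csv")
        assay_frames["CD"] = cd
        res = compare_groups(cd, "concentration_per_million_cells", alpha=cfg.alpha)
        assay_stats["CD"] = res
        _stats_csv(res, out, "stats_assay_cd")
        written += ["stats_assay_cd_anova.csv", "stats_assay_cd_tukey.csv",
                    "stats_assay_cd_letters.csv"]
    if tbars_table is not None:
        if tbars_standards is None:
            raise ValueError("TBARS table given without calibration standards")
        curve = fit_tbars_calibration(tbars_standards)
        tb = assay_table_results(tbars_table, "TBARS", curve=curve)
        tb.to_csv(out / "assay_tbars.csv", index=False)
        written.append("assay_tbars.csv")
        assay_frames["TBARS"] = tb
        res = compare_groups(tb, "concentration_per_million_cells", alpha=cfg.alpha)
        assay_stats["TBARS"] = res
        _stats_csv(res, out, "stats_assay_tbars")
        written += ["stats_assay_tbars_anova.csv", "stats_assay_tbars_tukey.csv",
                    "stats_assay_tbars_letters.csv"]

    # ---- manifest ---------------------------------------------------------
    manifest = {"config": {k: (str(v) if isinstance(v, Path)
                               else list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(cfg).items()},
                "outputs": written}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return {
        "markers": frame,
        "marker_stats": marker_stats,
        "pca": pca_models,
        "pca_centroids": {r: group_centroids(m) for r, m in pca_models.items()},
        "assays": assay_frames,
        "assay_stats": assay_stats,
        "output_dir": out,
        "written": written + ["manifest.yaml"],
    }
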