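"""End-to-end orchestration of the regional assemblage analysis.

One run covers four site sets (all sites plus the three catchment-size
sections) and produces, for each:

* EMS structure classifications on ordination axes 1 and 2 (a
  Table-2-style export: Abs/Re statistics, null moments, z, p, Morisita
  index, best-fit structure);
* per-site diversity summaries with between-section ANOVA + Tukey HSD
  and Bray–Curtis beta dispersion (a long-format export for plotting);
* boosted-regression-tree models of richness (Poisson) and of the
  primary ordination axis (Gaussian), the latter with and without
  spatial PCoA predictors and optionally with a drainage factor
  (Table-3-style evaluations plus long-format influence tables). The
  secondary axis is classified but never modelled against environment —
  the primary axis is the best arrangement of species ranges.

All outputs are plain CSV/JSON plus a manifest that makes reruns
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boost import (
    BRTConfig,
    VARIABLE_CATEGORIES,
    assemble_predictors,
    relative_influence,
    select_n_trees_cv,
)
from .diversity import beta_dispersion, bray_curtis, anova_tukey, diversity_summary
from .ems import MetacommunityStructure
from .matrix import (
    categorize_sites,
    drop_empty_sites,
    filter_rare_taxa,
    to_incidence,
)
from .ordination import (
    DegenerateMatrixError,
    ReciprocalAveraging,
    geographic_distances,
    pcoa,
)
from .synthetic import SyntheticConfig, simulate_study

logger = logging.getLogger(__name__)

TABLE2_COLUMNS = [
    "axis",
    "stream_type",
    "Abs",
    "Abs_mean",
    "Abs_SD",
    "Abs_z",
    "Abs_p",
    "Re",
    "Re_mean",
    "Re_SD",
    "Re_z",
    "Re_p",
    "MI",
    "MI_p",
    "structure",
]


@dataclass
class PipelineConfig:
    """Run configuration for :func:`run_pipeline`."""

    n_null: int = 1000
    alpha: float = 0.05
    breaks: tuple[float, float] = (20.0, 100.0)
    rarefy_n: int = 100
    min_taxon_sites: int = 2
    refilter_subsets: bool = True  # re-apply the rare-taxon filter per section
    axes: tuple[int, ...] = (1, 2)
    spatial: bool = True  # also fit composition models with PCo1/PCo2
    drainage_factor: bool = False
    seed: int = 0
    brt: BRTConfig = field(default_factory=BRTConfig)
    run_brt: bool = True

    def manifest(self) -> dict:
        d = asdict(self)
        d["breaks"] = list(self.breaks)
        d["axes"] = list(self.axes)
        return d


def _ems_for_subset(inc, name, axes, config: PipelineConfig):
    rows, estimators = [], {}
    for axis in axes:
        try:
            est = MetacommunityStructure(
                axis=axis,
                n_sim=config.n_null,
                alpha=config.alpha,
                random_state=config.seed + axis,
            ).fit(inc)
        except DegenerateMatrixError as exc:
            logger.warning("EMS %s axis %d skipped: %s", name, axis, exc)
            continue
        row = est.summary_row()
        row["stream_type"] = name
        rows.append(row)
        estimators[axis] = est
    return rows, estimators


def _brt_models(name, inc_sub, site_sub, config: PipelineConfig, drainage):
    """Richness and composition BRTs for one site set."""
    rows, influences = [], []
    rich = (inc_sub > 0).sum(axis=1).to_numpy()
    ra = ReciprocalAveraging(n_axes=1).fit(inc_sub)
    axis1 = ra.site_scores_[:, 0]
    site_aligned = site_sub.loc[inc_sub.index]
    spatial_vectors = None
    if config.spatial:
        spatial_vectors = pcoa(geographic_distances(site_aligned), n_axes=2).vectors_frame()

    variants = [("richness", "poisson", rich, False, False)]
    variants.append(("composition", "gaussian", axis1, False, False))
    if config.spatial:
        variants.append(("composition_spatial", "gaussian", axis1, True, False))
    if config.drainage_factor and name == "all":
        variants.append(("richness_drainage", "poisson", rich, False, True))
        variants.append(("composition_drainage", "gaussian", axis1, False, True))

    for model_name, loss, y, use_spatial, use_drainage in variants:
        X = assemble_predictors(
            site_aligned,
            pcoa_vectors=spatial_vectors if use_spatial else None,
            section=name,
            include_drainage=use_drainage,
            drainage=drainage,
        )
        cfg = BRTConfig(**{**asdict(config.brt), "loss": loss, "seed": config.seed})
        n_trees, evaluation, model = select_n_trees_cv(X, y, cfg)
        row = {"stream_type": name, "model": model_name, **evaluation.as_row()}
        rows.append(row)
        infl = relative_influence(model, categories=VARIABLE_CATEGORIES)
        infl.insert(0, "model", model_name)
        infl.insert(0, "stream_type", name)
        influences.append(infl)
    return rows, influences


def run_pipeline(
    abundance: pd.DataFrame | None = None,
    site_table: pd.DataFrame | None = None,
    synthetic: SyntheticConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis and return a report bundle (dict of tables).

    Either pass ``abundance`` + ``site_table`` or a ``synthetic`` recipe.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    if synthetic is not None:
        study = simulate_study(synthetic)
        abundance, site_table = study["abundance"], study["sites"]
    if abundance is None or site_table is None:
        raise ValueError("provide abundance + site_table, or a synthetic config")
    site_table = site_table.loc[abundance.index]
    sections = categorize_sites(site_table, breaks=config.breaks)
    drainage = (site_table["y"] > site_table["y"].median()).astype(int) \
        if "y" in site_table.columns else None

    incidence = to_incidence(abundance)

    subsets = {"all": abundance.index}
    for label in sections.unique():
        subsets[label] = abundance.index[sections == label]

    # --- EMS per subset -----------------------------------------------------
    ems_rows, brt_rows, influence_frames = [], [], []
    for name, idx in subsets.items():
        inc_sub = incidence.loc[idx]
        inc_sub = filter_rare_taxa(
            inc_sub,
            min_sites=config.min_taxon_sites if (config.refilter_subsets or name == "all")
            else 1,
        )
        inc_sub, dropped = drop_empty_sites(inc_sub)
        logger.info("EMS subset %s: %d sites x %d taxa (dropped %d empty sites)",
                    name, *inc_sub.shape, len(dropped))
        rows, _ = _ems_for_subset(inc_sub, name, config.axes, config)
        ems_rows.extend(rows)
        if config.run_brt:
            if len(inc_sub) < config.brt.n_folds:
                logger.warning(
                    "BRT %s skipped: %d sites < %d folds",
                    name, len(inc_sub), config.brt.n_folds,
                )
            else:
                brt, infl = _brt_models(name, inc_sub, site_table, config, drainage)
                brt_rows.extend(brt)
                influence_frames.extend(infl)

    table2 = (
        pd.DataFrame(ems_rows)[TABLE2_COLUMNS]
        if ems_rows
        else pd.DataFrame(columns=TABLE2_COLUMNS)
    )

    # --- diversity ----------------------------------------------------------
    div = diversity_summary(abundance, sections, rarefy_n=config.rarefy_n)
    disp = beta_dispersion(bray_curtis(abundance), sections)
    div["beta_dispersion"] = disp.distances_
    tests = {}
    for metric in ("richness", "rarefied_richness", "simpson", "beta_dispersion"):
        res = anova_tukey(div[metric].to_numpy(), sections.to_numpy(), alpha=config.alpha)
        tests[metric] = {
            "F": res["F"],
            "df": list(res["df"]),
            "p": res["p"],
            "letters": res["letters"],
            "tukey": res["tukey"].to_dict(orient="records"),
        }

    report = {
        "table2": table2,
        "diversity": div.reset_index(),
        "diversity_tests": tests,
        "manifest": {
            "version": __version__,
            "config": config.manifest(),
            "synthetic": synthetic.manifest() if synthetic is not None else None,
            "n_sites": int(len(abundance)),
            "n_taxa": int(abundance.shape[1]),
            "sections": sections.value_counts().to_dict(),
            "runtime_s": None,  # filled below
        },
    }
    if config.run_brt:
        report["table3"] = pd.DataFrame(brt_rows)
        report["influence"] = pd.concat(influence_frames, ignore_index=True)
    report["manifest"]["runtime_s"] = round(time.time() - t0, 3)
    return report


def write_report(report: dict, outdir) -> list[Path]:
    """Write the report bundle as CSV/JSON files; returns written paths."""
    if not report:
        raise ValueError("empty report bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("table2", "table3", "diversity", "influence"):
        if name in report:
            path = outdir / f"{name}.csv"
            report[name].to_csv(path, index=False, float_format="%.10g")
            written.append(path)
    for name in ("diversity_tests", "manifest"):
        if name in report:
            path = outdir / f"{name}.json"
            payload = dict(report[name])
            if name == "manifest":
                payload["runtime_s"] = None  # keep reruns byte-identical
            path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
            written.append(path)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
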