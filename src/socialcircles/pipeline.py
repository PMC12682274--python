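"""End-to-end pipeline: read/simulate -> filter -> fit -> structure -> attribute.

Produces a report bundle of plain CSV tables (per-ego eta estimates, filter
audit, group structure summary, community assignments, attribution outputs,
per-species eta histogram) plus a JSON manifest recording the configuration,
seeds and library versions for exact re-runs.  All tables are built in
memory first and written together, so a failed run leaves no partial bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import core, features, modularity, network_io, synth

__all__ = ["PipelineConfig", "run_pipeline", "eta_histogram"]

logger = logging.getLogger("socialcircles")

#: eta histogram bin edges: width 1.0 over [-10, 15]
HIST_RANGE = (-10.0, 15.0)
HIST_WIDTH = 1.0


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults are the study's settings."""

    interactions_path: str | None = None
    metadata_path: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    min_group_size: int = 6
    min_partners: int = 5
    delta: float = 0.025
    solver_tol: float = core.SOLVER_TOL
    modularity_seed: int = 0
    attribution_seed: int = 0
    attribution_hyperparams: dict = field(default_factory=dict)
    pdp_grid_size: int = 20
    outdir: str = "socialcircles_out"
    write_inputs: bool = True  # in synthetic mode, also emit the input CSVs

    def validate(self) -> None:
        if self.synthetic is None and (
            self.interactions_path is None or self.metadata_path is None
        ):
            raise ValueError(
                "either synthetic config or both interactions_path and "
                "metadata_path must be given"
            )


def eta_histogram(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-species eta histogram; frequency as proportion of individuals."""
    edges = np.arange(HIST_RANGE[0], HIST_RANGE[1] + HIST_WIDTH, HIST_WIDTH)
    rows = []
    for species, sub in estimates.groupby("species"):
        counts, _ = np.histogram(sub["eta"].clip(edges[0], edges[-1]), bins=edges)
        n = len(sub)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"species": species, "bin_low": lo, "bin_high": hi,
                 "count": int(c), "proportion": c / n if n else 0.0}
            )
    return pd.DataFrame(rows)


def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        return str(o)

    fields = {k: v for k, v in asdict(config).items() if k != "outdir"}
    payload = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle to config.outdir.

    Returns the bundle as a dict of DataFrames keyed by output name.  Stages:
    input (files or synthetic generator), inclusion filters with audit,
    per-ego maximum-likelihood eta fits with confidence intervals, group
    modularity and mean-eta summary, boosted-tree attribution (skipped with
    a log message when fewer than 30 egos are retained), and the per-species
    eta histogram.
    """
    config.validate()
    bundle: dict[str, pd.DataFrame] = {}

    # --- stage: input ---
    truth = None
    if config.synthetic is not None:
        cohort = synth.generate_cohort(config.synthetic)
        records = [
            network_io.InteractionRecord(
                group_id=r.group_id, actor_id=r.actor_id,
                receiver_id=r.receiver_id, weight=float(r.weight),
            )
            for r in cohort.interactions.itertuples(index=False)
        ]
        # aggregate any repeated dyads the same way the reader would
        meta = [
            network_io.IndividualMeta(
                individual_id=m.individual_id, group_id=m.group_id,
                species=m.species, sex=m.sex, age=float(m.age), habitat=m.habitat,
            )
            for m in cohort.metadata.itertuples(index=False)
        ]
        truth = cohort.truth
    else:
        try:
            records = network_io.read_interactions(config.interactions_path)
            meta = network_io.read_metadata(config.metadata_path)
        except (network_io.SchemaError, ValueError) as exc:
            raise network_io.SchemaError(f"[input] {exc}") from exc

    meta_by_id = network_io.metadata_index(meta)
    groups = network_io.build_group_networks(records, meta)

    # --- stage: filters ---
    retained, audit = network_io.apply_filters(
        groups, config.min_group_size, config.min_partners
    )
    logger.info(
        "filters: %d/%d groups, %d/%d egos retained",
        audit.groups_retained, audit.groups_in, audit.egos_retained, audit.egos_in,
    )
    for iid, reason in audit.exclusions:
        logger.debug("excluded %s: %s", iid, reason)
    bundle["filter_audit"] = audit.to_frame()

    # --- stage: per-ego fits ---
    est_rows = []
    fits_by_group: dict[str, list[core.CircleFitContinuous]] = {}
    for grp, tw in retained:
        fit = core.fit_ego(tw, delta=config.delta, tol=config.solver_tol)
        nd = core.normalize_distances(tw)
        m = meta_by_id[tw.ego_id]
        est_rows.append(
            {"ego_id": tw.ego_id, "group_id": grp.group_id, "species": m.species,
             "sex": m.sex, "age": m.age, "habitat": m.habitat,
             "group_size": grp.group_size, "L": tw.L, "sigma": nd.sigma,
             "t_bar": nd.t_bar, "eta": fit.eta, "ci_low": fit.ci_low,
             "ci_high": fit.ci_high, "regime": fit.regime.value}
        )
        fits_by_group.setdefault(grp.group_id, []).append(fit)
    estimates = pd.DataFrame(est_rows)
    bundle["eta_estimates"] = estimates

    # --- stage: group structure ---
    groups_with_fits = [g for g in groups if g.group_id in fits_by_group]
    species_of_group = {
        g.group_id: meta_by_id[next(iter(g.members))].species for g in groups
    }
    summaries = modularity.group_structure_table(
        groups_with_fits, fits_by_group, species_of_group, seed=config.modularity_seed
    )
    bundle["group_summary"] = modularity.structure_frame(summaries)
    assign_rows = []
    for g in groups_with_fits:
        part = modularity.detect_communities(
            modularity.symmetrize(g), seed=config.modularity_seed
        )
        for iid, c in sorted(part.assignment.items()):
            assign_rows.append({"group_id": g.group_id, "individual_id": iid, "community": c})
    bundle["community_assignments"] = pd.DataFrame(assign_rows)

    # --- stage: attribution ---
    if len(estimates) >= features.MIN_ROWS:
        table = features.build_feature_table(estimates, meta)
        result = features.attribution_analysis(
            table,
            hyperparams=config.attribution_hyperparams or None,
            seed=config.attribution_seed,
            grid_size=config.pdp_grid_size,
        )
        bundle["importance"] = pd.DataFrame(
            sorted(result.global_importance.items(), key=lambda kv: -kv[1]),
            columns=["feature", "importance"],
        )
        shap_df = result.shap_matrix.copy()
        shap_df["base_value"] = result.base_value
        bundle["shap_values"] = shap_df
        for f, curve in result.pdp_curves.items():
            bundle[f"pdp_{f}"] = curve
    else:
        logger.info(
            "attribution skipped: %d egos retained, need %d",
            len(estimates), features.MIN_ROWS,
        )

    # --- stage: report ---
    bundle["eta_histogram"] = eta_histogram(estimates)
    if truth is not None:
        bundle["truth"] = truth

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    manifest = {
        "config_digest": _config_digest(config),
        "seeds": {
            "synthetic": config.synthetic.seed if config.synthetic else None,
            "modularity": config.modularity_seed,
            "attribution": config.attribution_seed,
        },
        "filters": {
            "min_group_size": config.min_group_size,
            "min_partners": config.min_partners,
        },
        "delta": config.delta,
        "versions": _versions(),
        "outputs": sorted(f"{n}.csv" for n in bundle),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def _versions() -> Mapping[str, str]:
    import networkx
    import scipy
    import xgboost

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "xgboost": xgboost.__version__,
    }
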