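"""End-to-end orchestration: data -> summaries -> bias audit ->
covariate matching -> per-species model selection -> report bundle.

A run either simulates a dataset (no external data) or reads CSV
tables.  Every stage writes its table to the output directory together
with a manifest recording inputs, parameters, seed, per-stage row
counts, match-distance quantiles and every population dropped by a
filter (and why) — rerunning with an identical configuration
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .matching import match_sites
from .modelsel import (
    CANDIDATE_TERMS,
    ModelSelectionResult,
    candidate_df,
    lrt_abundance_mixed,
    select_models,
)
from .morphometrics import BiasAudit, bias_audit, population_summaries
from .simulate import BASELINE_COLLECTION, BIASED_COLLECTION, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sensitivity_rerun"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` or ``inputs`` must be provided.
    ``inputs`` maps table names (specimens, baseline [optional],
    sst_grid, npp_grid, assemblage) to CSV paths.
    """

    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    outdir: str | Path = "foramsize_run"
    radius_km: float = 300.0
    delta_threshold: float = 2.0
    candidates: tuple[str, ...] | None = None
    response_metric: str | None = None   # None: take the audit winner, else p95
    min_individuals: int = 1
    exclude_sites: tuple[str, ...] = ()
    exclude_collections: tuple[str, ...] = ()
    abundance_variant: str = "nearest"   # or "radius_median"
    center: bool = False
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("provide exactly one of simulation= or inputs=")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input path(s) not found: {missing}")
        if self.abundance_variant not in ("nearest", "radius_median"):
            raise ValueError("abundance_variant must be 'nearest' or 'radius_median'")
        if self.min_individuals < 1:
            raise ValueError("min_individuals must be >= 1")
        if self.candidates is not None:
            unknown = [c for c in self.candidates if c not in CANDIDATE_TERMS]
            if unknown:
                raise ValueError(f"unknown candidate label(s): {unknown}")


@dataclass
class PipelineResult:
    config: RunConfig
    summaries: pd.DataFrame
    audit: BiasAudit | None
    response_metric: str
    site_covariates: pd.DataFrame
    abundance: pd.DataFrame
    populations: pd.DataFrame
    selections: dict[str, ModelSelectionResult]
    unanalyzable: dict[str, str]
    mixed: object | None
    manifest: dict = field(repr=False)
    outdir: Path = None

    def plausible_sets(self) -> dict[str, tuple[str, ...]]:
        return {sp: res.plausible for sp, res in self.selections.items()}


def _load_tables(cfg: RunConfig):
    if cfg.simulation is not None:
        ds = simulate_dataset(cfg.simulation)
        specimens = pd.concat([ds.specimens_biased, ds.specimens], ignore_index=True)
        return {
            "specimens": specimens,
            "sst_grid": ds.grids["sst"],
            "npp_grid": ds.grids["npp"],
            "assemblage": ds.assemblage,
            "analysis_collection": BIASED_COLLECTION,
            "baseline_collection": BASELINE_COLLECTION,
            "source": {"mode": "simulate", "sim_config": cfg.simulation.to_dict()},
        }
    tables = {name: pd.read_csv(path) for name, path in cfg.inputs.items()}
    specimens = tables["specimens"]
    baseline_collection = None
    if "baseline" in tables:
        base = tables["baseline"]
        collections = set(specimens.get("collection", pd.Series(["collection"])).unique())
        if "collection" not in base.columns:
            base = base.assign(collection="baseline")
        if "collection" not in specimens.columns:
            specimens = specimens.assign(collection="collection")
        baseline_collection = str(base["collection"].iloc[0])
        specimens = pd.concat([specimens, base], ignore_index=True)
        analysis_collection = str(sorted(collections - {baseline_collection})[0]
                                  if collections - {baseline_collection} else "collection")
    else:
        if "collection" not in specimens.columns:
            specimens = specimens.assign(collection="collection")
        analysis_collection = str(specimens["collection"].iloc[0])
    return {
        "specimens": specimens,
        "sst_grid": tables["sst_grid"],
        "npp_grid": tables["npp_grid"],
        "assemblage": tables["assemblage"],
        "analysis_collection": analysis_collection,
        "baseline_collection": baseline_collection,
        "source": {"mode": "csv", "inputs": dict(cfg.inputs)},
    }


def _quantiles(x) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return {}
    return {q: float(np.quantile(x, float(q))) for q in ("0.5", "0.9", "1.0")}


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages in order and write the report bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: (v if not dataclasses.is_dataclass(v) else v.to_dict())
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("simulation",)
        },
        "seed": cfg.seed,
        "stages": {},
    }
    if cfg.simulation is not None:
        manifest["parameters"]["simulation"] = cfg.simulation.to_dict()
    manifest["parameters"]["outdir"] = str(cfg.outdir)

    # -- stage: load/simulate ----------------------------------------
    try:
        data = _load_tables(cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", str(e)) from e
    specimens = data["specimens"]
    manifest["source"] = data["source"]
    manifest["stages"]["load"] = {"n_specimens": int(len(specimens))}

    # -- stage: filters ----------------------------------------------
    dropped = []
    if cfg.exclude_sites:
        mask = specimens["site_id"].isin(cfg.exclude_sites)
        for sid, cnt in specimens.loc[mask].groupby("site_id").size().items():
            dropped.append({"site_id": str(sid), "n_specimens": int(cnt),
                            "reason": "excluded site"})
        specimens = specimens.loc[~mask]
    if cfg.exclude_collections:
        mask = specimens["collection"].isin(cfg.exclude_collections)
        specimens = specimens.loc[~mask]
    manifest["stages"]["filter"] = {
        "n_specimens": int(len(specimens)),
        "dropped": dropped,
        "exclude_sites": list(cfg.exclude_sites),
        "exclude_collections": list(cfg.exclude_collections),
    }
    if len(specimens) == 0:
        raise StageError("filter", "no specimens left after filters")

    # -- stage: population summaries ---------------------------------
    try:
        summaries = population_summaries(specimens)
    except ValueError as e:
        raise StageError("summaries", str(e)) from e
    manifest["stages"]["summaries"] = {"n_populations": int(len(summaries))}

    # -- stage: bias audit -------------------------------------------
    audit = None
    analysis_col = data["analysis_collection"]
    baseline_col = data["baseline_collection"]
    if baseline_col is not None and analysis_col != baseline_col:
        sc = summaries[summaries["collection"] == analysis_col]
        sb = summaries[summaries["collection"] == baseline_col]
        try:
            audit = bias_audit(sc, sb, min_individuals=cfg.min_individuals)
        except ValueError as e:
            raise StageError("audit", str(e)) from e
        manifest["stages"]["audit"] = {
            "n_pairs": int(audit.table["n_pairs"].iloc[0]),
            "selected_metric": audit.selected_metric,
            "mse": {r["metric"]: r["mse"] for _, r in audit.table.iterrows()},
        }
    response_metric = cfg.response_metric or (audit.selected_metric if audit else "p95")

    # -- stage: covariate matching -----------------------------------
    ana = summaries[summaries["collection"] == analysis_col] if "collection" in summaries else summaries
    site_coords = (
        specimens[specimens["collection"] == analysis_col]
        [["site_id", "latitude", "longitude"]].drop_duplicates("site_id")
        .sort_values("site_id").reset_index(drop=True)
    )
    try:
        site_cov, abundance = match_sites(
            site_coords, data["sst_grid"], data["npp_grid"], data["assemblage"],
            radius_km=cfg.radius_km,
        )
    except ValueError as e:
        raise StageError("match", str(e)) from e
    manifest["stages"]["match"] = {
        "n_sites": int(len(site_cov)),
        "radius_km": cfg.radius_km,
        "distance_quantiles_km": {
            "sst": _quantiles(site_cov["sst_km"]),
            "npp": _quantiles(site_cov["npp_km"]),
            "abundance": _quantiles(site_cov["abund_nearest_km"]),
        },
    }

    # -- stage: populations table ------------------------------------
    ab_col = "abund_nearest" if cfg.abundance_variant == "nearest" else "abund_radius_median"
    pops = ana.merge(site_cov[["site_id", "sst", "npp"]], on="site_id", how="left")
    pops = pops.merge(
        abundance[["site_id", "species", ab_col]].rename(columns={ab_col: "abund"}),
        on=["site_id", "species"], how="left",
    )
    pops["logp95"] = pops[response_metric]
    small = pops["n_individuals"] < cfg.min_individuals
    for _, r in pops.loc[small].iterrows():
        dropped.append({"site_id": str(r["site_id"]), "species": str(r["species"]),
                        "reason": f"n_individuals {int(r['n_individuals'])} < {cfg.min_individuals}"})
    pops = pops.loc[~small]
    unmatched = pops[["sst", "npp", "abund"]].isna().any(axis=1)
    for _, r in pops.loc[unmatched].iterrows():
        dropped.append({"site_id": str(r["site_id"]), "species": str(r["species"]),
                        "reason": "missing matched covariate"})
    pops = pops.loc[~unmatched].reset_index(drop=True)
    manifest["stages"]["populations"] = {
        "n_populations": int(len(pops)),
        "response_metric": response_metric,
        "dropped": [d for d in dropped if "species" in d],
    }

    # -- stage: model selection --------------------------------------
    selections: dict[str, ModelSelectionResult] = {}
    unanalyzable: dict[str, str] = {}
    for sp, grp in pops.groupby("species", sort=True):
        try:
            selections[str(sp)] = select_models(
                grp, response="logp95", candidates=cfg.candidates,
                delta_threshold=cfg.delta_threshold, center=cfg.center,
            )
        except (ValueError, KeyError) as e:
            unanalyzable[str(sp)] = str(e)
            logger.warning("species %s not analyzable: %s", sp, e)
    manifest["stages"]["model_selection"] = {
        "n_species": len(selections),
        "unanalyzable": unanalyzable,
        "per_species_n": {sp: int(res.table["n"].iloc[0]) for sp, res in selections.items()},
    }

    # -- stage: mixed-model LRT --------------------------------------
    mixed = None
    counts = pops.groupby("species").size()
    if len(counts) >= 2 and (counts >= 2).all():
        try:
            mixed = lrt_abundance_mixed(pops, response="logp95")
            manifest["stages"]["mixed_lrt"] = {
                "chi2": mixed.chi2, "df": mixed.df, "p_value": mixed.p_value,
                "boundary": mixed.boundary,
            }
        except Exception as e:  # noqa: BLE001
            manifest["stages"]["mixed_lrt"] = {"error": str(e)}

    result = PipelineResult(
        config=cfg, summaries=summaries, audit=audit, response_metric=response_metric,
        site_covariates=site_cov, abundance=abundance, populations=pops,
        selections=selections, unanalyzable=unanalyzable, mixed=mixed,
        manifest=manifest, outdir=outdir,
    )
    _write_bundle(result)
    return result


def _write_bundle(res: PipelineResult) -> None:
    out = res.outdir
    res.summaries.to_csv(out / "summaries.csv", index=False)
    res.site_covariates.to_csv(out / "site_covariates.csv", index=False)
    res.abundance.to_csv(out / "abundance_matches.csv", index=False)
    res.populations.to_csv(out / "populations.csv", index=False)
    if res.audit is not None:
        res.audit.pairs.to_csv(out / "audit_pairs.csv", index=False)
        res.audit.table.to_csv(out / "audit_table.csv", index=False)
    if res.selections:
        tables = []
        for sp, sel in res.selections.items():
            t = sel.table.copy()
            t.insert(0, "species", sp)
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(out / "model_selection.csv", index=False)
        plaus = pd.DataFrame(
            [(sp, ";".join(sel.plausible), sel.best) for sp, sel in res.selections.items()],
            columns=["species", "plausible_set", "best_model"],
        )
        plaus.to_csv(out / "plausible_sets.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(res))


def _summary_text(res: PipelineResult) -> str:
    lines = ["foramsize pipeline report", "=" * 26, ""]
    if res.audit is not None:
        lines.append(f"bias audit over {int(res.audit.table['n_pairs'].iloc[0])} paired populations:")
        for _, r in res.audit.table.iterrows():
            lines.append(f"  {r['metric']:>6}: MSE {r['mse']:.4f}  mean residual {r['mean_residual']:+.4f}")
        lines.append(f"  selected metric: {res.audit.selected_metric}")
        lines.append("")
    lines.append(f"response variable: log {res.response_metric} of shell area per population")
    lines.append(f"populations analyzed: {len(res.populations)}")
    lines.append("")
    for sp, sel in res.selections.items():
        best = sel.table.iloc[0]
        lines.append(
            f"{sp}: best {best['label']} (AICc {best['aicc']:.2f}, "
            f"R2_adj {best['r2_adj']:.2f}); plausible: {', '.join(sel.plausible)}"
        )
    for sp, why in res.unanalyzable.items():
        lines.append(f"{sp}: not analyzable ({why})")
    if res.mixed is not None:
        lines.append("")
        lines.append(f"mixed-model abundance LRT: {res.mixed}")
    return "\n".join(lines) + "\n"


def sensitivity_rerun(cfg: RunConfig, exclude_sites, outdir=None):
    """Run base and filtered pipelines and diff the plausible sets.

    Returns ``(base_result, filtered_result, diff)`` where ``diff`` has
    one row per species with models entering/leaving the plausible set
    under the filter; species losing all populations are flagged as not
    analyzable and the rest of the run continues.
    """
    base = run_pipeline(cfg)
    fcfg = dataclasses.replace(
        cfg,
        exclude_sites=tuple(cfg.exclude_sites) + tuple(exclude_sites),
        outdir=Path(outdir) if outdir is not None else Path(cfg.outdir) / "sensitivity",
    )
    filt = run_pipeline(fcfg)
    rows = []
    species = sorted(set(base.selections) | set(base.unanalyzable)
                     | set(filt.selections) | set(filt.unanalyzable))
    for sp in species:
        b = set(base.selections[sp].plausible) if sp in base.selections else None
        f = set(filt.selections[sp].plausible) if sp in filt.selections else None
        if f is None:
            rows.append({"species": sp, "status": "not analyzable after filter",
                         "entered": "", "left": ";".join(sorted(b or set()))})
            continue
        if b is None:
            rows.append({"species": sp, "status": "not analyzable in base run",
                         "entered": ";".join(sorted(f)), "left": ""})
            continue
        rows.append({
            "species": sp,
            "status": "unchanged" if b == f else "changed",
            "entered": ";".join(sorted(f - b)),
            "left": ";".join(sorted(b - f)),
        })
    diff = pd.DataFrame(rows, columns=["species", "status", "entered", "left"])
    diff.to_csv(Path(filt.outdir) / "plausible_set_diff.csv", index=False)
    return base, filt, diff
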