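"""End-to-end pipeline: simulate -> networks -> measures -> estimate -> multiplier.

A single seeded, configurable run that writes every intermediate artifact
(CSV edge lists, the per-physician analysis table, coefficient tables,
diagnostics JSON, multiplier deciles) and returns a machine-readable report.
Identical configuration and seed produce an identical report apart from the
timing block.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import ConfigurationError, SimulationConfig, load_config_file
from . import estimation, measures, multiplier as mult, networks as nets, simulate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input mode is active: ``simulation`` (a SimulationConfig
    block) or ``input_dir`` pointing at externally supplied CSV tables with
    the same schema the generator writes.
    """

    output_dir: str = "adoptnet_run"
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    min_shared: int = 1
    year_window: int = 1
    adoption_rule: "int | str" = "median"
    min_per_quarter: int = 0  # cohort filter; 0 disables
    gamma_source: "str | float" = "estimate"  # "estimate" or explicit value
    multiplier_tol: float = 1e-12
    write_graphml: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of 'simulation' and 'input_dir' must be set"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = load_config_file(path)
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown run configuration fields: {sorted(unknown)}")
        return cls(simulation=sim, **data)


def minimal_prescribing_filter(
    prescribing: pd.DataFrame,
    min_per_quarter: int = 1,
    window_quarters: int = measures.ADOPTION_WINDOW_QUARTERS,
) -> pd.Index:
    """Physicians with at least ``min_per_quarter`` class-level prescriptions
    in *every* quarter of the window (the cohort inclusion criterion).

    Class-level counts pool the new drug with the rest of its class.
    """
    all_ids = pd.Index(prescribing["physician_id"].unique(), name="physician_id")
    if min_per_quarter <= 0:
        return all_ids
    rows = prescribing[prescribing["quarter"] <= window_quarters]
    per_quarter = (
        rows.groupby(["physician_id", "quarter"])["n_prescriptions"].sum().unstack(fill_value=0)
    )
    for q in range(1, window_quarters + 1):
        if q not in per_quarter.columns:
            per_quarter[q] = 0
    keep = (per_quarter[list(range(1, window_quarters + 1))] >= min_per_quarter).all(axis=1)
    return keep.index[keep]


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute all stages in order, writing artifacts; returns the run report."""
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    # --- inputs -------------------------------------------------------
    with stage("inputs"):
        if config.simulation is not None:
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg = SimulationConfig.from_dict({**sim_cfg.to_dict(), "seed": config.seed})
            physicians = simulate.generate_physicians(sim_cfg)
            records = simulate.generate_patient_sharing(sim_cfg, physicians)
            affiliations = simulate.generate_affiliations(sim_cfg, physicians)
        else:
            indir = Path(config.input_dir)
            physicians = pd.read_csv(indir / "physicians.csv")
            records = pd.read_csv(indir / "shared_patients.csv")
            affiliations = pd.read_csv(indir / "affiliations.csv")
        report["stages"]["inputs"] = {
            "n_physicians": int(len(physicians)),
            "n_shared_patient_records": int(len(records)),
            "n_affiliation_records": int(len(affiliations)),
        }

    # --- networks -----------------------------------------------------
    with stage("networks"):
        networks = simulate.build_networks(
            physicians, records, affiliations,
            min_shared=config.min_shared, year_window=config.year_window,
        )
        overlap = nets.network_overlap(networks)
        for kind, net in networks.items():
            nets.write_edge_list(net, outdir / f"network_{kind}.csv")
            if config.write_graphml:
                net.to_graphml(outdir / f"network_{kind}.graphml")
        overlap.to_csv(outdir / "network_overlap.csv")
        report["stages"]["networks"] = {
            "edges": {k: int(net.n_edges) for k, net in networks.items()},
            "mean_degree": {
                k: round(float(net.degree().mean()), 3) for k, net in networks.items()
            },
            "overlap": {
                k1: {k2: round(float(overlap.loc[k1, k2]), 4) for k2 in overlap.columns}
                for k1 in overlap.index
            },
        }

    # --- adoption (simulate the outcome when in simulation mode) ------
    with stage("adoption"):
        if config.simulation is not None:
            truth, prescribing = simulate.simulate_adoption(physicians, networks, sim_cfg)
            (outdir / "truth.json").write_text(json.dumps(truth.to_dict()))
        else:
            prescribing = pd.read_csv(Path(config.input_dir) / "prescribing.csv")
        kept = minimal_prescribing_filter(prescribing, config.min_per_quarter)
        report["stages"]["adoption"] = {
            "n_in_cohort_filter": int(len(kept)),
        }

    # --- measures -----------------------------------------------------
    with stage("measures"):
        roster = physicians[physicians["physician_id"].isin(kept)].reset_index(drop=True)
        influence = {
            k: nets.row_normalize(net, roster["physician_id"]) for k, net in networks.items()
        }
        table, spec, outcome = measures.build_analysis_table(
            roster, influence, prescribing, adoption_rule=config.adoption_rule
        )
        table.to_csv(outdir / "analysis_table.csv", index=False)
        report["stages"]["measures"] = {
            "adoption_threshold": int(outcome.threshold),
            "adoption_rate": round(float(table["adopter"].mean()), 4),
            "no_peer_fraction": {
                k: round(float(table[f"nopeer_{k}"].mean()), 4) for k in networks
            },
        }

    # --- estimation ---------------------------------------------------
    with stage("estimation"):
        iv = estimation.fit_2sls(spec, table)
        ols = estimation.fit_ols(spec, table)
        diag = estimation.weak_instrument_diagnostics(iv, table)
        diag.lpm_logit = estimation.compare_lpm_logit(spec, table)
        unreliable = diag.unreliable_endog
        iv.to_frame(unreliable).to_csv(outdir / "estimates_2sls.csv")
        ols.to_frame(unreliable).to_csv(outdir / "estimates_ols.csv")
        (outdir / "diagnostics.json").write_text(json.dumps(diag.to_dict(), indent=2))
        gamma_cols = {k: f"ybar_{k}" for k in networks}
        report["stages"]["estimation"] = {
            "gamma_2sls": {
                k: round(float(iv.params[c]), 4) for k, c in gamma_cols.items()
            },
            "gamma_2sls_se": {
                k: round(float(iv.bse[c]), 4) for k, c in gamma_cols.items()
            },
            "gamma_ols": {
                k: round(float(ols.params[c]), 4) for k, c in gamma_cols.items()
            },
            "first_stage_f": {k: round(v, 2) for k, v in diag.first_stage_f.items()},
            "cragg_donald": round(diag.cragg_donald, 3) if diag.cragg_donald else None,
            "overid_p": None if diag.overid.df == 0 else round(diag.overid.pvalue, 4),
            "unreliable_networks": unreliable,
        }

    # --- multiplier ---------------------------------------------------
    with stage("multiplier"):
        if isinstance(config.gamma_source, str) and config.gamma_source == "estimate":
            gamma = float(iv.params["ybar_P"])
        else:
            gamma = float(config.gamma_source)
        gamma = min(max(gamma, 0.0), 0.99)  # attenuation must keep the series finite
        model = mult.SocialMultiplier(gamma=gamma, method="closed_form")
        model.fit(influence["P"])
        result = model.result_
        degree = networks["P"].degree().reindex(result.multiplier.index)
        volume = table.set_index("physician_id")["class_volume"].reindex(result.multiplier.index)
        summary = mult.decile_targeting(result, degree, volume)
        result.multiplier.rename("multiplier").to_csv(outdir / "multiplier.csv")
        summary.table.to_csv(outdir / "multiplier_deciles.csv", index=False)
        report["stages"]["multiplier"] = {
            "gamma": round(gamma, 4),
            "mean_multiplier": round(float(result.multiplier.mean()), 4),
            "decile_means_degree": [
                round(v, 4) for v in summary.decile_means("degree").tolist()
            ],
            "decile_means_volume": [
                round(v, 4) for v in summary.decile_means("volume").tolist()
            ],
            "ratios": {k: round(v, 4) for k, v in summary.ratios.items()},
        }

    report["timings_s"] = timings
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
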