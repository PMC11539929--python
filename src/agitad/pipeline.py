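"""End-to-end orchestration: generate -> identify -> analyze -> report.

`run_all` wires the modules together for a fully synthetic run and writes
every artifact (bundle tables, ground truth, assignments, attrition,
baseline, utilization and cost tables, run manifest) under one output
directory.  All randomness flows from the generator seed, so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import __version__
from .costs import pppy_costs
from .identify import IdentificationParams, assign_cohorts
from .io import default_code_sets, write_bundle
from .profile import (CCIConfig, baseline_table, config_digest,
                      default_cci_config, render_reports)
from .synth import GeneratorConfig, generate_population
from .utilization import AnalysisParams, summarize_utilization


def _config_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort_params"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                          else v for k, v in config.cohort_params.items()}
    return d


def run_all(config: GeneratorConfig, out_dir,
            code_sets=None,
            id_params: IdentificationParams | None = None,
            analysis_params: AnalysisParams | None = None,
            cci_config: CCIConfig | None = None) -> dict:
    """Run the full synthetic pipeline and write all outputs to ``out_dir``.

    Returns the in-memory results: ``bundle, ground_truth, assignments,
    attrition, baseline, utilization, costs``.
    """
    out_dir = Path(out_dir)
    code_sets = code_sets or default_code_sets()
    id_params = id_params or IdentificationParams()
    analysis_params = analysis_params or AnalysisParams()
    cci_config = cci_config or default_cci_config()

    bundle, truth = generate_population(config, code_sets=code_sets)
    write_bundle(bundle, out_dir / "bundle")
    truth_out = truth.copy()
    truth_out["intended_index_date"] = (
        pd.to_datetime(truth_out["intended_index_date"])
        .dt.strftime("%Y-%m-%d").fillna(""))
    truth_out.to_csv(out_dir / "bundle" / "ground_truth.csv", index=False,
                     float_format="%.2f")

    assignments, attrition = assign_cohorts(bundle, code_sets, id_params)
    baseline = baseline_table(bundle, assignments, cci_config, analysis_params)
    utilization = summarize_utilization(bundle, assignments, code_sets,
                                        analysis_params)
    costs = pppy_costs(bundle, assignments, analysis_params)

    manifest = {
        "seed": config.seed,
        "n_beneficiaries": config.n_beneficiaries,
        "config_digest": config_digest(_config_dict(config)),
        "agitad_version": __version__,
    }
    render_reports(out_dir / "reports", attrition, assignments, baseline,
                   utilization, costs, manifest)
    return {
        "bundle": bundle, "ground_truth": truth, "assignments": assignments,
        "attrition": attrition, "baseline": baseline,
        "utilization": utilization, "costs": costs,
    }
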