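"""End-to-end pipeline: generate -> simulate -> attribute -> report.

Writes, under the output directory:

* ``attributable_costs.csv`` — per-capita annual attributable cost by
  component for the combined counterfactual and each single factor, with
  95% CIs when Monte-Carlo draws are enabled;
* ``factor_shares.csv`` — each factor's share of the combined cost;
* ``national_costs.csv`` — national annual totals (billions USD);
* ``strata.csv`` — combined attributable cost by sex, age band, race,
  education, BMI band, and insurance;
* ``bearer_allocation.csv`` — national combined cost split by insurance
  category and ultimate cost-bearer;
* ``summary.json`` — headline numbers; and
* ``manifest.json`` — seeds, config hash, package version, file list.

Everything is deterministic in (config, seed).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from cardiocost import __version__
from cardiocost.attribution import (AttributionResult, bearer_allocation,
                                    national_total, proportion_of_total,
                                    per_factor_sweep, stratify)
from cardiocost.config import PipelineConfig, config_hash
from cardiocost.population import generate_population, resample_weighted, summarize

__all__ = ["pipeline"]

STRATIFIERS = ["sex", "age_band", "race", "education", "bmi_band", "insurance"]


def pipeline(config: PipelineConfig, outdir: str | Path,
             seed: int | None = None) -> dict:
    """Run the full analysis; returns the summary dict."""
    seed = config.seed if seed is None else int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    raw = generate_population(config.population, n=config.n, seed=seed)
    pop = resample_weighted(raw, n=config.n, seed=seed + 1)

    results = per_factor_sweep(
        pop, config.factors, config.sim, config.costs, seed=seed + 2,
        entrant_spec=config.population, ci_draws=config.ci_draws)

    rows = []
    order = ["combined"] + [f.name for f in config.factors.factors]
    for name in order:
        r = results[name]
        row = {"scenario": name, "total": r.per_capita,
               "acute": r.components["acute"],
               "chronic": r.components["chronic"],
               "chronic_cvd": r.components["chronic_cvd"],
               "chronic_diabetes": r.components["chronic_diabetes"],
               "drug": r.components["drug"]}
        if r.ci is not None:
            row["ci_lo"], row["ci_hi"] = r.ci
        rows.append(row)
    table2 = pd.DataFrame(rows)
    table2.to_csv(out / "attributable_costs.csv", index=False)

    shares = pd.DataFrame(
        [{"factor": f.name,
          "share_of_combined_pct": results[f.name].strata["share_of_combined"]}
         for f in config.factors.factors])
    shares.to_csv(out / "factor_shares.csv", index=False)

    nat = pd.DataFrame(
        [{"scenario": name,
          "national_billion": national_total(
              results[name].per_capita, config.national_population) / 1e9}
         for name in order])
    nat.to_csv(out / "national_costs.csv", index=False)

    combined = results["combined"]
    strat_rows = []
    for by in STRATIFIERS:
        s = stratify(combined, by=by)
        s = s.reset_index().rename(columns={"index": "stratum"})
        s.insert(0, "by", by)
        strat_rows.append(s)
    strata = pd.concat(strat_rows, ignore_index=True)
    strata.to_csv(out / "strata.csv", index=False)

    by_ins = stratify(combined, by="insurance")
    ins_shares = (by_ins["total"] * by_ins["n"])
    ins_shares = ins_shares / ins_shares.sum()
    nat_combined = national_total(combined.per_capita, config.national_population)
    bearer = bearer_allocation((ins_shares * nat_combined).to_dict(),
                               config.payer_mix)
    bearer.to_csv(out / "bearer_allocation.csv")

    summary = {
        "n": config.n,
        "seed": seed,
        "per_capita_total": combined.per_capita,
        "per_capita_components": {k: combined.components[k]
                                  for k in ("acute", "chronic", "chronic_cvd",
                                            "chronic_diabetes", "drug")},
        "national_total_billion": nat_combined / 1e9,
        "share_of_direct_cmd_cost_pct": proportion_of_total(
            nat_combined / 1e9, config.total_direct_cost_billion),
        "factor_per_capita": {f.name: results[f.name].per_capita
                              for f in config.factors.factors},
        "population_summary": summarize(pop, config.population),
    }
    if combined.ci is not None:
        summary["per_capita_ci"] = list(combined.ci)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config_sha256": config_hash(config),
        "seed": seed,
        "n": config.n,
        "outputs": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
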