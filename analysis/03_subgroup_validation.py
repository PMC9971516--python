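#!/usr/bin/env python
"""Subgroup validation: ethnicity and SES scenarios, all four models.

Runs the pipeline on the ethnicity-multiplier and SES-multiplier
scenarios, reporting pooled OE-ratios per stratum and region model,
the per-stratum best-fitting model, and whether each designed subgroup
multiplier is recovered. Outputs under results/subgroups/.
"""

import argparse
from pathlib import Path

from score2val import reference as ref
from score2val.engine import load_model_specs
from score2val.impute import ImputationConfig
from score2val.report import RunManifest, render
from score2val.simulate import generate, scenario_config
from score2val.subgroups import ALL, ValidationConfig, run_validation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--full", action="store_true")
    args = ap.parse_args()
    n_by_sex = None if args.full else {"male": 25000, "female": 25000}
    specs = load_model_specs()

    for scenario, strata, designed in (
        ("ethnicity_multipliers", ("sex", "sex_ethnicity"),
         lambda r: ref.OE_LOW_ETHNICITY[r["sex"]].get(r["ethnicity"])),
        ("ses_multipliers", ("sex", "sex_ses"),
         lambda r: (ref.ses_oe_interpolated(r["sex"]).get(r["ses_quintile"])
                    if r["ses_quintile"] != ALL else None)),
    ):
        cfg = scenario_config(scenario, seed=args.seed, n_by_sex=n_by_sex)
        cohort, _ = generate(cfg)
        vconfig = ValidationConfig(
            strata=strata,
            imputation=ImputationConfig(m=5, max_iterations=10, seed=args.seed + 500000),
        )
        report = run_validation(cohort, specs, vconfig)
        out = ROOT / "results" / "subgroups" / scenario
        render(report, out, RunManifest.create(cfg, seed=args.seed))

        print(f"\n=== {scenario} (n={report.n}) ===")
        rows = report.results
        low = rows[(rows["region"] == "low") & rows["evaluable"]]
        for _, r in low.iterrows():
            target = designed(r)
            target_txt = f"  designed {target:.2f}" if target else ""
            print(f"  {r['sex']:6s} ses={r['ses_quintile']!s:4s} eth={r['ethnicity']:10s} "
                  f"OE {r['oe']:.2f} ({r['oe_lo']:.2f}-{r['oe_hi']:.2f}){target_txt}")
        gated = rows[~rows["evaluable"]]
        if len(gated):
            labels = gated[["sex", "ses_quintile", "ethnicity"]].drop_duplicates()
            print(f"  below the {vconfig.min_events}-event gate: "
                  + "; ".join(f"{r['sex']}/{r['ses_quintile']}/{r['ethnicity']}"
                              for _, r in labels.iterrows()))
        print("  best-fitting region per stratum:")
        for key, region in sorted(report.best_region.items(), key=lambda kv: kv[0].label()):
            print(f"    {key.label()}: {region}")
        print("  eligibility shift (upper threshold):")
        for sex, vals in sorted(report.eligibility.items()):
            print(f"    {sex}: {vals['before_pct']:.1f}% -> {vals['after_pct']:.1f}%")
        print(f"  outputs in {out}")


if __name__ == "__main__":
    main()
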