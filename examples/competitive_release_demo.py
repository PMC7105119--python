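"""The worked three-arm pulsed-therapy experiment, scaled for a desk run.

Runs the competitive-release model (drug-sensitive vs drug-resistant
tumor cells plus a boundary-fed diffusible drug) on the full 100x100
lattice for 200 simulated days under three treatment schedules, writing
populations.csv and side-by-side PNG snapshots to ./cr_demo_out.

The full-length run (10000 ticks = 2.3 years) is the same call with
steps=10000 — or from a shell:

    competitive-release run --out results_dir
"""

from hybridgrid.competitive_release import CompetitiveReleaseParams, run_experiment

params = CompetitiveReleaseParams(steps=2400, seed=0)  # 2400 ticks = 200 days
print(f"domain: {params.xDim}x{params.yDim} cells = {params.domain_area_mm2:.0f} mm^2, "
      f"{params.steps} two-hour ticks = {params.simulated_days:.0f} days")
result = run_experiment(params, "cr_demo_out", snapshot_days=50)
for arm, model in zip(("no_drug", "constant", "pulsed"), result["models"]):
    nsen, nres = model.type_counts()
    print(f"{arm:>9}: population {model.population():5d} "
          f"(sensitive {nsen}, resistant {nres})")
print("no_drug fills the lattice; constant drug crashes the sensitive cells "
      "and releases the resistant clone; pulsed keeps both in check.")
print(f"wrote {result['csv']} and {len(result['pngs'])} snapshots")
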