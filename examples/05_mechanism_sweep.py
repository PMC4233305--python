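"""A small mechanism sweep with the study's selection rule.

Sweeps the calcium-transient mechanism over the sharp-gradient column
(z_a = 0.5, both basal sizes, all 8 homogeneous Ca_T50 settings — a
16-run subset of the full 72-configuration grid), then applies the
headline analysis: keep runs with EF between 30 and 60% and rank by
end-systolic A:B.  The full 378-run study runs the same way via
``all_grids()`` (or ``takolv sweep``) in roughly half an hour.
"""

from takolv import GradientSpec, MechanismConfig, run_sweep, select_results, summarize

configs = [
    MechanismConfig(
        mechanism="transient", gradient=GradientSpec(0.5, z_b), ca_t50_homog=ca
    )
    for z_b in (0.25, 0.5)
    for ca in [0.6 + 0.9 * i / 7 for i in range(8)]
]
table = run_sweep(configs, progress=True)
print(table[["config_id", "ef", "ab_end_systole", "status"]].to_string(index=False))

selected = select_results(table)
if len(selected):
    top = selected.iloc[0]
    print(f"\nbest in the 30-60% EF window: {top.config_id} "
          f"(EF {top.ef:.1f}%, A:B {top.ab_end_systole:.2f})")
print(summarize(table))
table.to_csv("sweep_transient_sharp.csv", index=False)
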