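"""How much shared data does alignment need?

Sweeps the fraction of the common stimulus set used to fit each
alignment method and reports mean direct 2-way identification accuracy,
alongside the within-subject ceiling.
"""

from brainalign import SweepConfig, SyntheticConfig, generate_multisubject, run_fraction_sweep

ds = generate_multisubject(SyntheticConfig(mode="permuted_voxels", seed=2))
cfg = SweepConfig(n_seeds=3, include_pixel_metrics=False)
result = run_fraction_sweep(ds, cfg)

table = (
    result.records[result.records.metric == "two_way_direct"]
    .groupby(["method", "fraction"]).value.mean().unstack()
)
print("mean direct 2-way accuracy by method and common-data fraction:")
print(table.round(3).to_string())
print(
    "\nThe learned maps (ridge, procrustes) approach the within-subject"
    "\nceiling as the alignment set grows; the anatomical identity baseline"
    "\nstays near chance (0.5) because these subjects' voxels are scrambled"
    "\ncopies of each other."
)
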