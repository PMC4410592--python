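"""How many controls does single-sample calling need?

Subsamples control groups of 5-40 from a 50-control pool, reruns the
calling pipeline each time, and reports detection sensitivity at the
injected DMR plus the mean width of the effect-size confidence interval
at its probes. Small control groups destabilise the calls (extra or
fragmented regions) and inflate the interval.
"""

from epicase import DMRSpec, SimulationConfig, control_titration, simulate
from epicase.preprocess import preprocess_pipeline

cfg = SimulationConfig(
    n_background_probes=600,
    n_controls=50,
    dmr_specs=(DMRSpec("chr6", 1000, 3000, 10, 0.25, "mosaic_dmr"),),
    seed=31,
)
ds, truth = simulate(cfg)
ds, m = preprocess_pipeline(ds)

report = control_titration(
    ds, m, sizes=(5, 10, 20, 40), replicates=3, seed=31,
    truth_regions=truth.dmr_spans(),
)
summary = report.groupby("size")[["n_regions", "sensitivity",
                                  "truth_mean_ci_width"]].mean()
print(summary.to_string(float_format="%.3f"))

# truth_mean_ci_width is the average width of the 95% z_cc interval at
# probes inside the injected DMR: with 5 controls the interval is several
# times wider than with 20-40, which is why small control groups give
# unreliable effect-size estimates even when detection succeeds. The
# surplus regions at size 5 (n_regions > 1 for a single injected DMR)
# are unstable calls that disappear once the control SD is estimated
# from 10+ samples.
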