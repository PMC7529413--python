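"""Summarize causality maps: regional contrasts and cross-correlations.

Places the flow->NND coupling in a region of elevated flow and reduced
NND (as seen around detected causal regions in real nuclei), detects
the causal map, and compares the time-averaged parameters between
causal and non-causal pixels with subsampled Wilcoxon rank-sum tests.
"""

from stgranger import (
    InferenceConfig,
    SyntheticFieldSpec,
    causal_fraction,
    causality_maps,
    central_region,
    ellipse_mask,
    generate_var_fields,
    mean_abs_xcorr,
    region_comparison,
)
from stgranger.fields import stack_pixel_series

mask = ellipse_mask((32, 32))
spec = SyntheticFieldSpec(
    coupling_coeff=0.5,
    causal_region=central_region(mask, 200),
    region_mean_shift={"flow": 1.0, "nnd": -1.0},
    seed=1,
)
stacks, truth = generate_var_fields(spec)
fmap = causality_maps(stacks, InferenceConfig(), pairs=[("flow", "nnd")])[("flow", "nnd")]
print(f"flow -> nnd detected in {causal_fraction(fmap):.1f}% of the nucleus")

for var in ("flow", "nnd"):
    rc = region_comparison(
        stacks[var].time_average(), fmap, parameter=var, n_tests=250, subsample=100, seed=0
    )
    print(
        f"{var:>5}: causal mean {rc.stats_causal['mean']:+.2f} vs "
        f"non-causal {rc.stats_noncausal['mean']:+.2f}, "
        f"median subsampled Wilcoxon p = {rc.median_p:.2e}"
    )

series, m = stack_pixel_series(stacks)
xc = mean_abs_xcorr(series["nnd"], series["flow"], fmap.decision[m], max_lag=10)
tau = spec.coupling_lag
print(f"mean |cross-correlation| at lag {tau}: causal {xc['causal'][tau]:.2f}, "
      f"non-causal {xc['noncausal'][tau]:.2f}")
print("Causal pixels show higher flow, lower NND and a sustained flow-NND")
print("cross-correlation - the regional signature of dynamics driving local density.")
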