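"""Simulate gridded chromatin-parameter fields with a known causal link.

Generates the three per-pixel time series (flow magnitude, nearest-
neighbor distance, blob area) on an elliptical nucleus mask, with a
directed flow->NND coupling (coefficient 0.5, lag 3 frames) injected in
a 200-pixel interior region, and shows that the injected coupling is
visible as a lagged cross-correlation only inside that region.
"""

import numpy as np

from stgranger import SyntheticFieldSpec, central_region, ellipse_mask, generate_var_fields

mask = ellipse_mask((32, 32))
spec = SyntheticFieldSpec(
    coupling_coeff=0.5,
    coupling_lag=3,
    causal_region=central_region(mask, 200),
    seed=1,
)
stacks, truth = generate_var_fields(spec)

print(f"grid {spec.grid_shape}, {int(mask.sum())} masked pixels, T={spec.T} frames at {spec.dt} s")
for name, st in stacks.items():
    print(f"  {name}: values shape {st.values.shape}, pixel pitch {st.pixel_size_nm} nm")

region = truth.causal_mask("flow", "nnd")
tau = spec.coupling_lag
flow, nnd = stacks["flow"].values, stacks["nnd"].values


def lagged_corr(sel):
    a = flow[:-tau][:, sel]
    b = nnd[tau:][:, sel]
    a = (a - a.mean(0)) / a.std(0)
    b = (b - b.mean(0)) / b.std(0)
    return float((a * b).mean())


print(f"\nlag-{tau} cross-correlation flow -> NND:")
print(f"  inside causal region ({int(region.sum())} px): {lagged_corr(region):.3f}")
print(f"  outside region: {lagged_corr(mask & ~region):.3f}")
print("The injected coupling produces a strong lagged correlation only where it was placed;")
print("elsewhere the two variables are independent AR(1) fields.")
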