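"""Full analysis of simulated stacks: dispersion profile and density.

Simulates three stacks of the gradually dispersing scenario at the
default study conditions (512 px field, 112 slices), runs the
cellness -> ROI -> orientation chain, and prints the recovered
depth-resolved dispersion next to the known truth, plus the mid-wall
cell density. Agreement within a few degrees / a few cells shows the
pipeline recovering the architecture it was pointed at; per-window
estimates from only three stacks still scatter by a degree or two.
"""

import dataclasses

import numpy as np
import pandas as pd

import tubeorient as to

results = []
for seed in (1, 2, 3):
    spec = dataclasses.replace(to.preset_scenarios()["ureter_like"], seed=seed)
    stack, truth = to.generate_stack(spec)
    stack.stack_id = f"demo-{seed}"
    res = to.analyze_stack(stack, lm_thickness_um=spec.wall_thickness_um)
    c = res.counts
    print(f"stack {seed}: {c['raw']} raw clusters -> {c['area_filtered']} after "
          f"area filter -> {c['in_roi']} in ROI -> {c['anisotropy_passed']} oriented")
    results.append(res)

samples = pd.concat([r.samples for r in results], ignore_index=True)
print(f"\n{len(samples)} orientation samples pooled from 3 stacks")

print("\nz_n    recovered SD   true SD")
for depth in (0.2, 0.4, 0.6, 0.8):
    sel = samples[np.abs(samples.z_n - depth) <= 0.1]
    sd = to.circular_sd(sel.alpha_deg.to_numpy())
    print(f"{depth:.1f} {sd:11.1f}° {25 + 7 * depth:9.1f}°")

mids = [
    r.density[(r.density.z_n > 0.4) & (r.density.z_n < 0.6)]
    .density_per_1e4um2.mean()
    for r in results
]
print(f"\nmid-wall density: {np.mean(mids):.1f} cells per 1e4 µm² "
      f"(simulated target 20; detection misses some faint and merged nuclei)")

dist = to.kde2d_circular(
    samples.z_n.to_numpy(), samples.alpha_deg.to_numpy(),
    stack_ids=samples.stack_id.to_numpy(),
)
marg = np.trapezoid(dist.density, dist.depth_grid, axis=0)
print(f"pooled orientation mode: {dist.angle_grid[np.argmax(marg)]:.0f}° "
      f"(0° = longitudinal axis)")
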