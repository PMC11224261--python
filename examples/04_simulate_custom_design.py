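"""Design a custom synthetic study and verify ground-truth recovery.

Plants a strong two-region correlation block in one of two groups, generates
counts, and checks that the realized across-animal correlations track the
configured target (the generator pre-calibrates its Gaussian copula against
lognormal distortion and binomial counting noise).
"""

import numpy as np

import coreactnet as cn
from coreactnet.simulate import block_corr_matrix

regions = [("PL", "mPFC"), ("BLA", "amygdala"), ("CEA", "amygdala"),
           ("vSUB", "PH"), ("PER_35", "PH")]
target = block_corr_matrix(5, block=[1, 2, 3, 4], value=0.7, background=0.15)

cfg = cn.SimulationConfig(
    groups=[cn.GroupSpec("conditioned", 40), cn.GroupSpec("control", 40)],
    regions=regions,
    p_td=0.08, p_cfos=0.04,
    ratio={"conditioned": 1.8, "control": 1.0},
    sigma_animal=0.3,
    corr={"conditioned": target, "control": np.eye(5)},
    seed=42,
)
counts, truth = cn.generate_dataset(cfg)
react = cn.reactivation_table(counts)

names = [r for r, _ in regions]
m = cn.correlation_matrix(react, "conditioned", regions=names)
mask = ~np.eye(5, dtype=bool)
mad = np.abs(m.r.values[mask] - target[mask]).mean()
print("realized correlations (conditioned group, n=40):")
print(m.r.round(2).to_string())
print(f"\nmean absolute deviation from the planted target: {mad:.3f}")
print(f"capped pairs during calibration: "
      f"{truth['groups']['conditioned']['n_capped_pairs']}, "
      f"clamped cells: {truth['groups']['conditioned']['n_clamped_cells']}")
print("\nSmall deviations are expected at n=40; they shrink as animals are added.")
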