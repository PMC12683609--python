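"""Trans-ancestry genetic-effect correlation for one trait in two populations.

The same polygenic trait measured in two ancestries with cross-population
effect correlation rho_ge = 0.6; the moment estimator regresses the
product of Z-scores on the cross-population LD score (intercept fixed at
0: no samples are shared across ancestries).
"""

from gsemkit import estimate_trans_rg, simulate_panel
from gsemkit.presets import cross_pair_scenario

panel, _ = simulate_panel(cross_pair_scenario(seed=1, rho_ge=0.6))
fit = estimate_trans_rg(panel, "TR_P1", "TR_P2")

print(f"true rho_ge      : 0.600")
print(f"estimated rho_ge : {fit.rho_ge:.4f} (jackknife SE {fit.se:.4f})")
print(f"normalizing h2   : {fit.h2_t:.3f}, {fit.h2_u:.3f}")
print(f"out of [-1,1]?   : {fit.out_of_range} (flagged, never clipped)")
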