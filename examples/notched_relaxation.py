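"""Strain-and-hold relaxation of a notched lattice (README worked example)."""

import hexfrac as hf

table = hf.PotentialTable()

# a notched 60x60 lattice held at 5% horizontal strain for 7 ns
system = hf.insert_notch(hf.build_hexagonal_lattice(60, 60), 30, 4, 2)
protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=20_000)
config = hf.DynamicsConfig(random_seed=1, series_every=100)
final, series, switch_log, _ = hf.run_constant_strain(system, table, protocol, config)

fit = hf.fit_exponential_decay(series, "sigma_xx")
report = hf.cluster_cracks(hf.detect_broken_bonds(final, table), final)

print(f"loading stress sigma_xx : {series.sigma_xx[0]:9.1f} kJ/mol/nm^2")
print(f"plateau stress sigma_xx : {series.sigma_xx[-1]:9.1f} kJ/mol/nm^2")
print(f"decay time tau          : {fit.tau:9.1f} ps  (R^2 = {fit.r_squared:.3f})")
print(f"damaged blocks          : {int(series.n_damaged[-1]):9d} of {final.n_blocks}")
print(f"broken bonds            : {report.n_broken:9d} in {report.n_clusters} micro-cracks")
print(
    "largest crack (x, y)    : "
    f"({report.cluster_extents[0][0]:.0f}, {report.cluster_extents[0][1]:.0f}) nm"
)
print(f"percolates              : {report.percolates}")
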