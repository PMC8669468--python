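"""Growth physiology and adenylate energy charge on synthetic kinetics.

Generates an exponential growth curve with lag and 2% OD noise plus a
substrate depletion series, recovers the growth rate and specific uptake
rate, partitions the carbon uptake, and evaluates the adenylate energy
charge for pools constructed at the magnitude reported for succinate-grown
cells (~0.68).
"""

import gluconeoflux as gf
from gluconeoflux import synth
from gluconeoflux.physiology import carbon_partition, exchange_rates, fit_growth

cfg = synth.ScenarioConfig(mu=0.85, lag=2.0, od_noise=0.02, seed=11,
                           yield_x_s=0.06)
data = synth.make_physiology_dataset(cfg, t_end=6.5)

growth = fit_growth(data["time"], data["od"], window=(cfg.lag + 0.5, 6.5))
print(f"mu = {growth.mu:.3f} h^-1 (true {cfg.mu}), R^2 = {growth.r_squared:.4f}")

rates = exchange_rates(data["conc"], data["cdw"], growth,
                       substrate="substrate")
q = rates.q("substrate")
print(f"q_succinate = {q:.2f} mmol gCDW^-1 h^-1 "
      f"(true {cfg.mu / cfg.yield_x_s:.2f}); yield "
      f"{rates.yield_x_s * 1000:.0f} mgCDW/mmol")

# biomass drains of the benchmark scenario account for 58% of carbon
biomass_c = 0.58 * q * 4
frac = carbon_partition(q, 4, {}, biomass_c)
print("carbon fate:", {k: round(v, 2) for k, v in frac.items()})

pools = gf.make_adenylate_pools(0.68)
print(f"energy charge of constructed pools: "
      f"{gf.energy_charge(pools):.3f} (ATP {pools.atp:.2f}, "
      f"ADP {pools.adp:.2f}, AMP {pools.amp:.2f} umol/g)")
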