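"""Dose kinetics of integrated difference electron density.

Simulates a series of 20 isomorphous difference maps (64^3 grid, cubic 20 A
P1 cell) in which a negative Gaussian feature at an iron site grows with a
dose constant of 79.5 kGy, then integrates all density below -3 sigma within
1.0 A of the site in every map and fits the growth of |negative sum| with
the same exponential model used for spectroscopic band traces.
"""

import numpy as np

from dosekin import (
    AtomSite,
    IntegrationSpec,
    MapFeature,
    MapSimConfig,
    series_site_kinetics,
    simulate_map_series,
)

cfg = MapSimConfig(
    grid=(64, 64, 64),
    cell_a=20.0,
    features=(MapFeature((10.0, 10.0, 10.0), -0.15, 0.5, 79.5),),
    noise_sd=0.0075,
    doses_kgy=np.linspace(14.4, 450.0, 20),
    seed=0,
)
maps, doses = simulate_map_series(cfg)
site = AtomSite("FE", np.array([10.0, 10.0, 10.0]))
table, fit = series_site_kinetics(
    maps, doses, site, IntegrationSpec(radius_a=1.0, sigma_mult=3.0), use="negative"
)

print(table[["dose_kgy", "negative_sum", "n_neg", "map_sigma"]].round(4).head())
print("...")
print(
    f"negative density at the site builds up with tau = {fit.tau_kgy:.1f} kGy "
    f"(true 79.5 kGy, converged={fit.converged})"
)
print("matching the dose constant of the spectroscopic Q0-band decay")
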