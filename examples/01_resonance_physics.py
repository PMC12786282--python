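"""Where do the chip's optical modes sit?

Evaluates the two closed-form resonance conditions of a 500 nm-pitch gold
nanohole array in water: the Wood-Rayleigh anomaly (period and bulk index
only) and the grating-coupled surface plasmon polariton (which also needs the
gold permittivity), including the damped fixed-point solve for dispersive gold.
"""

from plasmokan import (
    ChipGeometry,
    DiffractionOrder,
    MaterialModel,
    spp_wavelength,
    wood_anomaly_wavelength,
)

chip = ChipGeometry(period_nm=500.0, hole_diameter_nm=200.0, depth_nm=200.0)
water = MaterialModel(eps_metal=-20.0, n_medium=1.33)

print("Wood-Rayleigh anomaly (first order, water):")
wl = wood_anomaly_wavelength(chip, DiffractionOrder(1, 0), water)
print(f"  lambda_WA = {wl:.1f} nm   <- period x n_water; binding-insensitive reference mode")

print("SPP, constant gold permittivity eps_Au = -20:")
wl = spp_wavelength(chip, DiffractionOrder(1, 0), water)
print(f"  lambda_SPP = {wl:.1f} nm  <- red-shifted past the anomaly, as a bound mode must be")

drude = MaterialModel(eps_metal=lambda wl: 1.0 - (wl / 150.0) ** 2, n_medium=1.33)
wl = spp_wavelength(chip, DiffractionOrder(1, 0), drude)
print("SPP, Drude-like dispersive gold (fixed-point solve):")
print(f"  lambda_SPP = {wl:.1f} nm  <- self-consistent wavelength where eps_Au(lambda) supports the mode")
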