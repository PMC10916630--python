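"""Reference parameter set: RBFM soymilk storage stability.

Published storage-kinetic and sensory-link parameters for soymilk produced
by the repeated boiling-to-filtering method (RBFM), stored at 25/35/45 °C.
They serve two purposes: as the default "study conditions" of the synthetic
data generator, and as fixed inputs when reproducing the reported
transition-state parameter table.

All rate constants are first-order, in d⁻¹; activation energies in J/mol;
initial values in each index's own units (CSR %, particle size μm,
viscosity mPa·s).
"""

from __future__ import annotations

TEMPERATURES_K = (298.15, 308.15, 318.15)

#: index -> direction of change during storage (+1 grows, -1 decays)
DIRECTIONS = {"CSR": 1, "particle_size": 1, "viscosity": -1}

#: index -> initial value C0 at t = 0
INITIAL_VALUES = {"CSR": 0.82, "particle_size": 0.545, "viscosity": 5.82}

#: index -> {temperature K: first-order rate constant, d⁻¹}
RATE_CONSTANTS = {
    "CSR": {298.15: 0.0367, 308.15: 0.0678, 318.15: 0.1013},
    "particle_size": {298.15: 0.0158, 308.15: 0.0270, 318.15: 0.0420},
    # the 298.15 K value is reported as 0.0630, non-monotone vs the higher
    # temperatures; it is kept verbatim and used only row-wise
    "viscosity": {298.15: 0.0630, 308.15: 0.0112, 318.15: 0.0168},
}

#: index -> {temperature K: reported activation energy, J/mol}
#: (particle size is reported with 38.58 kJ/mol at two temperatures and
#: 38.56 at the third; each row keeps its own value)
ACTIVATION_ENERGIES = {
    "CSR": {298.15: 40_800.0, 308.15: 40_800.0, 318.15: 40_800.0},
    "particle_size": {298.15: 38_580.0, 308.15: 38_580.0, 318.15: 38_560.0},
    "viscosity": {298.15: 10_560.0, 308.15: 10_560.0, 318.15: 10_560.0},
}

#: index -> (slope points/index-unit, intercept points) of the sensory link
SENSORY_LINKS = {
    "CSR": (-9.6927, 96.131),
    "particle_size": (-33.187, 105.79),
    "viscosity": (10.322, -28.007),
}

#: sensory acceptance threshold, points (product unacceptable below this)
SENSORY_THRESHOLD = 80.0


def eyring_inputs() -> list[tuple[str, float, float, float]]:
    """Flat (index, T, k, Ea) rows in deterministic order."""
    rows = []
    for index in sorted(RATE_CONSTANTS):
        for T in TEMPERATURES_K:
            rows.append((index, T, RATE_CONSTANTS[index][T], ACTIVATION_ENERGIES[index][T]))
    return rows
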