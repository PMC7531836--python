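"""Physical constants and unit helpers shared across the package."""

AVOGADRO = 6.02214076e23  # mol^-1

SECONDS_PER_DAY = 86400.0

# Healthy adult reference values
HEALTHY_ERYTHROCYTES_PER_UL = 5.0e6     # cells uL^-1
ERYTHROCYTE_HALF_LIFE_DAYS = 60.0       # circulating half-life

# Unsaturable-membrane convention: attachment of nascent C3b and insertion
# of C5b-7 are second order in the free species and the membrane site pool,
# taken proportional to the cell concentration with a fixed structural site
# capacity per cell.  The pool is not consumed (occupancy at lytic MAC
# densities is negligible against this capacity).
MEMBRANE_SITES_PER_CELL = 3.0e5


def cells_per_liter_to_molar(cells_per_l: float) -> float:
    """Convert a cell count concentration (cells L^-1) to molar units."""
    return cells_per_l / AVOGADRO


def molar_to_cells_per_liter(molar: float) -> float:
    return molar * AVOGADRO


def per_day_to_per_second(k: float) -> float:
    return k / SECONDS_PER_DAY


def per_second_to_per_day(k: float) -> float:
    return k * SECONDS_PER_DAY
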