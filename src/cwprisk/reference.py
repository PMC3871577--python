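"""Published summary tables from the Kailuan colliery CWP cohort (1970–2011).

These printed aggregates are shipped as default inputs: the work-area dust
concentrations drive cumulative-exposure reconstruction, the subgroup
incidence rates drive projection, and the characteristic counts serve as a
reference for contingency testing. The underlying individual records were
never deposited; everything per-worker in this package comes from user data
or the synthetic-cohort generator.
"""

from __future__ import annotations

import math

from .cohort import Area, ConcentrationTable

#: Geometric mean (+1 SD, −1 SD) of dust concentration (mg/m³) per work area
#: and entry decade. The last block is open-ended: concentrations after 2009
#: are carried forward from the 2000- block.
DUST_CONCENTRATIONS: dict[str, dict[str, tuple[float, float, float]]] = {
    "1970-": {
        "tunneling": (72.6, 218.4, 24.2),
        "mining": (82.1, 200.9, 33.5),
        "combining": (51.1, 106.3, 24.6),
        "helping": (0.8, 1.1, 0.6),
    },
    "1980-": {
        "tunneling": (47.2, 89.9, 24.8),
        "mining": (64.0, 126.1, 32.5),
        "combining": (47.6, 66.3, 34.2),
        "helping": (0.7, 0.8, 0.6),
    },
    "1990-": {
        "tunneling": (44.4, 94.4, 20.8),
        "mining": (36.0, 65.4, 19.8),
        "combining": (26.8, 42.9, 16.8),
        "helping": (0.4, 0.5, 0.3),
    },
    "2000-": {
        "tunneling": (23.5, 40.2, 13.8),
        "mining": (23.9, 29.4, 19.4),
        "combining": (15.8, 35.7, 7.0),
        "helping": (0.2, 0.5, 0.2),
    },
}

_DECADE_BLOCKS = {"1970-": (1970, 1979), "1980-": (1980, 1989), "1990-": (1990, 1999),
                  "2000-": (2000, 2099)}


def default_concentration_table() -> ConcentrationTable:
    """Decade-block concentration table; GSD back-solved as sqrt(+1SD/−1SD)."""
    rows = []
    for block, (y0, y1) in _DECADE_BLOCKS.items():
        for area, (gm, plus, minus) in DUST_CONCENTRATIONS[block].items():
            gsd = math.sqrt(plus / minus)
            rows.append((Area(area), y0, y1, gm, gsd))
    return ConcentrationTable(rows)


#: Cohort characteristics: counts of workers with / without CWP per stratum.
CHARACTERISTIC_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "occupational_category": {
        "tunneling": (248, 1137),
        "mining": (245, 2559),
        "combining": (259, 2022),
        "helping": (86, 10467),
    },
    "era_of_first_exposure": {
        "1970-": (710, 5854),
        "1980-": (112, 5798),
        "1990-": (16, 4533),
    },
    "duration_of_exposure": {
        "<10": (27, 2485),
        "10-": (146, 3051),
        "20-": (435, 5031),
        "30-": (230, 5618),
    },
    "cumulative_dust_exposure": {
        "<100": (88, 10513),
        "100-": (238, 3237),
        "1000-": (512, 2435),
    },
}

N_CASES = 838
N_NONCASES = 16185
N_TOTAL = N_CASES + N_NONCASES

#: Annual average CWP incidence (per-year probability) per entry era and
#: occupational category, from the subgroup life tables.
SUBGROUP_ANNUAL_RATES: dict[tuple[str, str], float] = {
    ("1970-", "tunneling"): 8.1e-3,
    ("1970-", "mining"): 8.0e-3,
    ("1970-", "combining"): 6.5e-3,
    ("1970-", "helping"): 0.6e-3,
    ("1980-", "tunneling"): 1.7e-3,
    ("1980-", "mining"): 2.1e-3,
    ("1980-", "combining"): 1.4e-3,
    ("1980-", "helping"): 0.3e-3,
}

#: Projected new CWP cases per category × future decade window among the
#: 16,185 workers without CWP, within life expectancy.
PROJECTED_CASES_BY_WINDOW: dict[str, tuple[float, float, float, float]] = {
    "tunneling": (58.5, 58.5, 50.0, 7.5),
    "mining": (100.2, 100.2, 85.1, 31.4),
    "combining": (72.6, 72.6, 56.4, 11.4),
    "helping": (41.7, 41.7, 36.1, 19.6),
}

#: Grand total of projected cases used for threshold calibration.
PROJECTED_TOTAL = 844

#: MLP confusion counts at the 0.2 cutoff: (true positives, positives),
#: (true negatives, negatives), (correct, total).
MODEL_SENSITIVITY_COUNTS = (682, 838)
MODEL_SPECIFICITY_COUNTS = (14945, 16185)
MODEL_ACCURACY_COUNTS = (15627, 17023)

#: Low-risk pool: workers first exposed after 1980 in the helping category.
LOW_RISK_POOL = 6869

#: Category mix among workers without CWP (tunneling/mining/combining/helping).
CATEGORY_MIX = (0.070, 0.158, 0.125, 0.647)

#: Entry-era mix among workers without CWP (1970-/1980-/1990-).
ERA_MIX = (0.362, 0.358, 0.280)
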