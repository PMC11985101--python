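"""Built-in reference data for the twelve-ecosystem land-use gradient survey.

The package ships the ecosystem-level soil chemistry means (average of five
field replicates per ecosystem) and the sampling design (number of composite
soil samples collected per ecosystem) of a survey spanning a land-use
gradient from natural ecosystems (forests, shrublands, grasslands) to
intensively managed agricultural soils. These tables serve two purposes:

* realistic ecosystem means for the synthetic chemistry generator, and
* a worked reference for the C/N-ratio derivation
  (``CN = organic carbon / total nitrogen``, both in g/kg).

Trait units: sand/loam/clay and limestone and OC and TN in g/kg, EC in dS/m,
P2O5 in mg/kg, CEC in meq/100 g, pH unitless.
"""

from __future__ import annotations

import pandas as pd

#: Ecosystem labels, agricultural systems first, then natural ecosystems.
ECOSYSTEMS = [
    "intensive_agriculture",
    "intensive_horticulture",
    "vineyard",
    "polluted_agriculture",
    "arid_greenhouse",
    "mediterranean_grassland",
    "mountain_grassland",
    "mediterranean_shrubland",
    "subalpine_shrubland",
    "deciduous_forest",
    "evergreen_forest",
    "kiln_forest",
]

#: Chemistry trait columns, in canonical order. "CN" is derived, not measured.
CHEMISTRY_TRAITS = [
    "sand", "loam", "clay", "pH", "EC", "limestone",
    "OC", "TN", "CN", "P2O5", "CEC",
]

_CHEMISTRY_MEANS = {
    #                          sand  loam  clay   pH     EC   lime    OC    TN   P2O5   CEC
    "intensive_agriculture":   (959,   17,   24, 7.06, 0.213,  6.79, 14.4, 1.68, 107.1, 14.4),
    "intensive_horticulture":  (516,  309,  175, 7.82, 0.263, 47.7,  13.3, 1.96, 272.2, 20.1),
    "vineyard":                (450,  200,  350, 6.33, 0.901, 35.2,  12.7, 4.44, 147.4, 25.7),
    "polluted_agriculture":    (620,  230,  150, 7.30, 0.160, 46.8,  20.3, 3.90, 150.1, 34.3),
    "arid_greenhouse":         (384,  106,   24, 8.74, 0.502, 36.6,   6.1, 0.63, 127.3,  6.0),
    "mediterranean_grassland": (840,  158,    2, 5.79, 0.103,  5.91, 64.5, 9.56,  15.3, 40.3),
    "mountain_grassland":      (208,  275,  125, 6.88, 0.207,  5.45, 86.4, 8.54,  27.5, 53.0),
    "mediterranean_shrubland": (602,  237,  161, 7.16, 0.131,  5.78, 26.3, 3.07,  30.8, 37.7),
    "subalpine_shrubland":     (200,  300,  100, 6.41, 0.388,  2.26, 28.5, 2.12,  29.0, 15.7),
    "deciduous_forest":        (192,  192,  238, 7.38, 0.137,  3.09, 63.0, 4.78,  44.7, 42.2),
    "evergreen_forest":        (930,   66,    4, 7.19, 0.274, 31.8,  41.6, 4.85,  76.4, 36.1),
    "kiln_forest":             (860,  117,   23, 7.32, 0.161, 91.9,  76.1, 5.92,  61.8, 51.0),
}

#: Published (rounded to one decimal) C/N ratios, for cross-checking the
#: derived OC/TN column against the survey's own table.
PUBLISHED_CN = {
    "intensive_agriculture": 8.6,
    "intensive_horticulture": 6.8,
    "vineyard": 2.9,
    "polluted_agriculture": 5.2,
    "arid_greenhouse": 9.7,
    "mediterranean_grassland": 6.7,
    "mountain_grassland": 10.1,
    "mediterranean_shrubland": 8.6,
    "subalpine_shrubland": 13.4,
    "deciduous_forest": 13.2,
    "evergreen_forest": 8.6,
    "kiln_forest": 12.9,
}

_SAMPLE_COUNTS = {
    "deciduous_forest": 20,
    "mountain_grassland": 12,
    "mediterranean_shrubland": 21,
    "mediterranean_grassland": 9,
    "subalpine_shrubland": 36,
    "evergreen_forest": 6,
    "kiln_forest": 12,
    "polluted_agriculture": 32,
    "intensive_agriculture": 24,
    "intensive_horticulture": 30,
    "vineyard": 30,
    "arid_greenhouse": 10,
}


def soil_chemistry() -> pd.DataFrame:
    """Ecosystem-mean soil chemistry table.

    Returns a DataFrame indexed by ecosystem with the canonical trait
    columns; ``CN`` is derived as ``OC / TN``.
    """
    cols = ["sand", "loam", "clay", "pH", "EC", "limestone", "OC", "TN", "P2O5", "CEC"]
    df = pd.DataFrame.from_dict(_CHEMISTRY_MEANS, orient="index", columns=cols)
    df.index.name = "ecosystem"
    df = df.loc[ECOSYSTEMS]
    df["CN"] = df["OC"] / df["TN"]
    return df[CHEMISTRY_TRAITS]


def sampling_design() -> pd.Series:
    """Number of composite soil samples collected per ecosystem.

    The counts differ between ecosystems (6-36 samples) because of field
    logistics; their sum is the study total of 242 samples.
    """
    s = pd.Series(_SAMPLE_COUNTS, name="n_samples").loc[ECOSYSTEMS]
    s.index.name = "ecosystem"
    return s
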