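"""Published record counts for twelve endemic dry-forest birds of western Mexico.

These small printed tables travel with the package as worked-example inputs:
per-species museum record counts next to field occurrence counts (distinct
1x1 km cells), and the field-validation cross-tabulations of an
actual-distribution-model study of the same twelve species — true presences
vs false absences at surveyed sites, and predicted-presence vs
predicted-absence pixel counts within merged 1-km buffers around the survey
points (the buffer table covers the eleven species with area validation).
"""

from __future__ import annotations

import pandas as pd

_SPECIES_COUNTS = [
    # species, museum records, field occurrence cells
    ("Cacicus melanicterus", 135, 62),
    ("Chlorostilbon auriceps", 61, 23),
    ("Deltarhynchus flammulatus", 26, 26),
    ("Granatellus venustus", 48, 29),
    ("Melanerpes chrysogenys", 196, 87),
    ("Ortalis poliocephala", 41, 58),
    ("Passerina leclancherii", 117, 78),
    ("Polioptila nigriceps", 38, 12),
    ("Pheugopedius felix", 123, 92),
    ("Thryophilus sinaloa", 151, 92),
    ("Trogon citreolus", 146, 70),
    ("Vireo hypochryseus", 106, 62),
]

_VALIDATION_COUNTS = [
    # species, site: (total cells, true presences), buffer: (total cells, true cells)
    ("Cacicus melanicterus", 62, 35, 150, 86),
    ("Chlorostilbon auriceps", 23, 15, 63, 47),
    ("Deltarhynchus flammulatus", 26, 22, 67, 56),
    ("Granatellus venustus", 29, 20, 75, 57),
    ("Melanerpes chrysogenys", 87, 58, 197, 134),
    ("Ortalis poliocephala", 58, 39, 156, 102),
    ("Passerina leclancherii", 78, 50, 184, 121),
    ("Polioptila nigriceps", 12, 6, 28, 15),
    ("Pheugopedius felix", 92, 61, 197, 139),
    ("Thryophilus sinaloa", 92, 60, 187, 126),
    ("Trogon citreolus", 70, 49, 170, 112),
]


def species_record_counts() -> pd.DataFrame:
    """Museum vs field record counts for the twelve species."""
    return pd.DataFrame(
        _SPECIES_COUNTS, columns=["species", "museum_records", "field_cells"]
    )


def field_validation_counts() -> pd.DataFrame:
    """Site and buffer validation cross-tabulation counts (eleven species)."""
    df = pd.DataFrame(
        _VALIDATION_COUNTS,
        columns=[
            "species",
            "site_total_cells",
            "site_true_presences",
            "buffer_total_cells",
            "buffer_true_cells",
        ],
    )
    df["site_false_absences"] = df["site_total_cells"] - df["site_true_presences"]
    df["buffer_false_cells"] = df["buffer_total_cells"] - df["buffer_true_cells"]
    return df
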