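"""Published per-record beat counts of the MIT-BIH Atrial Fibrillation Database.

These are the annotated class sizes of the 25 ten-hour records after
trimming the 10 boundary beats at each record edge (the beats without a
complete 21-beat feature window), as tabulated in the study that
evaluated this method on that database.  They let the arithmetic of the
evaluation protocol — exclusion counts, class totals, balanced-draw
sizes, training fractions — be reproduced without downloading the
database itself.  ``RAW_TOTAL_BEATS``/``RAW_AF_BEATS`` are the database
totals before the boundary trim.
"""

from __future__ import annotations

#: (N_AF, N_nAF) per record after boundary exclusion.
MITBIH_AF_COUNTS: dict[str, tuple[int, int]] = {
    "00735": (332, 39880),
    "03665": (11057, 41687),
    "04015": (525, 43459),
    "04043": (14634, 47260),
    "04048": (813, 39100),
    "04126": (3293, 39546),
    "04746": (30873, 16979),
    "04908": (5810, 55929),
    "04936": (39681, 13944),
    "05091": (138, 36634),
    "05121": (33759, 16101),
    "05261": (934, 44579),
    "06426": (53115, 2019),
    "06453": (445, 34371),
    "06995": (27505, 27663),
    "07162": (39277, 0),
    "07859": (60245, 0),
    "07879": (40035, 16538),
    "07910": (6758, 29820),
    "08215": (33118, 10217),
    "08219": (14194, 45078),
    "08378": (11478, 34016),
    "08405": (45083, 13752),
    "08434": (2310, 37519),
    "08455": (44252, 15279),
}

#: Database totals before the boundary trim.
RAW_TOTAL_BEATS = 1_221_534
RAW_AF_BEATS = 519_788

#: Published beat-level (Se, PPV) operating points of the LSVM pipeline
#: on this database, before and after the aggregation stage.
OPERATING_POINT_NO_AGGREGATION = (98.10, 96.67)
OPERATING_POINT_WITH_AGGREGATION = (98.94, 98.39)
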