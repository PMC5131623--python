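"""Published structural and marker summaries for 16 Melastomataceae plastomes.

These are the deposited-genome summary values for GenBank accessions
KX826819-KX826834 (the first complete plastomes of the family), shipped so
that cohort statistics, the structural tiling identity and the composite
marker ranking can be exercised and cross-checked without downloading the
accessions themselves.

Units: lengths in bp, GC as fractions, bootstrap in percent, RF distance as
the unnormalised bipartition count on 16 taxa.
"""

from __future__ import annotations

import pandas as pd

# species, accession, lsc_bp, lsc_gc, ssc_bp, ssc_gc, ir_bp, ir_gc, full_bp, full_gc
_REGION_ROWS = [
    ("Allomaieta villosa", "KX826819", 85915, 0.347, 16975, 0.306, 26781, 0.425, 156452, 0.369),
    ("Bertolonia acuminata", "KX826820", 85571, 0.347, 17008, 0.308, 26733, 0.425, 156045, 0.370),
    ("Blakea schlimii", "KX826821", 85370, 0.349, 16998, 0.308, 26747, 0.425, 155862, 0.370),
    ("Eriocnema fulva", "KX826822", 85431, 0.348, 16953, 0.308, 26805, 0.425, 155994, 0.370),
    ("Graffenrieda moritziana", "KX826823", 85341, 0.347, 16924, 0.309, 26734, 0.425, 155733, 0.370),
    ("Henriettea barkeri", "KX826824", 85991, 0.347, 17036, 0.306, 26750, 0.425, 156527, 0.369),
    ("Merianthera pulchra", "KX826825", 85621, 0.348, 17001, 0.307, 26773, 0.424, 156168, 0.370),
    ("Miconia dodecandra", "KX826826", 86609, 0.348, 16999, 0.310, 26804, 0.425, 157216, 0.370),
    ("Nepsera aquatica", "KX826827", 84644, 0.348, 17066, 0.310, 26700, 0.426, 155110, 0.371),
    ("Opisthocentra clidemioides", "KX826828", 85866, 0.348, 16942, 0.309, 26772, 0.425, 156352, 0.370),
    ("Pterogastra divaricata", "KX826829", 84718, 0.351, 17156, 0.312, 26537, 0.425, 154948, 0.372),
    ("Rhexia virginica", "KX826830", 84459, 0.351, 16924, 0.311, 26626, 0.425, 154635, 0.372),
    ("Rhynchanthera bracteata", "KX826831", 85093, 0.347, 16729, 0.307, 26643, 0.426, 155108, 0.370),
    ("Salpinga maranoniensis", "KX826832", 85128, 0.353, 16653, 0.317, 25765, 0.428, 153311, 0.374),
    ("Tibouchina longifolia", "KX826833", 86297, 0.349, 17124, 0.311, 26684, 0.425, 156789, 0.371),
    ("Triolena amazonica", "KX826834", 86200, 0.347, 16970, 0.307, 26741, 0.425, 156652, 0.369),
]

# species, cds_bp, cds_gc, trna_bp, trna_gc, rrna_bp, rrna_gc, intron_bp,
# intron_gc, intergenic_bp, intergenic_gc
_CLASS_ROWS = [
    ("Allomaieta villosa", 80826, 0.374, 3348, 0.497, 9050, 0.425, 20553, 0.347, 42675, 0.316),
    ("Bertolonia acuminata", 80670, 0.375, 3356, 0.497, 9050, 0.425, 20437, 0.347, 42532, 0.316),
    ("Blakea schlimii", 80742, 0.375, 3348, 0.498, 9050, 0.425, 20541, 0.347, 42181, 0.319),
    ("Eriocnema fulva", 80628, 0.375, 3354, 0.497, 9050, 0.425, 20540, 0.347, 42422, 0.318),
    ("Graffenrieda moritziana", 80286, 0.375, 3349, 0.497, 9050, 0.425, 19691, 0.347, 43357, 0.317),
    ("Henriettea barkeri", 80781, 0.374, 3363, 0.495, 9050, 0.425, 20571, 0.347, 42762, 0.315),
    ("Merianthera pulchra", 80751, 0.375, 3364, 0.498, 9050, 0.425, 20478, 0.347, 42525, 0.318),
    ("Miconia dodecandra", 80586, 0.376, 3354, 0.498, 9050, 0.425, 20548, 0.347, 43678, 0.317),
    ("Nepsera aquatica", 80646, 0.375, 3370, 0.496, 9050, 0.425, 20619, 0.347, 41425, 0.318),
    ("Opisthocentra clidemioides", 80643, 0.376, 3360, 0.496, 9050, 0.425, 20641, 0.347, 42658, 0.317),
    ("Pterogastra divaricata", 80427, 0.377, 3339, 0.498, 9050, 0.425, 19911, 0.347, 42221, 0.318),
    ("Rhexia virginica", 80466, 0.377, 3353, 0.496, 9050, 0.425, 20260, 0.347, 41506, 0.319),
    ("Rhynchanthera bracteata", 80415, 0.375, 3241, 0.502, 9048, 0.425, 20538, 0.347, 41866, 0.317),
    ("Salpinga maranoniensis", 79326, 0.376, 3349, 0.500, 9050, 0.425, 18991, 0.347, 42595, 0.326),
    ("Tibouchina longifolia", 80682, 0.377, 3348, 0.497, 9050, 0.425, 20666, 0.347, 43043, 0.317),
    ("Triolena amazonica", 80619, 0.375, 3337, 0.496, 9050, 0.425, 20476, 0.347, 43170, 0.316),
]

# the published top-10 marker survey rows: name, class, mean/min/max bases,
# aligned bp, variable sites, PIS, mean K80 distance, RF to the full-plastome
# tree, mean bootstrap (published rank = list position + 1)
_MARKER_ROWS = [
    ("trnS-trnG spacer", "spacer", 780, 628, 884, 1125, 438, 128, 0.104, 4, 82),
    ("ndhF-rpl32 spacer", "spacer", 898, 849, 965, 1266, 507, 171, 0.114, 6, 71),
    ("trnG intron", "intron", 762, 743, 790, 846, 236, 76, 0.059, 4, 75),
    ("ndhC-trnV spacer", "spacer", 734, 504, 821, 991, 330, 98, 0.081, 4, 63),
    ("ndhA intron", "intron", 1016, 939, 1045, 1127, 250, 74, 0.046, 4, 64),
    ("trnG-atpA spacer", "spacer", 641, 550, 750, 895, 353, 136, 0.114, 6, 65),
    ("atpH-atpI spacer", "spacer", 898, 638, 980, 1178, 323, 92, 0.062, 8, 76),
    ("psbE-petL spacer", "spacer", 1058, 570, 1165, 1396, 381, 132, 0.068, 8, 70),
    ("petA-psbJ spacer", "spacer", 736, 420, 944, 1062, 285, 90, 0.076, 8, 76),
    ("trnE-trnT spacer", "spacer", 842, 478, 1029, 1345, 406, 121, 0.089, 8, 63),
]

# survey-wide metric ranges reported for the full 41-marker survey; the
# column maxima anchor "relative values" when scoring the top-10 subset
SURVEY_COLUMN_MAX = {"variable": 507.0, "bootstrap": 82.0, "rf": 22.0}
SURVEY_COLUMN_MIN = {"variable": 12.0, "bootstrap": 26.0, "rf": 4.0}


def region_table() -> pd.DataFrame:
    """Per-species region lengths and GC (one row per plastome)."""
    cols = [
        "species", "accession", "lsc_bp", "lsc_gc", "ssc_bp", "ssc_gc",
        "ir_bp", "ir_gc", "full_bp", "full_gc",
    ]
    return pd.DataFrame(_REGION_ROWS, columns=cols).set_index("species")


def class_table() -> pd.DataFrame:
    """Per-species sequence-class lengths and GC."""
    cols = [
        "species", "protein_coding_bp", "protein_coding_gc", "trna_bp", "trna_gc",
        "rrna_bp", "rrna_gc", "intron_bp", "intron_gc", "intergenic_bp", "intergenic_gc",
    ]
    return pd.DataFrame(_CLASS_ROWS, columns=cols).set_index("species")


def marker_table() -> pd.DataFrame:
    """The published top-10 marker survey metrics, in published rank order."""
    cols = [
        "marker", "mclass", "bases_mean", "bases_min", "bases_max", "aligned_bp",
        "variable_n", "pis_n", "k80_mean", "rf_to_reference", "bootstrap_mean",
    ]
    df = pd.DataFrame(_MARKER_ROWS, columns=cols)
    df["published_rank"] = range(1, len(df) + 1)
    return df
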