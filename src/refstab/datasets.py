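"""Published stability orderings for the five-HKG culture-media study design.

The study design this package emulates profiles five candidate
housekeeping genes (ACTB, EF1A, GAPDH, RPLP0, TBP) in adipose-derived
mesenchymal stromal cells from four donors (ASC1-ASC4) cultured in a
standard serum-containing medium (FBS) and two serum/xeno-free synthetic
media (X1, X2).  The published analysis ranked the five genes with four
algorithms in eleven strata: each medium alone, the medium pairs, all
media together, and each donor across media.

This module stores those published per-algorithm best-to-worst orderings
and the published geometric-mean consensus values as plain data.  They
serve as worked-example inputs (list position = rank; the stepwise
algorithm's tied best pair is a tuple) for re-aggregating the consensus
without the raw Ct measurements, and as a cross-check fixture for the
rank-aggregation code.
"""

from __future__ import annotations

__all__ = [
    "STUDY_HKGS",
    "STUDY_DONORS",
    "STUDY_CONDITIONS",
    "STUDY_TARGETS",
    "CONDITION_STRATA",
    "DONOR_STRATA",
    "STUDY_ORDERINGS",
    "STUDY_GEOMEANS",
    "STUDY_BEST_WORST",
]

STUDY_HKGS = ("ACTB", "EF1A", "GAPDH", "RPLP0", "TBP")
STUDY_DONORS = ("ASC1", "ASC2", "ASC3", "ASC4")
STUDY_CONDITIONS = ("FBS", "X1", "X2")
STUDY_TARGETS = ("LIF", "CCL5", "IL6")

#: Condition-level strata: label -> condition labels pooled.
CONDITION_STRATA = {
    "FBS": ("FBS",),
    "X1": ("X1",),
    "X2": ("X2",),
    "X1/X2": ("X1", "X2"),
    "FBS/X1": ("FBS", "X1"),
    "FBS/X2": ("FBS", "X2"),
    "ALL": ("FBS", "X1", "X2"),
}

#: Donor-level strata: label -> donor (all conditions pooled).
DONOR_STRATA = {d: d for d in STUDY_DONORS}

# Published per-algorithm orderings, best to worst.  Tuples mark tied
# positions (the stepwise algorithm cannot separate its final pair).
STUDY_ORDERINGS = {
    "FBS": {
        "delta_ct": ["EF1A", "TBP", "RPLP0", "ACTB", "GAPDH"],
        "bestkeeper": ["TBP", "EF1A", "RPLP0", "GAPDH", "ACTB"],
        "normfinder": ["EF1A", "TBP", "RPLP0", "ACTB", "GAPDH"],
        "genorm": [("EF1A", "RPLP0"), "TBP", "ACTB", "GAPDH"],
    },
    "X1": {
        "delta_ct": ["GAPDH", "TBP", "ACTB", "EF1A", "RPLP0"],
        "bestkeeper": ["GAPDH", "ACTB", "TBP", "EF1A", "RPLP0"],
        "normfinder": ["GAPDH", "TBP", "ACTB", "EF1A", "RPLP0"],
        "genorm": [("TBP", "GAPDH"), "ACTB", "EF1A", "RPLP0"],
    },
    "X2": {
        "delta_ct": ["GAPDH", "TBP", "ACTB", "RPLP0", "EF1A"],
        "bestkeeper": ["TBP", "ACTB", "GAPDH", "RPLP0", "EF1A"],
        "normfinder": ["GAPDH", "TBP", "ACTB", "RPLP0", "EF1A"],
        "genorm": [("RPLP0", "GAPDH"), "ACTB", "TBP", "EF1A"],
    },
    "X1/X2": {
        "delta_ct": ["GAPDH", "TBP", "ACTB", "EF1A", "RPLP0"],
        "bestkeeper": ["GAPDH", "TBP", "ACTB", "RPLP0", "EF1A"],
        "normfinder": ["GAPDH", "TBP", "ACTB", "EF1A", "RPLP0"],
        "genorm": [("TBP", "GAPDH"), "ACTB", "EF1A", "RPLP0"],
    },
    "FBS/X1": {
        "delta_ct": ["EF1A", "TBP", "GAPDH", "RPLP0", "ACTB"],
        "bestkeeper": ["TBP", "GAPDH", "EF1A", "RPLP0", "ACTB"],
        "normfinder": ["EF1A", "TBP", "GAPDH", "RPLP0", "ACTB"],
        "genorm": [("EF1A", "TBP"), "GAPDH", "RPLP0", "ACTB"],
    },
    "FBS/X2": {
        "delta_ct": ["TBP", "EF1A", "RPLP0", "GAPDH", "ACTB"],
        "bestkeeper": ["TBP", "EF1A", "GAPDH", "RPLP0", "ACTB"],
        "normfinder": ["TBP", "GAPDH", "RPLP0", "EF1A", "ACTB"],
        "genorm": [("EF1A", "TBP"), "RPLP0", "GAPDH", "ACTB"],
    },
    "ALL": {
        "delta_ct": ["GAPDH", "TBP", "EF1A", "RPLP0", "ACTB"],
        "bestkeeper": ["TBP", "GAPDH", "EF1A", "RPLP0", "ACTB"],
        "normfinder": ["GAPDH", "TBP", "EF1A", "RPLP0", "ACTB"],
        "genorm": [("EF1A", "TBP"), "GAPDH", "RPLP0", "ACTB"],
    },
    "ASC1": {
        "delta_ct": ["TBP", "RPLP0", "EF1A", "GAPDH", "ACTB"],
        "bestkeeper": ["RPLP0", "ACTB", "TBP", "EF1A", "GAPDH"],
        "normfinder": ["TBP", "RPLP0", "EF1A", "GAPDH", "ACTB"],
        "genorm": [("EF1A", "GAPDH"), "TBP", "RPLP0", "ACTB"],
    },
    "ASC2": {
        "delta_ct": ["GAPDH", "EF1A", "RPLP0", "TBP", "ACTB"],
        "bestkeeper": ["TBP", "RPLP0", "GAPDH", "EF1A", "ACTB"],
        "normfinder": ["GAPDH", "EF1A", "RPLP0", "TBP", "ACTB"],
        "genorm": [("RPLP0", "TBP"), "GAPDH", "EF1A", "ACTB"],
    },
    "ASC3": {
        "delta_ct": ["GAPDH", "TBP", "EF1A", "RPLP0", "ACTB"],
        "bestkeeper": ["TBP", "GAPDH", "EF1A", "RPLP0", "ACTB"],
        "normfinder": ["TBP", "GAPDH", "EF1A", "RPLP0", "ACTB"],
        "genorm": [("TBP", "GAPDH"), "EF1A", "RPLP0", "ACTB"],
    },
    "ASC4": {
        "delta_ct": ["ACTB", "EF1A", "GAPDH", "RPLP0", "TBP"],
        "bestkeeper": ["GAPDH", "RPLP0", "ACTB", "EF1A", "TBP"],
        "normfinder": ["ACTB", "EF1A", "GAPDH", "RPLP0", "TBP"],
        "genorm": [("ACTB", "GAPDH"), "EF1A", "RPLP0", "TBP"],
    },
}

# Published geometric-mean consensus values (2 decimals) per stratum.
STUDY_GEOMEANS = {
    "FBS": {"EF1A": 1.19, "TBP": 1.86, "RPLP0": 2.28, "ACTB": 4.23, "GAPDH": 4.73},
    "X1": {"GAPDH": 1.00, "TBP": 1.86, "ACTB": 2.71, "EF1A": 4.00, "RPLP0": 5.00},
    "X2": {"GAPDH": 1.32, "TBP": 2.00, "ACTB": 2.71, "RPLP0": 2.83, "EF1A": 5.00},
    "X1/X2": {"GAPDH": 1.00, "TBP": 1.68, "ACTB": 3.00, "EF1A": 4.23, "RPLP0": 4.73},
    "FBS/X1": {"EF1A": 1.32, "TBP": 1.41, "GAPDH": 2.71, "RPLP0": 4.00, "ACTB": 5.00},
    "FBS/X2": {"TBP": 1.00, "EF1A": 2.00, "GAPDH": 3.13, "RPLP0": 3.22, "ACTB": 5.00},
    "ALL": {"TBP": 1.41, "GAPDH": 1.57, "EF1A": 2.28, "RPLP0": 4.00, "ACTB": 5.00},
    "ASC1": {"TBP": 1.73, "RPLP0": 2.00, "EF1A": 2.45, "GAPDH": 2.99, "ACTB": 3.98},
    "ASC2": {"GAPDH": 1.73, "TBP": 2.00, "RPLP0": 2.06, "EF1A": 2.83, "ACTB": 5.00},
    "ASC3": {"TBP": 1.19, "GAPDH": 1.41, "EF1A": 3.00, "RPLP0": 4.00, "ACTB": 5.00},
    "ASC4": {"ACTB": 1.32, "GAPDH": 1.73, "EF1A": 2.63, "RPLP0": 3.36, "TBP": 5.00},
}

#: Published best/worst normalizer per pairwise-comparison stratum, used
#: by the normalizer-impact analysis (best = consensus rank 1, worst =
#: consensus rank G of that comparison's stratum).
STUDY_BEST_WORST = {
    "FBS/X1": ("EF1A", "ACTB"),
    "FBS/X2": ("TBP", "ACTB"),
    "X1/X2": ("GAPDH", "RPLP0"),
}
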