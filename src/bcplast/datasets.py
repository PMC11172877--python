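"""Published subtype-transition and qPCR/RNA-seq summary tables.

These are small label/summary tables from public breast-cancer cohorts
(GEO accessions given per table) as published for matched-sample PAM50
plasticity comparisons, plus the paired pre/post-chemotherapy group-mean
table for a 17-gene qPCR panel from a TNBC neoadjuvant cohort.  They are
label and summary data only — no expression matrices — and serve as
fixed, citable inputs for the transition/retention and direction-
concordance statistics.
"""

from __future__ import annotations

import pandas as pd

from .pam50 import PAM50_CLASSES, TransitionMatrix

__all__ = [
    "PAM50_CLASSES",
    "letrozole_transition_gse10281",
    "chemo_transition_gse32518",
    "chemo_transition_gse32072",
    "brain_metastasis_transition_gse125989",
    "metastasis_patient_records_gse110590",
    "pairs_from_counts",
    "qpcr_rnaseq_mean_table",
    "concordance_rows",
]


def _tm(rows: list[list[int]]) -> TransitionMatrix:
    frame = pd.DataFrame(rows, index=pd.Index(PAM50_CLASSES), columns=pd.Index(PAM50_CLASSES))
    return TransitionMatrix(counts=frame)


def letrozole_transition_gse10281() -> TransitionMatrix:
    """PAM50 calls pre vs post Letrozole therapy, 18 matched pairs (GSE10281)."""
    return _tm(
        [
            [2, 0, 0, 0, 0],
            [1, 1, 0, 2, 0],
            [0, 0, 2, 3, 0],
            [0, 0, 0, 1, 0],
            [3, 0, 1, 1, 1],
        ]
    )


def chemo_transition_gse32518() -> TransitionMatrix:
    """PAM50 calls pre vs post anthracycline/taxane neoadjuvant chemotherapy
    (GSE32518), 28 matched pairs."""
    return _tm(
        [
            [2, 0, 0, 0, 2],
            [1, 1, 0, 1, 1],
            [0, 0, 3, 0, 4],
            [1, 0, 4, 3, 3],
            [0, 0, 1, 0, 1],
        ]
    )


def chemo_transition_gse32072() -> TransitionMatrix:
    """PAM50 calls pre vs post neoadjuvant therapy (GSE32072), 21 matched pairs."""
    return _tm(
        [
            [5, 0, 0, 0, 0],
            [0, 4, 0, 0, 0],
            [0, 0, 5, 1, 0],
            [0, 0, 0, 1, 0],
            [2, 1, 1, 0, 1],
        ]
    )


def brain_metastasis_transition_gse125989() -> TransitionMatrix:
    """PAM50 calls for primary tumors vs matched brain metastases
    (GSE125989), 16 pairs."""
    return _tm(
        [
            [2, 1, 0, 0, 0],
            [1, 2, 0, 0, 1],
            [0, 0, 4, 0, 0],
            [0, 0, 0, 0, 0],
            [3, 2, 0, 0, 0],
        ]
    )


# (patient, primary class, metastasis counts per PAM50 class) — GSE110590,
# 16 primary tumors with 67 matched metastases in total.
_GSE110590 = [
    ("A11", "Basal", [5, 0, 0, 0, 0]),
    ("A15", "Basal", [2, 0, 0, 0, 3]),
    ("A1", "Basal", [4, 0, 0, 0, 1]),
    ("A23", "Basal", [5, 0, 0, 0, 0]),
    ("A5", "Basal", [2, 0, 0, 0, 0]),
    ("A7", "Basal", [5, 0, 0, 0, 0]),
    ("A8", "HER2", [0, 4, 0, 0, 0]),
    ("A12", "LumA", [0, 0, 2, 4, 0]),
    ("A17", "LumA", [2, 0, 0, 0, 0]),
    ("A26", "LumA", [3, 0, 0, 0, 0]),
    ("A28", "LumA", [0, 0, 3, 3, 0]),
    ("A2", "LumA", [0, 1, 0, 2, 0]),
    ("A30", "LumA", [5, 0, 0, 0, 0]),
    ("A34", "LumA", [0, 0, 4, 0, 0]),
    ("A4", "LumA", [0, 1, 1, 0, 0]),
    ("A20", "Normal", [5, 0, 0, 0, 0]),
]


def metastasis_patient_records_gse110590() -> dict[str, tuple[str, list[str]]]:
    """Primary vs multi-site metastasis PAM50 calls per patient (GSE110590).

    Returns ``{patient: (primary_label, [one label per metastasis])}``,
    ready for :func:`bcplast.pam50.per_primary_transitions`.
    """
    records: dict[str, tuple[str, list[str]]] = {}
    for patient, primary, counts in _GSE110590:
        mets: list[str] = []
        for cls, n in zip(PAM50_CLASSES, counts):
            mets.extend([cls] * n)
        records[patient] = (primary, mets)
    return records


def pairs_from_counts(tm: TransitionMatrix) -> list[tuple[str, str]]:
    """Expand a transition count matrix back into a paired-label list."""
    pairs: list[tuple[str, str]] = []
    for r in tm.class_names:
        for c in tm.class_names:
            pairs.extend([(r, c)] * int(tm.counts.loc[r, c]))
    return pairs


# Published group means (before/after neoadjuvant chemotherapy) for the
# 17-gene qPCR chemoresistance panel of a TNBC cohort: qPCR on the −ΔΔCt
# scale and RNA-seq from the same samples under three normalizations
# (median-of-ratios/DESeq, FPKM, TMM), on a log-like reporting scale.
_QPCR_TABLE = [
    # gene, qpcr_bc, qpcr_ac, deseq_bc, deseq_ac, fpkm_bc, fpkm_ac, tmm_bc, tmm_ac
    ("ABHD4", 6.37, 2.98, 7.67, 7.98, 0.93, 1.37, 7.55, 8.12),
    ("CDYL2", 8.35, 7.39, 8.28, 8.24, 0.74, 0.94, 8.15, 8.38),
    ("COPS7A", 7.72, 4.23, 8.66, 8.61, 1.75, 2.05, 8.53, 8.75),
    ("DPM2", 11.64, 8.75, 7.89, 7.68, 1.26, 1.42, 7.75, 7.82),
    ("GSG1", 10.74, 7.88, 2.30, 1.11, 0.11, 0.02, 2.24, 0.98),
    ("JMJD7", 10.78, 7.17, 5.13, 5.33, 0.43, 0.59, 5.07, 5.47),
    ("KIAA1456", 11.04, 6.33, 7.54, 7.39, 0.41, 0.44, 7.41, 7.53),
    ("KRTAP17-1", 12.07, 6.47, 1.05, 0.36, 0.07, 0.02, 0.92, 0.42),
    ("LIN9", 9.49, 7.21, 7.83, 7.40, 1.00, 1.03, 7.71, 7.54),
    ("MIGLL", 6.27, 4.59, 8.67, 9.09, 0.79, 1.28, 8.54, 9.23),
    ("OFD1", 6.44, 4.19, 10.64, 10.76, 2.72, 3.23, 10.51, 10.90),
    ("PHKA2", 8.25, 6.05, 9.36, 9.24, 1.20, 1.43, 9.23, 9.38),
    ("PRMT7", 10.93, 6.34, 9.31, 9.24, 1.12, 1.38, 9.17, 9.38),
    ("ST3GAL4", 7.12, 3.31, 8.91, 8.77, 1.57, 1.80, 8.78, 8.91),
    ("TAL2", 9.09, 3.64, 1.76, 0.87, 0.15, 0.08, 1.62, 0.96),
    ("TMTM221", 7.64, 3.50, 2.35, 1.53, 0.08, 0.05, 2.16, 1.51),
    ("ZDHHC7", 6.12, 3.41, 9.35, 9.51, 2.03, 2.49, 9.22, 9.65),
]

_SCHEMES = ("qpcr", "deseq", "fpkm", "tmm")


def qpcr_rnaseq_mean_table() -> pd.DataFrame:
    """The full 17-gene group-mean table (all four measurement schemes)."""
    cols = ["gene_id"] + [f"{s}_{g}" for s in _SCHEMES for g in ("bc", "ac")]
    return pd.DataFrame(_QPCR_TABLE, columns=cols).set_index("gene_id")


def concordance_rows(scheme: str) -> pd.DataFrame:
    """Group-mean rows (mean_bc/mean_ac) for one measurement scheme,
    shaped for :func:`bcplast.normalize.direction_concordance`."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    t = qpcr_rnaseq_mean_table()
    return t[[f"{scheme}_bc", f"{scheme}_ac"]].rename(
        columns={f"{scheme}_bc": "mean_bc", f"{scheme}_ac": "mean_ac"}
    )
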