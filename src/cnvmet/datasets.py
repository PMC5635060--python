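"""Bundled reference tables.

``SNU_CLINICAL_TABLES`` holds the published clinico-pathological
contingency tables of a 64-patient HBV-related HCC cohort (GEO GSE87630)
stratified by its three integrative molecular subtypes (n = 9 / 24 / 31,
ordered aggressive to favorable).  Rows are the two clinical levels, columns
the three subtypes.  These serve as a worked example and regression anchor
for the chi-square association test.

The vascular-invasion row of the published table is internally inconsistent
with the subtype sizes (its column sums are 8/31/24 against n = 9/24/31), so
it is kept separately under ``SNU_CLINICAL_TABLES_INCONSISTENT`` and not
treated as a verified reference.
"""

from __future__ import annotations

SNU_SUBTYPE_SIZES = (9, 24, 31)

#: feature -> (row labels, 2x3 count table)
SNU_CLINICAL_TABLES: dict[str, tuple[tuple[str, str], list[list[int]]]] = {
    "sex": (("Male", "Female"), [[8, 19, 29], [1, 5, 2]]),
    "age": (("<60", ">=60"), [[5, 12, 16], [4, 12, 15]]),
    "stage": (("T1/T2", "T3/T4"), [[5, 21, 27], [4, 3, 4]]),
    "nodal_metastasis": (("No", "Yes"), [[7, 24, 30], [1, 0, 0]]),
    "tumor_size": (("<5cm", ">=5cm"), [[6, 10, 12], [3, 14, 19]]),
    "gross_type": (
        ("Simple nodular", "Multi nodular/infiltrative"),
        [[3, 16, 14], [6, 7, 16]],
    ),
    "afp": (("<400", ">=400"), [[5, 18, 25], [4, 5, 6]]),
    "grade": (("I,II", "III,IV"), [[2, 11, 19], [4, 5, 10]]),
}

SNU_CLINICAL_TABLES_INCONSISTENT: dict[str, tuple[tuple[str, str], list[list[int]]]] = {
    "vascular_invasion": (("No", "Yes"), [[1, 15, 19], [7, 16, 5]]),
}
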