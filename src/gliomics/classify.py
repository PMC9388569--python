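"""WHO-2021 molecular subtype assignment for diffuse gliomas.

The 2021 WHO classification splits adult diffuse gliomas on IDH hotspot
mutation and 1p/19q codeletion:

* IDH-mutant with 1p/19q codeletion -> oligodendroglioma,
* IDH-mutant without codeletion -> astrocytoma, IDH-mutant,
* IDH-wildtype tumors are glioblastoma when grade 4, or — even at
  histological grade 2/3 — when they carry combined chromosome 7 gain and
  chromosome 10 loss, a TERT promoter mutation, or EGFR amplification,
* IDH-wildtype grade 2/3 tumors with none of those markers stay
  unclassified (and are excluded from cohort analyses).

Markers are tri-state (True / False / unknown).  An unknown marker leads
to ``unclassified`` only when it is decisive; an unknown IDH status, the
primary split, is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

OLIGODENDROGLIOMA = "oligodendroglioma_IDHmut_codel"
ASTROCYTOMA = "astrocytoma_IDHmut"
GLIOBLASTOMA = "glioblastoma_IDHwt"
UNCLASSIFIED = "unclassified"
SUBTYPES = (OLIGODENDROGLIOMA, ASTROCYTOMA, GLIOBLASTOMA, UNCLASSIFIED)


@dataclass
class CaseMarkers:
    """Molecular markers of one case; None encodes unknown."""

    case_id: str = ""
    idh_mutant: bool | None = None
    codel_1p19q: bool | None = None
    grade: int | None = None
    chr7_gain: bool | None = None
    chr10_loss: bool | None = None
    tert_promoter: bool | None = None
    egfr_amplified: bool | None = None

    def __post_init__(self) -> None:
        if self.grade is not None and self.grade not in (2, 3, 4):
            raise ValueError(f"grade must be 2, 3 or 4, got {self.grade}")


def classify_who2021(markers: CaseMarkers) -> str:
    """Assign the WHO-2021 subtype label for one case.

    Exactly one label is returned for fully specified markers; 1p/19q
    codeletion alone never yields oligodendroglioma without IDH mutation.
    """
    m = markers
    if m.idh_mutant is None:
        raise ValueError(f"case {m.case_id or '?'}: IDH status unknown, classification impossible")
    if m.idh_mutant:
        if m.codel_1p19q is None:
            return UNCLASSIFIED
        return OLIGODENDROGLIOMA if m.codel_1p19q else ASTROCYTOMA
    # IDH-wildtype: glioblastoma on grade 4 or any molecular GBM criterion.
    combined_7_10 = None
    if m.chr7_gain is False or m.chr10_loss is False:
        combined_7_10 = False
    elif m.chr7_gain and m.chr10_loss:
        combined_7_10 = True
    criteria = [m.grade == 4 if m.grade is not None else None,
                combined_7_10, m.tert_promoter, m.egfr_amplified]
    if any(c is True for c in criteria):
        return GLIOBLASTOMA
    return UNCLASSIFIED


def classify_cohort(clinical: pd.DataFrame) -> pd.Series:
    """Vector version over a clinical table; returns a label per case.

    Expects boolean-ish columns ``idh_mutant``, ``codel_1p19q``,
    ``chr7_gain``, ``chr10_loss``, ``tert_promoter``, ``egfr_amplified``
    and an integer ``grade``; NaN encodes unknown.
    """

    def _tri(v):
        if pd.isna(v):
            return None
        return bool(v)

    labels = []
    for row in clinical.itertuples():
        m = CaseMarkers(
            case_id=str(getattr(row, "case_id", row.Index)),
            idh_mutant=_tri(row.idh_mutant),
            codel_1p19q=_tri(row.codel_1p19q),
            grade=None if pd.isna(row.grade) else int(row.grade),
            chr7_gain=_tri(row.chr7_gain),
            chr10_loss=_tri(row.chr10_loss),
            tert_promoter=_tri(row.tert_promoter),
            egfr_amplified=_tri(row.egfr_amplified),
        )
        labels.append(classify_who2021(m))
    return pd.Series(labels, index=clinical.index, name="who2021")
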