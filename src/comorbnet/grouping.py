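"""From coded diagnosis records to per-stratum binary disease matrices.

Raw records carry one coded diagnosis event per row (ICD-9-CM or ICPC-1).
Two user-supplied lookup tables drive the reduction: a chronic-condition
flag per code, and a code-to-clinical-category grouping (the machinery of
the AHRQ Chronic Condition Indicator and Clinical Classifications Software
steps; the real distributed tables are external resources and are not
shipped — only the toy fixtures used in tests).

The output is one :class:`DiseaseMatrix` per (sex, age band) stratum:
a binary patient x category indicator grid where a patient scores 1 on a
category iff at least one of their chronic diagnoses maps to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from comorbnet.tetrachoric import ContingencyTable

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "DiagnosisRecord",
    "CodeLookup",
    "DiseaseMatrix",
    "RecordError",
    "age_to_band",
    "read_records",
    "read_lookup",
    "filter_chronic",
    "build_matrix",
]

#: The five age intervals used for stratification, youngest first.
AGE_BANDS = ("0-2", "3-10", "11-17", "18-65", ">65")
SEXES = ("M", "F")

_BAND_EDGES = ((0, 2), (3, 10), (11, 17), (18, 65))


class RecordError(ValueError):
    """Raised on unrecoverable record problems (conflicting demographics,
    missing columns)."""


def _normalize_band(token: str) -> str:
    # accept en/em dashes and surrounding space in age-band tokens
    return token.strip().replace("–", "-").replace("—", "-").replace(" ", "")


def age_to_band(age: float) -> str:
    """Map a raw age in years to its band: [0,2], [3,10], [11,17], [18,65],
    (65, inf), with inclusive integer bounds."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    for (lo, hi), band in zip(_BAND_EDGES, AGE_BANDS):
        if lo <= age <= hi:
            return band
    return ">65"


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    sex: str
    age_band: str
    code: str
    coding_system: str = "ICD9CM"


@dataclass
class CodeLookup:
    """Chronic flag and clinical-category grouping for diagnosis codes.

    ``chronic`` maps code -> bool; ``category`` maps code ->
    (category_id, category_label).  ``index_category_id`` optionally names
    the cohort-defining index condition (e.g. the atopic-dermatitis
    category), which is excluded from matrices by default because a disease
    present in essentially every patient has degenerate margins.
    """

    chronic: dict[str, bool]
    category: dict[str, tuple[int, str]]
    index_category_id: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.category if c not in self.chronic]
        if missing:
            raise ValueError(
                f"codes in category table missing from chronic table: {missing[:5]}")
        ids: dict[int, str] = {}
        for code, (cid, label) in self.category.items():
            if cid in ids and ids[cid] != label:
                raise ValueError(
                    f"category id {cid} carries two labels: {ids[cid]!r}, {label!r}")
            ids[cid] = label
        if ids:
            lo, hi = min(ids), max(ids)
            if set(ids) != set(range(lo, hi + 1)):
                raise ValueError("category ids must form a contiguous set")
        self._labels_by_id = dict(sorted(ids.items()))

    @property
    def categories(self) -> dict[int, str]:
        """category_id -> label, ordered by id."""
        return dict(self._labels_by_id)


@dataclass
class DiseaseMatrix:
    """Binary patient x disease-category indicators for one stratum."""

    stratum: tuple[str, str]
    patients: list[str]
    diseases: list[str]
    indicators: np.ndarray  # shape (n_patients, n_diseases), values {0,1}

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=np.uint8)
        if self.indicators.shape != (len(self.patients), len(self.diseases)):
            raise ValueError("indicator shape does not match patients x diseases")
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValueError("indicators must be 0/1")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def prevalences(self) -> np.ndarray:
        """Per-disease fraction of patients with the disease (column mean)."""
        if self.n_patients == 0:
            return np.zeros(len(self.diseases))
        return self.indicators.mean(axis=0)

    def restrict(self, keep: np.ndarray) -> "DiseaseMatrix":
        """A copy restricted to the disease columns selected by ``keep``."""
        keep = np.asarray(keep)
        return DiseaseMatrix(
            stratum=self.stratum,
            patients=list(self.patients),
            diseases=[d for d, k in zip(self.diseases, keep) if k],
            indicators=self.indicators[:, keep],
        )

    def pair_table(self, i: int, j: int) -> ContingencyTable:
        """2x2 joint counts for disease columns ``i`` and ``j``."""
        a = self.indicators[:, i].astype(bool)
        b = self.indicators[:, j].astype(bool)
        n11 = int(np.sum(a & b))
        n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b))
        return ContingencyTable(n11, n10, n01, self.n_patients - n11 - n10 - n01)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.indicators, index=self.patients,
                            columns=self.diseases)


def read_records(path, delimiter: str = "\t",
                 columns: dict[str, str] | None = None
                 ) -> tuple[list[DiagnosisRecord], pd.DataFrame]:
    """Read long-format diagnosis records from delimited text.

    ``columns`` remaps logical names (patient_id, sex, age_band, code,
    coding_system) to the file's header names.  Malformed rows are not
    silently dropped: they are returned as a rejects report with a reason
    per row.  A missing required column is a hard error naming it.
    """
    names = {"patient_id": "patient_id", "sex": "sex", "age_band": "age_band",
             "code": "code", "coding_system": "coding_system"}
    if columns:
        names.update(columns)
    df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    for logical in ("patient_id", "sex", "age_band", "code"):
        if names[logical] not in df.columns:
            raise RecordError(f"missing required column {names[logical]!r}")
    has_system = names["coding_system"] in df.columns

    records: list[DiagnosisRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        sex = row[names["sex"]].strip().upper()
        band = _normalize_band(row[names["age_band"]])
        pid = row[names["patient_id"]].strip()
        code = row[names["code"]].strip()
        reason = None
        if not pid:
            reason = "empty patient id"
        elif sex not in SEXES:
            reason = f"unknown sex {row[names['sex']]!r}"
        elif band not in AGE_BANDS:
            reason = "unknown age band"
        elif not code:
            reason = "empty code"
        if reason is not None:
            rejects.append({"row": int(idx), "reason": reason, **row.to_dict()})
            continue
        system = row[names["coding_system"]].strip() if has_system else "ICD9CM"
        records.append(DiagnosisRecord(pid, sex, band, code, system or "ICD9CM"))
    rejects_df = pd.DataFrame(rejects, columns=["row", "reason", *df.columns])
    return records, rejects_df


def read_lookup(chronic_path, category_path, delimiter: str = "\t",
                index_category_id: int | None = None) -> CodeLookup:
    """Load the two lookup tables.

    Chronic table schema: columns ``code``, ``chronic_flag`` (values
    chronic / not_chronic, or 1 / 0).  Category table schema: columns
    ``code``, ``category_id``, ``category_label``.
    """
    cdf = pd.read_csv(chronic_path, sep=delimiter, dtype=str)
    for col in ("code", "chronic_flag"):
        if col not in cdf.columns:
            raise RecordError(f"chronic table missing column {col!r}")
    truthy = {"chronic", "1", "true", "yes"}
    falsy = {"not_chronic", "0", "false", "no"}
    chronic: dict[str, bool] = {}
    for _, row in cdf.iterrows():
        flag = str(row["chronic_flag"]).strip().lower()
        if flag in truthy:
            chronic[str(row["code"]).strip()] = True
        elif flag in falsy:
            chronic[str(row["code"]).strip()] = False
        else:
            raise RecordError(f"unknown chronic flag {row['chronic_flag']!r}")
    gdf = pd.read_csv(category_path, sep=delimiter, dtype=str)
    for col in ("code", "category_id", "category_label"):
        if col not in gdf.columns:
            raise RecordError(f"category table missing column {col!r}")
    category = {str(r["code"]).strip(): (int(r["category_id"]),
                                         str(r["category_label"]).strip())
                for _, r in gdf.iterrows()}
    return CodeLookup(chronic=chronic, category=category,
                      index_category_id=index_category_id)


def filter_chronic(records: list[DiagnosisRecord], lookup: CodeLookup
                   ) -> tuple[list[DiagnosisRecord], pd.DataFrame]:
    """Keep records whose code is flagged chronic.

    Codes absent from the chronic table are excluded and reported (code,
    count) rather than raising: unmapped codes are a data-quality fact, not
    a programming error.
    """
    kept: list[DiagnosisRecord] = []
    unmapped: dict[str, int] = {}
    for rec in records:
        flag = lookup.chronic.get(rec.code)
        if flag is None:
            unmapped[rec.code] = unmapped.get(rec.code, 0) + 1
        elif flag:
            kept.append(rec)
    report = pd.DataFrame(sorted(unmapped.items()), columns=["code", "count"])
    return kept, report


def build_matrix(records: list[DiagnosisRecord], lookup: CodeLookup,
                 retain_index: bool = False
                 ) -> dict[tuple[str, str], DiseaseMatrix]:
    """Group chronic records into one binary matrix per (sex, age band).

    A patient scores 1 on a category iff at least one of their records maps
    to it (duplicate diagnoses are idempotent).  A patient whose rows carry
    conflicting sex or age band is a hard error — first-seen-wins would
    silently misstratify.  Codes absent from the category table are
    ignored here (route them through :func:`filter_chronic` first to get
    the unmapped report).  The index category, when designated on the
    lookup, is excluded unless ``retain_index``.
    """
    demo: dict[str, tuple[str, str]] = {}
    for rec in records:
        seen = demo.get(rec.patient_id)
        if seen is None:
            demo[rec.patient_id] = (rec.sex, rec.age_band)
        elif seen != (rec.sex, rec.age_band):
            raise RecordError(
                f"patient {rec.patient_id!r} has conflicting demographics: "
                f"{seen} vs {(rec.sex, rec.age_band)}")

    cats = lookup.categories
    if lookup.index_category_id is not None and not retain_index:
        cats = {cid: lab for cid, lab in cats.items()
                if cid != lookup.index_category_id}
    col_of = {cid: j for j, cid in enumerate(cats)}
    labels = list(cats.values())

    by_stratum: dict[tuple[str, str], dict[str, set[int]]] = {}
    for rec in records:
        mapped = lookup.category.get(rec.code)
        stratum_key = demo[rec.patient_id]
        patients = by_stratum.setdefault(stratum_key, {})
        hits = patients.setdefault(rec.patient_id, set())
        if mapped is not None and mapped[0] in col_of:
            hits.add(col_of[mapped[0]])

    out: dict[tuple[str, str], DiseaseMatrix] = {}
    for stratum_key in sorted(by_stratum):
        patients = by_stratum[stratum_key]
        pids = sorted(patients)
        grid = np.zeros((len(pids), len(labels)), dtype=np.uint8)
        for i, pid in enumerate(pids):
            for j in patients[pid]:
                grid[i, j] = 1
        out[stratum_key] = DiseaseMatrix(
            stratum=stratum_key, patients=pids, diseases=labels, indicators=grid)
    return out
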