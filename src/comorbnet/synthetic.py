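"""Synthetic stratified cohorts with known ground truth.

Real EHR-derived cohorts of this kind cannot be redistributed, so the
package ships a generator whose planted structure every downstream stage
can be tested against.  The model is the latent-Gaussian threshold model
that the tetrachoric correlation inverts exactly: each patient draws a
latent multivariate normal with a block-structured correlation matrix
(diseases in the same block share latent correlation ``rho_within``,
cross-block pairs ``rho_between``), and disease j is present iff the j-th
latent coordinate exceeds the upper-``prevalence_j`` standard-normal
quantile.  Blocks are the planted comorbidity patterns.

Seed contract: each stratum uses a fresh ``numpy`` Generator seeded by
``SeedSequence([seed, crc32("SEX|BAND")])`` and draws a single
``standard_normal((n_patients, n_diseases))`` block (row-major), so a
stratum's data depend only on the master seed and the stratum label.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from comorbnet.grouping import AGE_BANDS, SEXES, CodeLookup, DiseaseMatrix
from comorbnet.tetrachoric import ContingencyTable

__all__ = [
    "DiseaseSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortSpecError",
    "build_latent_sigma",
    "generate_cohort",
    "median_split_pair",
    "default_spec",
    "write_cohort",
    "read_cohort",
    "write_cohort_records",
    "identity_lookup",
]


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class DiseaseSpec:
    """One synthetic disease: its label, population prevalence, and the
    planted community (block) it belongs to."""

    disease_id: str
    prevalence: float
    block_id: int

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise CohortSpecError(
                f"prevalence of {self.disease_id!r} must be in (0,1), "
                f"got {self.prevalence}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a stratified synthetic cohort."""

    strata: tuple[tuple[str, str, int], ...]  # (sex, age_band, n_patients)
    diseases: tuple[DiseaseSpec, ...]
    rho_within: float = 0.5
    rho_between: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata:
            raise CohortSpecError("strata list is empty")
        for sex, band, n in self.strata:
            if sex not in SEXES:
                raise CohortSpecError(f"unknown sex {sex!r}")
            if band not in AGE_BANDS:
                raise CohortSpecError(f"unknown age band {band!r}")
            if n <= 0:
                raise CohortSpecError(f"stratum ({sex},{band}) has n={n} <= 0")
        ids = [d.disease_id for d in self.diseases]
        if len(set(ids)) != len(ids):
            raise CohortSpecError("disease ids must be unique")
        if not -1.0 < self.rho_within < 1.0 or not -1.0 < self.rho_between < 1.0:
            raise CohortSpecError("latent correlations must lie in (-1, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: the latent correlation matrix, the block
    label per disease, and the prevalence-matching thresholds."""

    sigma: np.ndarray
    disease_ids: tuple[str, ...]
    blocks: tuple[int, ...]
    thresholds: np.ndarray
    seed: int

    def block_of(self) -> dict[str, int]:
        return dict(zip(self.disease_ids, self.blocks))

    def to_json(self) -> str:
        return json.dumps({
            "disease_ids": list(self.disease_ids),
            "blocks": list(self.blocks),
            "thresholds": [float(t) for t in self.thresholds],
            "sigma": [[float(v) for v in row] for row in self.sigma],
            "seed": self.seed,
        }, indent=1)


def build_latent_sigma(spec: CohortSpec) -> np.ndarray:
    """The planted latent correlation matrix: unit diagonal, ``rho_within``
    for same-block pairs, ``rho_between`` otherwise.

    Raises :class:`CohortSpecError` if the implied matrix is not positive
    definite (e.g. a large block with negative within-correlation).
    """
    blocks = np.array([d.block_id for d in spec.diseases])
    same = blocks[:, None] == blocks[None, :]
    sigma = np.where(same, spec.rho_within, spec.rho_between).astype(float)
    np.fill_diagonal(sigma, 1.0)
    eigmin = float(np.linalg.eigvalsh(sigma).min()) if len(sigma) else 1.0
    if eigmin <= 1e-12:
        raise CohortSpecError(
            f"latent correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}) for rho_within={spec.rho_within}, "
            f"rho_between={spec.rho_between}, "
            f"block sizes {np.bincount(blocks - blocks.min()).tolist()}")
    return sigma


def _stratum_rng(seed: int, sex: str, band: str) -> np.random.Generator:
    tag = zlib.crc32(f"{sex}|{band}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def generate_cohort(spec: CohortSpec
                    ) -> tuple[dict[tuple[str, str], DiseaseMatrix], GroundTruth]:
    """Draw the cohort: one binary DiseaseMatrix per stratum plus the
    planted ground truth.  Identical spec (including seed) gives
    bit-identical matrices."""
    if not spec.diseases:
        raise CohortSpecError("no diseases specified")
    sigma = build_latent_sigma(spec)
    chol = np.linalg.cholesky(sigma)
    prevalences = np.array([d.prevalence for d in spec.diseases])
    thresholds = -special.ndtri(prevalences)  # P(Z > t) = prevalence
    ids = tuple(d.disease_id for d in spec.diseases)

    matrices: dict[tuple[str, str], DiseaseMatrix] = {}
    for sex, band, n in spec.strata:
        rng = _stratum_rng(spec.seed, sex, band)
        z = rng.standard_normal((n, len(ids)))
        latent = z @ chol.T
        grid = (latent > thresholds).astype(np.uint8)
        width = len(str(n - 1))
        pids = [f"{sex}-{band}-{i:0{width}d}" for i in range(n)]
        matrices[(sex, band)] = DiseaseMatrix(
            stratum=(sex, band), patients=pids, diseases=list(ids),
            indicators=grid)
    truth = GroundTruth(sigma=sigma, disease_ids=ids,
                        blocks=tuple(d.block_id for d in spec.diseases),
                        thresholds=thresholds, seed=spec.seed)
    return matrices, truth


def median_split_pair(rho: float, n: int, seed: int = 0) -> ContingencyTable:
    """Sample a 2x2 table from a latent bivariate normal with correlation
    ``rho``, both traits thresholded at the median (prevalence 0.5).

    The expected joint-positive fraction is the closed orthant form
    1/4 + arcsin(rho)/(2*pi) — the sharp end-to-end check for the
    tetrachoric estimator.
    """
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    a, b = x > 0, y > 0
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    return ContingencyTable(n11, n10, n01, n - n11 - n10 - n01)


def default_spec(n_blocks: int = 3, diseases_per_block: int = 8,
                 n_per_stratum: int = 5000, rho_within: float = 0.5,
                 rho_between: float = 0.0, seed: int = 0,
                 strata: tuple[tuple[str, str, int], ...] | None = None
                 ) -> CohortSpec:
    """The package's reference planted-block cohort: 3 blocks x 8 diseases,
    within-block latent correlation 0.5, both sexes x all five age bands,
    5000 patients per stratum.  Disease prevalences cycle over
    {0.05, 0.10, 0.20, 0.30} — all above the 1% analysis floor.
    """
    prev_cycle = (0.05, 0.10, 0.20, 0.30)
    diseases = tuple(
        DiseaseSpec(disease_id=f"D{b:02d}{j:02d}",
                    prevalence=prev_cycle[(b * diseases_per_block + j) % len(prev_cycle)],
                    block_id=b)
        for b in range(n_blocks) for j in range(diseases_per_block))
    if strata is None:
        strata = tuple((sex, band, n_per_stratum)
                       for sex in SEXES for band in AGE_BANDS)
    return CohortSpec(strata=strata, diseases=diseases,
                      rho_within=rho_within, rho_between=rho_between, seed=seed)


def write_cohort(matrices: dict[tuple[str, str], DiseaseMatrix],
                 truth: GroundTruth, records_path, sidecar_path=None,
                 delimiter: str = "\t") -> None:
    """Write the cohort as long-format text (patient_id, sex, age_band,
    disease_id, indicator — one row per patient x disease, zeros included
    so the round trip is lossless) plus a JSON ground-truth sidecar."""
    frames = []
    for (sex, band), mat in matrices.items():
        df = mat.to_frame().stack().reset_index()
        df.columns = ["patient_id", "disease_id", "indicator"]
        df.insert(1, "sex", sex)
        df.insert(2, "age_band", band)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        records_path, sep=delimiter, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            fh.write(truth.to_json())


def read_cohort(records_path, delimiter: str = "\t"
                ) -> dict[tuple[str, str], DiseaseMatrix]:
    """Read a cohort written by :func:`write_cohort` back into matrices."""
    df = pd.read_csv(records_path, sep=delimiter, dtype={"patient_id": str,
                                                         "disease_id": str})
    out: dict[tuple[str, str], DiseaseMatrix] = {}
    for (sex, band), grp in df.groupby(["sex", "age_band"], sort=True):
        wide = grp.pivot(index="patient_id", columns="disease_id",
                         values="indicator")
        wide = wide.sort_index()
        out[(sex, band)] = DiseaseMatrix(
            stratum=(sex, band), patients=list(wide.index),
            diseases=list(wide.columns),
            indicators=wide.to_numpy(dtype=np.uint8))
    return out


def write_cohort_records(matrices: dict[tuple[str, str], DiseaseMatrix],
                         path, delimiter: str = "\t",
                         coding_system: str = "SYNTH") -> None:
    """Write positive indicators as diagnosis records (patient_id, sex,
    age_band, code, coding_system) — the shape the grouping stage reads.
    Patients with no disease at all produce no rows, exactly as real
    diagnosis extracts behave."""
    rows = []
    for (sex, band), mat in matrices.items():
        ii, jj = np.nonzero(mat.indicators)
        for i, j in zip(ii.tolist(), jj.tolist()):
            rows.append((mat.patients[i], sex, band, mat.diseases[j],
                         coding_system))
    pd.DataFrame(rows, columns=["patient_id", "sex", "age_band", "code",
                                "coding_system"]).to_csv(
        path, sep=delimiter, index=False)


def identity_lookup(disease_ids, index_category_id: int | None = None
                    ) -> CodeLookup:
    """A lookup where each synthetic disease id is its own chronic code and
    its own category — lets synthetic cohorts flow through the grouping
    stage unchanged."""
    ids = list(disease_ids)
    return CodeLookup(
        chronic={d: True for d in ids},
        category={d: (i, d) for i, d in enumerate(ids)},
        index_category_id=index_category_id)
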