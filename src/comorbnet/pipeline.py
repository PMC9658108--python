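"""End-to-end orchestration: records -> chronic filter -> per-stratum
matrices -> filtered networks -> Louvain patterns -> reports and exports.

With both sexes and all five age bands present this yields ten disease
networks, one per stratum, each with its own community partition.  Every
artifact of a run (networks, partitions, demographics, pattern report,
resolved config, log) lands in the output directory, and a rerun with the
same config and seed is bit-identical (file timestamps aside).
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from comorbnet import community as community_mod
from comorbnet import grouping, network, synthetic
from comorbnet.grouping import AGE_BANDS, DiseaseMatrix
from comorbnet.synthetic import CohortSpec

__all__ = ["RunConfig", "StratumResult", "PatternReport", "ConfigError",
           "run", "summarize_demographics", "percentage_table",
           "analyze_matrices"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run.

    Exactly one input source: either the three file paths (records +
    chronic/category lookups) or a synthetic cohort spec.
    """

    records_path: str | None = None
    chronic_path: str | None = None
    category_path: str | None = None
    cohort_spec: CohortSpec | None = None
    alpha: float = 0.01
    min_prevalence: float = 0.01
    edge_sign: str = "positive"
    louvain_restarts: int = 5
    resolution: float = 1.0
    seed: int = 0
    out_dir: str | None = None
    formats: tuple[str, ...] = ("graphml",)
    delimiter: str = "\t"
    index_category_id: int | None = None

    def __post_init__(self) -> None:
        from_files = self.records_path is not None
        from_spec = self.cohort_spec is not None
        if from_files == from_spec:
            raise ConfigError(
                "exactly one input source required: records files XOR a "
                "synthetic cohort spec")
        if from_files and (self.chronic_path is None or self.category_path is None):
            raise ConfigError("records input needs chronic and category lookup paths")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 <= self.min_prevalence < 1.0:
            raise ConfigError(
                f"min_prevalence must be in [0,1), got {self.min_prevalence}")
        if self.louvain_restarts < 1:
            raise ConfigError("louvain_restarts must be >= 1")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # the snapshot's own location; not a parameter
        if self.cohort_spec is not None:
            d["cohort_spec"] = {
                "strata": [list(s) for s in self.cohort_spec.strata],
                "diseases": [dataclasses.asdict(x) for x in self.cohort_spec.diseases],
                "rho_within": self.cohort_spec.rho_within,
                "rho_between": self.cohort_spec.rho_between,
                "seed": self.cohort_spec.seed,
            }
        d["formats"] = list(self.formats)
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class StratumResult:
    stratum: tuple[str, str]
    n_patients: int
    net: nx.Graph
    partition: community_mod.Partition
    prevalences: dict[str, float]

    @property
    def empty(self) -> bool:
        return self.net.number_of_nodes() == 0


@dataclass
class PatternReport:
    """Per-stratum network summaries and community (pattern) memberships."""

    strata: list[StratumResult] = field(default_factory=list)
    demographics: pd.DataFrame | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append({
                "sex": s.stratum[0], "age_band": s.stratum[1],
                "n_patients": s.n_patients,
                "n_diseases": s.net.number_of_nodes(),
                "n_edges": s.net.number_of_edges(),
                "n_patterns": s.partition.n_communities,
                "modularity": round(s.partition.q, 6),
            })
        return pd.DataFrame(rows)

    def pattern_frame(self) -> pd.DataFrame:
        """One row per disease: stratum, pattern id, prevalence; diseases
        within a pattern sorted by descending prevalence."""
        rows = []
        for s in self.strata:
            for cid, members in enumerate(s.partition.communities()):
                ranked = sorted(members, key=lambda d: (-s.prevalences[d], d))
                for rank, disease in enumerate(ranked):
                    rows.append({
                        "sex": s.stratum[0], "age_band": s.stratum[1],
                        "pattern": cid, "rank": rank, "disease": disease,
                        "prevalence": round(s.prevalences[disease], 6),
                    })
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["# Comorbidity pattern report", ""]
        if self.demographics is not None:
            lines += ["## Demographics", "", self.demographics.to_markdown(), ""]
        for s in self.strata:
            sex, band = s.stratum
            lines.append(f"## Stratum {sex} {band} "
                         f"(n={s.n_patients})")
            if s.empty:
                lines += ["", "*empty after prevalence filtering*", ""]
                continue
            lines.append(f"{s.net.number_of_nodes()} diseases, "
                         f"{s.net.number_of_edges()} edges, "
                         f"{s.partition.n_communities} patterns, "
                         f"modularity q = {s.partition.q:.4f}")
            for cid, members in enumerate(s.partition.communities()):
                ranked = sorted(members, key=lambda d: (-s.prevalences[d], d))
                top = ", ".join(
                    f"{d} ({100 * s.prevalences[d]:.1f}%)" for d in ranked)
                intra = sorted(
                    ((u, v, d["rho"]) for u, v, d in s.net.edges(data=True)
                     if s.partition.assignment[u] == cid
                     and s.partition.assignment[v] == cid),
                    key=lambda e: -e[2])[:3]
                lines.append(f"- pattern {cid}: {top}")
                for u, v, r in intra:
                    lines.append(f"    - {u} -- {v}: rho = {r:.3f}")
            lines.append("")
        return "\n".join(lines)


def percentage_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Render a counts table (rows = categories, columns = populations) as
    "count (pct%)" strings, percentages of each column total at one
    decimal place.  A column's total is the sum over the rows of its first
    row-group; here simply the column sum of the age-band rows unless a
    ``__total__`` row is present."""
    if "__total__" in counts.index:
        totals = counts.loc["__total__"]
        body = counts.drop(index="__total__")
    else:
        totals = counts.sum(axis=0)
        body = counts
    out = pd.DataFrame(index=body.index, columns=body.columns, dtype=object)
    for col in body.columns:
        for idx in body.index:
            c = int(body.loc[idx, col])
            pct = 100.0 * c / totals[col] if totals[col] else 0.0
            out.loc[idx, col] = f"{c} ({pct:.1f}%)"
    return out


def summarize_demographics(matrices: dict[tuple[str, str], DiseaseMatrix],
                           covariates: pd.DataFrame | None = None
                           ) -> pd.DataFrame:
    """Counts and percentages by sex and age band (and optional categorical
    patient covariates), one column per sex plus a Total column; percentages
    are of the column total, one decimal place.

    ``covariates``: optional DataFrame indexed by patient id, one column per
    categorical covariate (e.g. residence area); each level becomes a row.
    """
    if not matrices:
        raise ValueError("no strata")
    counts = pd.DataFrame(0, index=list(AGE_BANDS), columns=["Total", "M", "F"])
    patient_sex: dict[str, str] = {}
    for (sex, band), mat in matrices.items():
        counts.loc[band, sex] += mat.n_patients
        counts.loc[band, "Total"] += mat.n_patients
        for pid in mat.patients:
            patient_sex[pid] = sex
    counts = counts.loc[counts.sum(axis=1) > 0]

    if covariates is not None:
        for col in covariates.columns:
            levels = covariates[col].astype(str)
            for level in sorted(levels.unique()):
                pids = levels.index[levels == level]
                row = f"{col}: {level}"
                counts.loc[row, "Total"] = len(pids)
                counts.loc[row, "M"] = sum(patient_sex.get(p) == "M" for p in pids)
                counts.loc[row, "F"] = sum(patient_sex.get(p) == "F" for p in pids)
    counts = counts.fillna(0).astype(int)
    band_rows = [r for r in counts.index if r in AGE_BANDS]
    totals = counts.loc[band_rows].sum(axis=0)
    # sex shares (of each column's total); matches the "% men" convention
    for sex in ("M", "F"):
        counts.loc[f"sex: {sex}", :] = [
            int(totals[sex]) if c in ("Total", sex) else 0
            for c in counts.columns]
    counts = counts.astype(int)
    with_total = counts.copy()
    with_total.loc["__total__"] = totals
    table = percentage_table(with_total)
    table.loc["N", :] = [str(int(totals[c])) for c in table.columns]
    return table.loc[["N", *[r for r in table.index if r != "N"]]]


def analyze_matrices(matrices: dict[tuple[str, str], DiseaseMatrix],
                     config: RunConfig) -> PatternReport:
    """Network + pattern extraction per stratum (the compute core of
    :func:`run`, reusable on in-memory matrices)."""
    report = PatternReport()
    for stratum in sorted(matrices):
        mat = matrices[stratum]
        filtered = network.prevalence_filter(mat, config.min_prevalence)
        net = network.build_network(filtered, alpha=config.alpha,
                                    edge_sign=config.edge_sign)
        if net.number_of_nodes() == 0:
            log.warning("stratum %s empty after prevalence filtering", stratum)
            part = community_mod.Partition(assignment={}, q=0.0)
        else:
            # restart seeds derived deterministically from the master seed
            # and the stratum label so stratum results are order-independent
            # (zlib.crc32, not hash(): the latter is salted per process)
            tag = zlib.crc32("|".join(stratum).encode("utf-8"))
            base = np.random.SeedSequence(
                [int(config.seed), tag]).generate_state(1)[0]
            seeds = [int((base + i) % (1 << 31)) for i in range(config.louvain_restarts)]
            part = community_mod.louvain_best_of(
                net, seeds=seeds, resolution=config.resolution)
        prev = dict(zip(filtered.diseases, map(float, filtered.prevalences)))
        report.strata.append(StratumResult(
            stratum=stratum, n_patients=mat.n_patients, net=net,
            partition=part, prevalences=prev))
    report.demographics = summarize_demographics(matrices)
    return report


def _load_matrices(config: RunConfig
                   ) -> dict[tuple[str, str], DiseaseMatrix]:
    if config.cohort_spec is not None:
        matrices, _ = synthetic.generate_cohort(config.cohort_spec)
        return matrices
    records, rejects = grouping.read_records(config.records_path,
                                             delimiter=config.delimiter)
    if len(rejects):
        log.warning("%d malformed record rows rejected", len(rejects))
    lookup = grouping.read_lookup(config.chronic_path, config.category_path,
                                  delimiter=config.delimiter,
                                  index_category_id=config.index_category_id)
    kept, unmapped = grouping.filter_chronic(records, lookup)
    if len(unmapped):
        log.warning("%d distinct codes unmapped in chronic table", len(unmapped))
    return grouping.build_matrix(kept, lookup)


def run(config: RunConfig) -> PatternReport:
    """Execute the full pipeline; writes artifacts when ``out_dir`` is set.

    Artifacts: per-stratum network files in each requested format,
    ``patterns.tsv`` (disease -> pattern id), ``demographics.csv``,
    ``report.md``, ``summary.csv``, and ``config.yaml`` (the resolved
    config snapshot, sufficient to reproduce the run).
    """
    matrices = _load_matrices(config)
    report = analyze_matrices(matrices, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")
        for s in report.strata:
            tag = f"{s.stratum[0]}_{s.stratum[1].replace('>', 'gt')}"
            for fmt in config.formats:
                network.export_network(s.net, out / f"net_{tag}.{fmt}", fmt)
        report.pattern_frame().to_csv(out / "patterns.tsv", sep="\t", index=False)
        report.summary_frame().to_csv(out / "summary.csv", index=False)
        report.demographics.to_csv(out / "demographics.csv")
        (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    return report
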