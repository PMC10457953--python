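"""End-to-end orchestration: CSV tables in, quality report out.

Stages run in the order of the underlying workflow — physical indices,
internal-standard quantification, OAV profiling, membership-function
composite evaluation, correlation and PCA — each behind its library
module; this module only wires them together, validates inputs and
assembles a reproducible report with a provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .aroma import (
    CANONICAL_AROMA_TYPES,
    DescriptorMap,
    OAVMatrix,
    aroma_type_profile,
    oav_matrix,
    select_characteristic,
    shared_compounds,
)
from .evaluate import (
    ConfidenceEllipse,
    CorrelationResult,
    IndicatorMatrix,
    MembershipResult,
    PCAResult,
    composite_scores,
    ellipse_95,
    group_percent_difference,
    pca,
    pearson_matrix,
)
from .physical import color_index, summary_table
from .synthetic import StudyDataset
from .volatiles import (
    CompoundRecord,
    class_totals,
    mean_concentrations,
    quantify_table,
    variety_summaries,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "analyze_study", "validate_inputs", "load_study"]

_TABLE_FILES = (
    "varieties",
    "physical",
    "color",
    "composition",
    "peaks",
    "batches",
    "sensory",
    "registry",
)


class PipelineConfig(BaseModel):
    """Paths and knobs for one pipeline run.

    ``input_dir`` must contain the eight study CSVs (as written by
    ``StudyDataset.to_csv_dir``); ``descriptor_map`` and ``directions``
    default to the packaged files when unset.
    """

    input_dir: Path
    output_dir: Path = Path("tomatoq_out")
    descriptor_map: Path | None = None
    directions: Path | None = None
    oav_cutoff: float = Field(default=1.0, ge=0)
    aggregation: str = Field(default="mean", pattern="^(mean|sum)$")
    match_score_cutoff: float = Field(default=80.0, ge=0, le=100)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def table_path(self, name: str) -> Path:
        return Path(self.input_dir) / f"{name}.csv"


@dataclass
class StudyReport:
    """Everything one run computes, plus provenance for reproducibility."""

    physical_summary: pd.DataFrame
    concentrations: pd.DataFrame  # variety × compound means, long format
    volatile_totals: pd.DataFrame
    class_totals: pd.DataFrame
    oav: OAVMatrix
    characteristic: list[str]
    shared: dict[str, list[str]]
    profiles: pd.DataFrame  # groups × 13 aroma types
    membership: MembershipResult
    group_differences: dict[str, dict[str, float]]
    correlation: CorrelationResult
    pca: PCAResult
    ellipses: dict[str, ConfidenceEllipse]
    groups: pd.Series
    provenance: dict[str, Any]

    def membership_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups.reindex(self.membership.composite.index),
                "membership": self.membership.composite,
                "rank": self.membership.rank,
            }
        )

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "characteristic_compounds": self.characteristic,
            "shared_compounds": self.shared,
            "aroma_profiles": {
                g: row.to_dict() for g, row in self.profiles.iterrows()
            },
            "membership": {
                v: {
                    "group": str(self.groups.get(v, "")),
                    "score": float(self.membership.composite[v]),
                    "rank": int(self.membership.rank[v]),
                }
                for v in self.membership.composite.index
            },
            "group_differences": self.group_differences,
            "volatile_totals": self.volatile_totals.to_dict("index"),
            "pca_explained_variance_fraction": [
                float(x) for x in self.pca.explained_variance_fraction
            ],
            "ellipses": {
                g: {
                    "center": list(e.center),
                    "semi_axes": list(e.semi_axes),
                    "angle_deg": e.angle_deg,
                }
                for g, e in self.ellipses.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, output_dir: str | Path) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.physical_summary.to_csv(out / "physical_summary.csv")
        self.concentrations.to_csv(out / "concentrations.csv", index=False)
        self.volatile_totals.to_csv(out / "volatile_totals.csv")
        self.class_totals.to_csv(out / "class_totals.csv")
        self.oav.values.to_csv(out / "oav_matrix.csv")
        self.profiles.stack().rename("oav").rename_axis(
            ["group", "aroma_type"]
        ).reset_index().to_csv(out / "aroma_profiles_long.csv", index=False)
        self.membership_table().to_csv(out / "membership.csv")
        self.correlation.r.to_csv(out / "correlation_r.csv")
        self.correlation.p.to_csv(out / "correlation_p.csv")
        self.correlation.stars.to_csv(out / "correlation_stars.csv")
        self.pca.scores.to_csv(out / "pca_scores.csv")
        self.pca.loadings.to_csv(out / "pca_loadings.csv")
        report_path = out / "report.json"
        report_path.write_text(self.to_json(), encoding="utf-8")
        return report_path


def _read_registry(df: pd.DataFrame) -> dict[str, CompoundRecord]:
    recs = {}
    for row in df.itertuples():
        thr = getattr(row, "odor_threshold_ug_per_kg", np.nan)
        recs[row.compound_name] = CompoundRecord(
            compound_name=row.compound_name,
            cas=str(getattr(row, "cas", "")),
            chemical_class=getattr(row, "chemical_class", "other"),
            odor_threshold=None if pd.isna(thr) else float(thr),
            aroma_descriptors=tuple(
                d for d in str(getattr(row, "descriptors", "")).split(";") if d
            ),
        )
    return recs


def load_study(config: PipelineConfig) -> StudyDataset:
    """Read the eight study CSVs into a :class:`StudyDataset`."""
    tables = {}
    for name in _TABLE_FILES:
        p = config.table_path(name)
        if not p.exists():
            raise FileNotFoundError(f"[load] missing input table: {p}")
        tables[name] = pd.read_csv(p)
    return StudyDataset(
        **tables, true_concentrations=pd.DataFrame(columns=["variety_id", "compound_name", "concentration"])
    )


def analyze_study(
    dataset: StudyDataset,
    *,
    descriptor_map: DescriptorMap | None = None,
    directions: Mapping[str, str] | None = None,
    oav_cutoff: float = 1.0,
    aggregation: str = "mean",
    match_score_cutoff: float = 80.0,
    provenance: dict[str, Any] | None = None,
) -> StudyReport:
    """Run the full analysis on an in-memory study."""
    dmap = descriptor_map or DescriptorMap.default()
    if directions is None:
        from .synthetic import load_fixture

        dirs_df = load_fixture("directions")
        directions = dict(zip(dirs_df["indicator"], dirs_df["direction"]))
    groups = dataset.varieties.set_index("variety_id")["group"]

    logger.info("[physical] summarising %d replicate rows", len(dataset.physical))
    phys = summary_table(dataset.physical, dataset.color)

    logger.info("[quantify] %d peak rows", len(dataset.peaks))
    quantified = quantify_table(
        dataset.peaks, dataset.batches, min_score=match_score_cutoff
    )
    conc = mean_concentrations(quantified)
    registry = _read_registry(dataset.registry)
    totals = variety_summaries(conc)
    ctotals = class_totals(conc, registry)

    logger.info("[oav] scoring %d compounds", conc["compound_name"].nunique())
    matrix = oav_matrix(conc, registry)
    char = select_characteristic(matrix, cutoff=oav_cutoff)
    shared = {
        g: shared_compounds(
            matrix, [v for v in matrix.varieties if groups.get(v) == g], cutoff=oav_cutoff
        )
        for g in groups.unique()
    }
    descriptors = {
        name: list(rec.aroma_descriptors) for name, rec in registry.items()
    }
    char_matrix = OAVMatrix(
        values=matrix.values.loc[char], thresholds=matrix.thresholds.loc[char]
    )
    profiles = pd.DataFrame(
        {
            g: aroma_type_profile(
                char_matrix,
                [v for v in matrix.varieties if groups.get(v) == g],
                descriptors,
                dmap,
                agg=aggregation,
            )
            for g in groups.unique()
        }
    ).T.reindex(columns=list(CANONICAL_AROMA_TYPES))

    logger.info("[evaluate] assembling indicator matrix")
    indicators = _indicator_matrix(dataset, phys, conc, char)
    imatrix = IndicatorMatrix(values=indicators, directions=dict(directions), groups=groups)
    mem = composite_scores(imatrix)

    diffs: dict[str, dict[str, float]] = {}
    glabels = groups.reindex(indicators.index)
    key_traits = [
        t
        for t in (
            "moisture",
            "firmness_with_peel",
            "firmness_without_peel",
            "soluble_solids",
            "flavor_score",
            "total_volatiles",
        )
        if t in indicators.columns or t == "total_volatiles"
    ]
    for trait in key_traits:
        series = (
            totals["total_ug_per_kg"].reindex(indicators.index)
            if trait == "total_volatiles"
            else indicators[trait]
        )
        diffs[trait] = {}
        for a in groups.unique():
            for b in groups.unique():
                if a != b:
                    diffs[trait][f"{a}_vs_{b}"] = group_percent_difference(
                        series, glabels, a, b
                    )

    corr = pearson_matrix(indicators)

    pca_input = indicators.loc[:, indicators.std(ddof=0) > 0]
    n_comp = min(2, len(pca_input) - 1, pca_input.shape[1])
    pca_res = pca(pca_input, n_components=n_comp)
    ellipses = {}
    if pca_res.scores.shape[1] >= 2:
        for g in groups.unique():
            pts = pca_res.scores.loc[glabels == g, ["PC1", "PC2"]]
            if len(pts) >= 3:
                ellipses[g] = ellipse_95(pts.to_numpy())

    return StudyReport(
        physical_summary=phys,
        concentrations=conc,
        volatile_totals=totals,
        class_totals=ctotals,
        oav=matrix,
        characteristic=char,
        shared=shared,
        profiles=profiles,
        membership=mem,
        group_differences=diffs,
        correlation=corr,
        pca=pca_res,
        ellipses=ellipses,
        groups=groups,
        provenance=provenance or {},
    )


def _indicator_matrix(
    dataset: StudyDataset,
    phys: pd.DataFrame,
    conc: pd.DataFrame,
    characteristic: list[str],
) -> pd.DataFrame:
    """Variety × indicator means: physical, colour, composition, sensory,
    and the characteristic volatiles' concentrations."""
    parts = [phys[[c for c in phys.columns if not c.endswith("_se")]]]
    comp_means = dataset.composition.drop(columns=["replicate"]).groupby(
        "variety_id", sort=False
    ).mean()
    parts.append(comp_means)
    sens = dataset.sensory.drop(columns=["replicate"]).groupby(
        "variety_id", sort=False
    ).mean()
    parts.append(sens)
    vol = (
        conc[conc["compound_name"].isin(characteristic)]
        .pivot_table(
            index="variety_id",
            columns="compound_name",
            values="concentration",
            fill_value=0.0,
            sort=False,
        )
    )
    parts.append(vol)
    out = pd.concat(parts, axis=1)
    return out.fillna(0.0)


def _hash_run(config: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(
        config.model_dump_json(exclude={"output_dir", "log_level"}).encode()
    )
    for name in _TABLE_FILES:
        p = config.table_path(name)
        if p.exists():
            h.update(name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Load, validate, analyse and write one study end to end.

    Deterministic given inputs and seed; raises a stage-labelled error on
    the first hard failure.
    """
    logging.basicConfig(level=config.log_level)
    violations = validate_inputs(config)
    if violations:
        raise ValueError("[validate] input violations:\n" + "\n".join(violations))
    dataset = load_study(config)
    dmap = (
        DescriptorMap.from_csv(config.descriptor_map)
        if config.descriptor_map
        else None
    )
    directions = None
    if config.directions:
        dirs_df = pd.read_csv(config.directions)
        directions = dict(zip(dirs_df["indicator"], dirs_df["direction"]))
    provenance = {
        "config_input_hash": _hash_run(config),
        "seed": config.seed,
        "versions": {
            "tomatoq": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    report = analyze_study(
        dataset,
        descriptor_map=dmap,
        directions=directions,
        oav_cutoff=config.oav_cutoff,
        aggregation=config.aggregation,
        match_score_cutoff=config.match_score_cutoff,
        provenance=provenance,
    )
    report.write(config.output_dir)
    return report


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema, range and referential-integrity checks; lists every violation."""
    violations: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name in _TABLE_FILES:
        p = config.table_path(name)
        if not p.exists():
            violations.append(f"[{name}] missing file {p}")
            continue
        tables[name] = pd.read_csv(p)

    required = {
        "varieties": {"variety_id", "group"},
        "physical": {
            "variety_id",
            "replicate",
            "firmness_with_peel",
            "firmness_without_peel",
            "long_diam",
            "trans_diam",
            "fresh_w",
            "dry_w",
        },
        "color": {"variety_id", "replicate", "L", "a", "b"},
        "peaks": {"variety_id", "replicate", "compound_name", "area"},
        "batches": {"variety_id", "replicate", "is_area", "sample_mass_g"},
        "sensory": {"variety_id", "replicate", "flavor_score", "appearance_score"},
        "registry": {"compound_name", "chemical_class"},
    }
    for name, cols in required.items():
        if name in tables:
            missing = cols - set(tables[name].columns)
            if missing:
                violations.append(f"[{name}] missing columns {sorted(missing)}")

    if "varieties" in tables:
        known = set(tables["varieties"]["variety_id"])
        for name in ("physical", "color", "composition", "peaks", "batches", "sensory"):
            if name in tables and "variety_id" in tables[name].columns:
                orphan = set(tables[name]["variety_id"]) - known
                if orphan:
                    violations.append(
                        f"[{name}] references unknown varieties {sorted(orphan)}"
                    )

    if "physical" in tables:
        ph = tables["physical"]
        for col in ("firmness_with_peel", "firmness_without_peel", "fresh_w", "dry_w"):
            if col in ph.columns and (ph[col] < 0).any():
                violations.append(f"[physical] negative values in {col}")
        if {"fresh_w", "dry_w"} <= set(ph.columns) and (ph["dry_w"] > ph["fresh_w"]).any():
            violations.append("[physical] dry_w exceeds fresh_w in some rows")

    if "peaks" in tables:
        pk = tables["peaks"]
        if "area" in pk.columns and (pk["area"] < 0).any():
            violations.append("[peaks] negative peak areas")
        if "match_score" in pk.columns and (
            (pk["match_score"] < 0) | (pk["match_score"] > 100)
        ).any():
            violations.append("[peaks] match_score outside [0, 100]")

    if "batches" in tables:
        bt = tables["batches"]
        for col in ("is_area", "sample_mass_g"):
            if col in bt.columns and (bt[col] <= 0).any():
                violations.append(f"[batches] non-positive {col}")

    if "registry" in tables:
        rg = tables["registry"]
        if "odor_threshold_ug_per_kg" in rg.columns:
            bad = rg["odor_threshold_ug_per_kg"].dropna() <= 0
            if bad.any():
                violations.append("[registry] non-positive odor thresholds")

    if "sensory" in tables:
        sn = tables["sensory"]
        for col in ("flavor_score", "appearance_score"):
            if col in sn.columns and ((sn[col] < 1) | (sn[col] > 5)).any():
                violations.append(f"[sensory] {col} outside the 1-5 scale")

    return violations
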