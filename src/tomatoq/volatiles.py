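"""Internal-standard quantification of GC-MS volatile peak tables.

A spiked internal standard (2-octanol by default) of known amount M1 (µg)
in a sample of mass M2 (g) converts peak-area ratios into concentrations:

    concentration [µg·kg⁻¹] = (A1 / A2) · (M1 / M2) · 1000

where A1 is the analyte peak area and A2 the internal-standard area.  The
×1000 factor converts per-gram to per-kilogram.  Identification quality is
controlled upstream by a spectral match-score filter (strictly above 80%
by default); this module only applies the score threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CHEMICAL_CLASSES",
    "DEFAULT_SAMPLE_MASS_G",
    "DEFAULT_IS_AMOUNT_UG",
    "VolatilePeak",
    "PeakBatch",
    "CompoundRecord",
    "QuantifiedCompound",
    "internal_standard_amount",
    "quantify",
    "quantify_batch",
    "filter_matches",
    "quantify_table",
    "mean_concentrations",
    "class_totals",
    "variety_summary",
    "variety_summaries",
]

CHEMICAL_CLASSES = frozenset(
    {"alcohol", "aldehyde", "ketone", "hydrocarbon", "ester", "other"}
)

#: SPME protocol constants: 8.0 g homogenate spiked with 10 µL of
#: 8.82 mg·L⁻¹ 2-octanol = 0.0882 µg internal standard.
DEFAULT_SAMPLE_MASS_G = 8.0
DEFAULT_IS_AMOUNT_UG = 0.0882


@dataclass(frozen=True)
class VolatilePeak:
    """One detected GC-MS peak: compound identity, area A1, spectral match score."""

    compound_name: str
    cas: str
    area: float
    match_score: float = 100.0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")
        if not 0 <= self.match_score <= 100:
            raise ValueError(f"match_score must be in [0, 100], got {self.match_score}")


@dataclass(frozen=True)
class PeakBatch:
    """One GC-MS run: internal-standard constants plus the detected peaks.

    ``internal_standard_amount`` is M1 in µg, ``sample_mass`` M2 in g,
    ``internal_standard_area`` A2 in detector counts.
    """

    internal_standard_area: float
    internal_standard_amount: float = DEFAULT_IS_AMOUNT_UG
    sample_mass: float = DEFAULT_SAMPLE_MASS_G
    peaks: tuple[VolatilePeak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.internal_standard_area <= 0:
            raise ValueError("internal_standard_area (A2) must be > 0")
        if self.internal_standard_amount <= 0:
            raise ValueError("internal_standard_amount (M1) must be > 0")
        if self.sample_mass <= 0:
            raise ValueError("sample_mass (M2) must be > 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))


@dataclass(frozen=True)
class CompoundRecord:
    """Registry entry for one volatile: identity, class, odor threshold, descriptors.

    ``odor_threshold`` is the human detection threshold in µg·kg⁻¹ (None when
    no literature value exists; such compounds are skipped in OAV scoring).
    """

    compound_name: str
    cas: str = ""
    chemical_class: str = "other"
    odor_threshold: float | None = None
    aroma_descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ValueError(
                f"chemical_class {self.chemical_class!r} not in {sorted(CHEMICAL_CLASSES)}"
            )
        if self.odor_threshold is not None and self.odor_threshold <= 0:
            raise ValueError("odor_threshold must be > 0 when present")
        object.__setattr__(self, "aroma_descriptors", tuple(self.aroma_descriptors))


@dataclass(frozen=True)
class QuantifiedCompound:
    variety_id: str
    compound_name: str
    concentration: float  # µg·kg⁻¹; 0 means not detected

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


def internal_standard_amount(volume_uL: float, concentration_mg_per_L: float) -> float:
    """M1 in µg from the spike volume (µL) and stock concentration (mg·L⁻¹)."""
    if volume_uL <= 0 or concentration_mg_per_L <= 0:
        raise ValueError("spike volume and concentration must be > 0")
    # mg/L == µg/mL; µL × µg/mL / 1000 = µg
    return volume_uL * concentration_mg_per_L / 1000.0


def quantify(area: float | VolatilePeak, batch: PeakBatch) -> float:
    """Concentration in µg·kg⁻¹ of one peak by the internal-standard method.

    Linear in the analyte area: (A1/A2)·(M1/M2)·1000.
    """
    a1 = area.area if isinstance(area, VolatilePeak) else float(area)
    if a1 < 0:
        raise ValueError("peak area must be >= 0")
    return (
        (a1 / batch.internal_standard_area)
        * (batch.internal_standard_amount / batch.sample_mass)
        * 1000.0
    )


def filter_matches(
    peaks: Sequence[VolatilePeak], min_score: float = 80.0
) -> list[VolatilePeak]:
    """Retain peaks whose spectral match score is strictly above ``min_score``.

    Order is preserved; the default mirrors the usual "above 80%"
    identification rule.
    """
    return [p for p in peaks if p.match_score > min_score]


def quantify_batch(
    batch: PeakBatch, variety_id: str, min_score: float = 80.0
) -> list[QuantifiedCompound]:
    """Filter and quantify every peak in a run.

    Duplicate compound rows (a co-eluting peak split by integration) are
    summed, with a warning.
    """
    kept = filter_matches(batch.peaks, min_score)
    areas: dict[str, float] = {}
    for peak in kept:
        if peak.compound_name in areas:
            logger.warning(
                "duplicate peak for %s in batch of %s: summing areas",
                peak.compound_name,
                variety_id,
            )
        areas[peak.compound_name] = areas.get(peak.compound_name, 0.0) + peak.area
    return [
        QuantifiedCompound(variety_id, name, quantify(a, batch))
        for name, a in areas.items()
    ]


# ---------------------------------------------------------------------------
# Table-level helpers (long-format DataFrames)


def quantify_table(
    peaks: pd.DataFrame, batches: pd.DataFrame, min_score: float = 80.0
) -> pd.DataFrame:
    """Quantify a long-format peak table against its per-run batch constants.

    ``peaks``: variety_id, replicate, compound_name, [cas], area, [match_score].
    ``batches``: variety_id, replicate, is_area, is_amount_ug, sample_mass_g
    (alternatively ``is_volume_uL`` + ``is_conc_mg_per_L`` instead of
    ``is_amount_ug``).  Returns variety_id, replicate, compound_name,
    concentration.
    """
    b = batches.copy()
    if "is_amount_ug" not in b.columns:
        if {"is_volume_uL", "is_conc_mg_per_L"} <= set(b.columns):
            b["is_amount_ug"] = [
                internal_standard_amount(v, c)
                for v, c in zip(b["is_volume_uL"], b["is_conc_mg_per_L"])
            ]
        else:
            raise ValueError(
                "batch table needs is_amount_ug or (is_volume_uL, is_conc_mg_per_L)"
            )
    key = ["variety_id", "replicate"]
    merged = peaks.merge(b[key + ["is_area", "is_amount_ug", "sample_mass_g"]], on=key, how="left")
    if merged["is_area"].isna().any():
        orphans = merged.loc[merged["is_area"].isna(), key].drop_duplicates()
        raise ValueError(f"peaks reference runs with no batch constants: {orphans.to_dict('records')}")
    if "match_score" in merged.columns:
        merged = merged[merged["match_score"] > min_score]
    dups = merged.duplicated(subset=key + ["compound_name"], keep=False)
    if dups.any():
        logger.warning(
            "summing %d duplicate peak rows (co-eluting splits)", int(dups.sum())
        )
    conc = (
        merged.assign(
            concentration=lambda d: (d["area"] / d["is_area"])
            * (d["is_amount_ug"] / d["sample_mass_g"])
            * 1000.0
        )
        .groupby(key + ["compound_name"], sort=False, as_index=False)["concentration"]
        .sum()
    )
    return conc


def mean_concentrations(quantified: pd.DataFrame) -> pd.DataFrame:
    """Average concentrations across replicate runs per variety × compound."""
    return quantified.groupby(
        ["variety_id", "compound_name"], sort=False, as_index=False
    )["concentration"].mean()


def _as_records(registry: Iterable[CompoundRecord] | Mapping[str, CompoundRecord]) -> dict[str, CompoundRecord]:
    if isinstance(registry, Mapping):
        return dict(registry)
    return {r.compound_name: r for r in registry}


def class_totals(
    quantified: pd.DataFrame | Sequence[QuantifiedCompound],
    registry: Iterable[CompoundRecord] | Mapping[str, CompoundRecord],
) -> pd.DataFrame:
    """Per-variety concentration sums by chemical class.

    Every quantified compound must appear in the registry; an unknown
    compound raises a KeyError naming it.  The class sums of a variety add
    up to its total volatile content.
    """
    if not isinstance(quantified, pd.DataFrame):
        quantified = pd.DataFrame([vars(q) for q in quantified])
    recs = _as_records(registry)
    unknown = set(quantified["compound_name"]) - set(recs)
    if unknown:
        raise KeyError(f"compounds missing from registry: {sorted(unknown)}")
    df = quantified.assign(
        chemical_class=quantified["compound_name"].map(
            lambda n: recs[n].chemical_class
        )
    )
    out = (
        df.groupby(["variety_id", "chemical_class"], sort=False)["concentration"]
        .sum()
        .unstack(fill_value=0.0)
    )
    return out.reindex(columns=sorted(out.columns))


def variety_summary(
    concentrations: Sequence[float] | Sequence[QuantifiedCompound],
) -> tuple[float, int]:
    """(total content µg·kg⁻¹, number of detected compounds) for one variety."""
    vals = np.asarray(
        [
            q.concentration if isinstance(q, QuantifiedCompound) else float(q)
            for q in concentrations
        ],
        dtype=float,
    )
    return float(vals.sum()), int((vals > 0).sum())


def variety_summaries(quantified: pd.DataFrame) -> pd.DataFrame:
    """Total content and detected-compound count for every variety."""
    grp = quantified.groupby("variety_id", sort=False)["concentration"]
    return pd.DataFrame(
        {
            "total_ug_per_kg": grp.sum(),
            "n_detected": grp.apply(lambda s: int((s > 0).sum())),
        }
    )
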