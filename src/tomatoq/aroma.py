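"""Odor-activity-value (OAV) aroma profiling.

OAV = concentration / odor threshold.  Compounds whose OAV strictly
exceeds 1 in at least one variety are the characteristic aroma compounds;
the intersection across a group's varieties gives the group's shared set.
Free-text descriptors ("citrus, floral, sweet") are normalised onto 13
canonical aroma types, and a compound's full OAV is credited to every type
it maps to (the multi-type duplication rule), yielding a 13-entry aroma
profile per group suitable for radar/contour plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volatiles import CompoundRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_AROMA_TYPES",
    "DescriptorMap",
    "OAVMatrix",
    "compute_oav",
    "oav_matrix",
    "select_characteristic",
    "shared_compounds",
    "parse_descriptor_field",
    "normalize_descriptors",
    "aroma_type_profile",
]

#: The 13 canonical aroma types, in display order.
CANONICAL_AROMA_TYPES: tuple[str, ...] = (
    "fruity",
    "sweet",
    "floral",
    "fresh",
    "mushroom-like",
    "earthy",
    "green",
    "waxy",
    "fatty",
    "herbal",
    "vegetable",
    "woody",
    "pungent",
)


class DescriptorMap:
    """Maps free-text aroma descriptors onto canonical aroma types.

    Built from (descriptor, canonical_type) pairs; a descriptor occurring
    in several pairs accumulates all its types (used e.g. for the fused
    token "fruity sweet").  Lookup is case-insensitive on stripped text.
    Unmapped descriptors raise, never guess.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        mapping: dict[str, set[str]] = {}
        for descriptor, canonical in pairs:
            canonical = canonical.strip().lower()
            if canonical not in CANONICAL_AROMA_TYPES:
                raise ValueError(
                    f"{canonical!r} is not one of the 13 canonical aroma types"
                )
            mapping.setdefault(descriptor.strip().lower(), set()).add(canonical)
        self._map = {k: frozenset(v) for k, v in mapping.items()}

    @classmethod
    def from_csv(cls, path) -> "DescriptorMap":
        df = pd.read_csv(path)
        return cls(zip(df["descriptor"], df["canonical_type"]))

    @classmethod
    def default(cls) -> "DescriptorMap":
        from .synthetic import load_fixture

        df = load_fixture("descriptor_map")
        return cls(zip(df["descriptor"], df["canonical_type"]))

    def __contains__(self, descriptor: str) -> bool:
        return descriptor.strip().lower() in self._map

    def __getitem__(self, descriptor: str) -> frozenset[str]:
        key = descriptor.strip().lower()
        if key not in self._map:
            raise KeyError(
                f"descriptor {key!r} has no canonical aroma type; "
                "add it to the descriptor map"
            )
        return self._map[key]


@dataclass
class OAVMatrix:
    """Compounds × varieties OAV table plus the per-compound thresholds.

    A zero entry means the compound was not detected in that variety.
    """

    values: pd.DataFrame  # index: compounds, columns: varieties
    thresholds: pd.Series  # index: compounds, µg·kg⁻¹

    def __post_init__(self) -> None:
        self.thresholds = self.thresholds.reindex(self.values.index)
        if (self.thresholds <= 0).any() or self.thresholds.isna().any():
            bad = self.thresholds.index[
                self.thresholds.isna() | (self.thresholds <= 0)
            ].tolist()
            raise ValueError(f"non-positive or missing thresholds for {bad}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("OAVs must be >= 0")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def varieties(self) -> list[str]:
        return list(self.values.columns)


def compute_oav(concentration: float, threshold: float) -> float:
    """OAV of one compound: concentration / odor threshold (both µg·kg⁻¹)."""
    if threshold <= 0:
        raise ValueError(f"odor threshold must be > 0, got {threshold}")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration / threshold


def oav_matrix(
    concentrations: pd.DataFrame,
    registry: Iterable[CompoundRecord] | Mapping[str, CompoundRecord],
) -> OAVMatrix:
    """Build the compounds × varieties OAV matrix from mean concentrations.

    ``concentrations`` is long-format (variety_id, compound_name,
    concentration).  Compounds with no odor threshold in the registry are
    skipped with a warning — no OAV can be assigned to them.
    """
    if isinstance(registry, Mapping):
        recs = dict(registry)
    else:
        recs = {r.compound_name: r for r in registry}
    wide = (
        concentrations.pivot_table(
            index="compound_name",
            columns="variety_id",
            values="concentration",
            fill_value=0.0,
            sort=False,
        )
    )
    thresholds = {}
    keep = []
    for name in wide.index:
        rec = recs.get(name)
        thr = rec.odor_threshold if rec is not None else None
        if thr is None:
            logger.warning("no odor threshold for %s: skipped in OAV scoring", name)
            continue
        thresholds[name] = thr
        keep.append(name)
    values = wide.loc[keep].div(pd.Series(thresholds), axis=0)
    values.index.name = "compound"
    values.columns.name = None
    return OAVMatrix(values=values, thresholds=pd.Series(thresholds, name="threshold"))


def select_characteristic(matrix: OAVMatrix, cutoff: float = 1.0) -> list[str]:
    """Compounds with OAV strictly above ``cutoff`` in at least one variety.

    These are the characteristic (aroma-active) compounds of the panel;
    row order of the matrix is preserved.
    """
    mask = (matrix.values > cutoff).any(axis=1)
    return list(matrix.values.index[mask])


def shared_compounds(
    matrix: OAVMatrix, varieties: Sequence[str], cutoff: float = 1.0
) -> list[str]:
    """Compounds characteristic (OAV > cutoff) in *every* listed variety.

    The set intersection over the subset; undetected (OAV 0) never
    qualifies.  Unknown varieties raise a KeyError.
    """
    if len(varieties) == 0:
        raise ValueError("varieties subset must be nonempty")
    unknown = [v for v in varieties if v not in matrix.values.columns]
    if unknown:
        raise KeyError(f"unknown varieties: {unknown}")
    mask = (matrix.values[list(varieties)] > cutoff).all(axis=1)
    return list(matrix.values.index[mask])


def parse_descriptor_field(text: str) -> list[str]:
    """Split a free-text descriptor field ("Citrus, floral, sweet") into tokens."""
    return [tok.strip().lower() for tok in str(text).split(",") if tok.strip()]


def normalize_descriptors(
    descriptors: Sequence[str], dmap: DescriptorMap
) -> set[str]:
    """De-duplicated set of canonical aroma types for a descriptor list."""
    out: set[str] = set()
    for d in descriptors:
        out |= dmap[d]
    return out


def aroma_type_profile(
    matrix: OAVMatrix,
    varieties: Sequence[str],
    descriptors: Mapping[str, Sequence[str]],
    dmap: DescriptorMap | None = None,
    agg: str = "mean",
    compounds: Sequence[str] | None = None,
) -> pd.Series:
    """Aggregate a group's OAVs into the 13 canonical aroma types.

    For each compound its group-level OAV (mean across the subset's
    varieties, or sum when ``agg='sum'``) is added in full to every
    canonical type the compound's descriptors map to.  ``descriptors``
    maps compound → raw descriptor strings; ``compounds`` restricts the
    profile to a subset (default: all rows of the matrix).

    Returns a Series indexed by the 13 canonical types, in order.
    """
    if len(varieties) == 0:
        raise ValueError("varieties subset must be nonempty")
    if agg not in ("mean", "sum"):
        raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")
    dmap = dmap or DescriptorMap.default()
    rows = list(compounds) if compounds is not None else matrix.compounds
    sub = matrix.values.loc[rows, list(varieties)]
    group_oav = sub.mean(axis=1) if agg == "mean" else sub.sum(axis=1)
    profile = pd.Series(0.0, index=list(CANONICAL_AROMA_TYPES), name="oav")
    for compound, value in group_oav.items():
        types = normalize_descriptors(descriptors[compound], dmap)
        for t in types:
            profile[t] += value
    profile.index.name = "aroma_type"
    return profile
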