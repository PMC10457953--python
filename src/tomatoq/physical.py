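"""Physical fruit-quality indices: moisture, shape index, CIELAB colour index.

All operations work on single fruits (one replicate measurement) and are
aggregated per variety with :func:`summarize`, reported as mean ± standard
error as is conventional for horticultural trait tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalReplicate",
    "ColorReading",
    "TraitSummary",
    "moisture_content",
    "shape_index",
    "color_index",
    "summarize",
    "physical_indices",
    "summary_table",
]


@dataclass(frozen=True)
class PhysicalReplicate:
    """One fruit's physical measurements.

    Firmness in kg·cm⁻², diameters in mm, weights in g.  ``fresh_weight``
    (W1) and ``dry_weight`` (W2) refer to the same tissue aliquot before
    and after oven drying, so W2 cannot exceed W1.
    """

    firmness_with_peel: float
    firmness_without_peel: float
    longitudinal_diameter: float
    transverse_diameter: float
    fresh_weight: float
    dry_weight: float

    def __post_init__(self) -> None:
        for name in (
            "firmness_with_peel",
            "firmness_without_peel",
            "longitudinal_diameter",
            "fresh_weight",
            "dry_weight",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.transverse_diameter <= 0:
            raise ValueError("transverse_diameter must be > 0")
        if self.dry_weight > self.fresh_weight:
            raise ValueError("dry_weight (W2) cannot exceed fresh_weight (W1)")

    @property
    def moisture(self) -> float:
        return moisture_content(self.fresh_weight, self.dry_weight)

    @property
    def shape(self) -> float:
        return shape_index(self.longitudinal_diameter, self.transverse_diameter)


@dataclass(frozen=True)
class ColorReading:
    """A CIELAB colorimeter reading (L* lightness, a* red–green, b* yellow–blue)."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if self.L_star <= 0:
            raise ValueError("L_star must be > 0")

    @property
    def index(self) -> float:
        return color_index(self.L_star, self.a_star, self.b_star)


@dataclass(frozen=True)
class TraitSummary:
    """Replicate summary of one trait: mean ± standard error of the mean."""

    mean: float
    standard_error: float
    n: int


def moisture_content(fresh_weight: float, dry_weight: float) -> float:
    """Percent water in the fruit: (W1 − W2) / W1 × 100.

    Parameters
    ----------
    fresh_weight
        W1, mass of the fresh aliquot in g; must be positive.
    dry_weight
        W2, mass after drying to constant weight in g; 0 ≤ W2 ≤ W1.
    """
    if fresh_weight <= 0:
        raise ValueError(f"fresh_weight (W1) must be > 0, got {fresh_weight}")
    if not 0 <= dry_weight <= fresh_weight:
        raise ValueError(
            f"dry_weight (W2) must satisfy 0 <= W2 <= W1, got W2={dry_weight}, W1={fresh_weight}"
        )
    return (fresh_weight - dry_weight) / fresh_weight * 100.0


def shape_index(
    longitudinal: float | Sequence[float], transverse: float | Sequence[float]
) -> float:
    """Fruit shape index: longitudinal / transverse diameter.

    ≈1 round, <1 oblate, >1 obround.  Repeated caliper readings of the
    same fruit (the perpendicular re-measurement) may be passed as
    sequences; they are averaged before the ratio is taken.
    """
    lon = float(np.mean(longitudinal))
    trans = float(np.mean(transverse))
    if lon <= 0 or trans <= 0:
        raise ValueError(f"diameters must be > 0, got ({lon}, {trans})")
    return lon / trans


def color_index(L_star: float, a_star: float, b_star: float) -> float:
    """Tomato surface colour index 2000·a* / (L*·√(a*² + b*²)).

    Positive (red fruit) iff a* > 0; larger values mean deeper red.  The
    chroma √(a*² + b*²) must be nonzero, and L* positive.
    """
    if L_star <= 0:
        raise ValueError(f"L_star must be > 0, got {L_star}")
    chroma = math.hypot(a_star, b_star)
    if chroma == 0:
        raise ValueError("a_star and b_star cannot both be 0")
    return 2000.0 * a_star / (L_star * chroma)


def summarize(values: Sequence[float]) -> TraitSummary:
    """Mean and standard error (sample sd / √n; 0 when n = 1) of replicate values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    se = 0.0 if arr.size == 1 else float(arr.std(ddof=1) / math.sqrt(arr.size))
    return TraitSummary(mean=float(arr.mean()), standard_error=se, n=int(arr.size))


# ---------------------------------------------------------------------------
# Table-level helpers

_REPLICATE_COLUMNS = [
    "firmness_with_peel",
    "firmness_without_peel",
    "long_diam",
    "trans_diam",
    "fresh_w",
    "dry_w",
]


def physical_indices(replicates: pd.DataFrame) -> pd.DataFrame:
    """Add derived per-replicate indices to a physical-replicates table.

    Expects columns ``variety_id, replicate`` + the six measurement columns;
    returns a copy with ``moisture`` and ``shape_index`` appended.
    """
    missing = [c for c in _REPLICATE_COLUMNS if c not in replicates.columns]
    if missing:
        raise ValueError(f"physical table missing columns: {missing}")
    out = replicates.copy()
    out["moisture"] = [
        moisture_content(w1, w2) for w1, w2 in zip(out["fresh_w"], out["dry_w"])
    ]
    out["shape_index"] = [
        shape_index(lo, tr) for lo, tr in zip(out["long_diam"], out["trans_diam"])
    ]
    return out


def summary_table(replicates: pd.DataFrame, color: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-variety mean ± SE of the physical traits (layout of a trait table).

    ``color``, if given, must have columns ``variety_id, L, a, b``; its
    colour index is summarised alongside the physical traits.
    """
    enriched = physical_indices(replicates)
    traits = ["firmness_with_peel", "firmness_without_peel", "shape_index", "moisture"]
    frames = {}
    for trait in traits:
        grp = enriched.groupby("variety_id", sort=False)[trait].agg(list)
        summ = grp.map(summarize)
        frames[trait] = summ.map(lambda s: s.mean)
        frames[f"{trait}_se"] = summ.map(lambda s: s.standard_error)
    if color is not None:
        idx = color.assign(
            color_index=[
                color_index(L, a, b) for L, a, b in zip(color["L"], color["a"], color["b"])
            ]
        )
        grp = idx.groupby("variety_id", sort=False)["color_index"].agg(list)
        summ = grp.map(summarize)
        frames["color_index"] = summ.map(lambda s: s.mean)
        frames["color_index_se"] = summ.map(lambda s: s.standard_error)
    return pd.DataFrame(frames)
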