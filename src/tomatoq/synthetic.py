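"""Synthetic tomato-study generator and packaged reference tables.

The generator emulates a three-group variety panel (regular, tasty and
cherry tomatoes, five varieties each, three replicates) with the trait
structure such panels show: tasty varieties highest in soluble solids,
sugars, vitamins and volatiles; regular varieties highest in moisture,
firmness and oxalic acid.  Group effects are multiplicative on trait
baselines, varieties scatter multiplicatively around their group mean,
and replicates add truncated multiplicative Gaussian noise (sd =
``noise_cv``).  GC-MS peak areas are constructed by inverting the
internal-standard formula, so quantification recovers the configured
concentrations exactly when ``noise_cv`` is zero.

Packaged fixtures (:func:`load_fixture`) carry the printed reference
tables of a published 15-variety panel: physical traits, the 34-compound
OAV matrix with odor thresholds, sensory scores, and membership-function
scores with ranks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .aroma import CANONICAL_AROMA_TYPES, OAVMatrix, parse_descriptor_field
from .volatiles import (
    DEFAULT_IS_AMOUNT_UG,
    DEFAULT_SAMPLE_MASS_G,
    CompoundRecord,
)

__all__ = [
    "SyntheticConfig",
    "StudyDataset",
    "generate_study",
    "load_fixture",
    "fixture_names",
    "table2_oav_matrix",
    "DEFAULT_GROUP_EFFECT",
    "TRAIT_BASELINES",
]

# ---------------------------------------------------------------------------
# Study conditions

#: trait → (family, baseline).  Baselines are typical commercial-maturity
#: values: firmness kg·cm⁻², moisture %, soluble solids °Brix-like %,
#: vitamin C mg·100g⁻¹, lycopene mg·kg⁻¹, sugars mg·g⁻¹ FW, acids mg·g⁻¹,
#: volatiles µg·kg⁻¹, sensory on the 1–5 scale.
TRAIT_BASELINES: dict[str, tuple[str, float]] = {
    "firmness_with_peel": ("firmness", 2.6),
    "firmness_without_peel": ("firmness", 1.1),
    "shape_index": ("shape", 0.85),
    "moisture": ("moisture", 93.5),
    "fresh_w": ("fruit_size", 30.0),
    "a_star": ("color", 25.0),
    "b_star": ("", 28.0),
    "L_star": ("", 40.0),
    "soluble_solids": ("soluble_solids", 5.0),
    "vitamin_c": ("vitamins", 17.5),
    "lycopene": ("lycopene", 45.0),
    "fructose": ("sugars", 28.0),
    "glucose": ("sugars", 22.0),
    "citric_acid": ("organic_acids", 3.0),
    "malic_acid": ("organic_acids", 0.8),
    "tartaric_acid": ("organic_acids", 0.25),
    "fumaric_acid": ("organic_acids", 0.02),
    "ketoglutaric_acid": ("organic_acids", 0.15),
    "oxalic_acid": ("oxalic", 0.30),
    "total_volatiles": ("volatiles", 2000.0),
    "flavor_score": ("sensory_flavor", 3.7),
    "appearance_score": ("sensory_appearance", 3.7),
}

#: Group multipliers per trait family.  Ratios reproduce the group-level
#: percent differences typical of such panels (e.g. tasty soluble solids
#: ~60% above regular, regular moisture ~3% above tasty, regular oxalic
#: acid ~55% above tasty).
DEFAULT_GROUP_EFFECT: dict[str, dict[str, float]] = {
    "regular": {
        "moisture": 1.019,
        "firmness": 1.35,
        "shape": 0.95,
        "fruit_size": 1.30,
        "soluble_solids": 0.85,
        "sugars": 0.875,
        "organic_acids": 0.94,
        "oxalic": 1.45,
        "vitamins": 0.89,
        "lycopene": 0.75,
        "volatiles": 0.855,
        "color": 0.93,
        "sensory_flavor": 0.95,
    },
    "tasty": {
        "moisture": 0.988,
        "firmness": 0.80,
        "shape": 1.00,
        "fruit_size": 1.10,
        "soluble_solids": 1.36,
        "sugars": 1.45,
        "organic_acids": 1.33,
        "oxalic": 0.935,
        "vitamins": 1.30,
        "lycopene": 1.35,
        "volatiles": 1.35,
        "color": 1.18,
        "sensory_flavor": 1.25,
    },
    "cherry": {
        "moisture": 1.000,
        "firmness": 1.00,
        "shape": 1.05,
        "fruit_size": 0.25,
        "soluble_solids": 1.13,
        "sugars": 0.96,
        "organic_acids": 1.06,
        "oxalic": 0.76,
        "vitamins": 1.15,
        "lycopene": 1.21,
        "volatiles": 1.172,
        "color": 1.09,
        "sensory_flavor": 1.065,
    },
}

#: chemical-class mix of a ~110-compound tomato volatile panel
_CLASS_MIX: tuple[tuple[str, int], ...] = (
    ("alcohol", 31),
    ("aldehyde", 33),
    ("ketone", 13),
    ("hydrocarbon", 16),
    ("ester", 6),
    ("other", 11),
)

_GROUP_PREFIX = {"regular": "P", "tasty": "T", "cherry": "Y"}


class SyntheticConfig(BaseModel):
    """Study design and noise model for :func:`generate_study`.

    ``group_effect`` maps group → trait family → positive multiplier;
    families absent from the map default to 1.  ``noise_cv`` is the
    replicate-level coefficient of variation, ``variety_cv`` the spread
    of variety means around their group mean.  ``detection_prob`` gives
    the per-compound probability that a variety of a group expresses a
    volatile at all (undetected compounds get zero peak area), so
    detected-compound counts vary by variety like in real panels.
    """

    n_groups: int = Field(default=3, ge=1)
    varieties_per_group: int = Field(default=5, ge=1)
    replicates: int = Field(default=3, ge=1)
    n_compounds: int = Field(default=110, ge=1)
    group_effect: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_EFFECT.items()}
    )
    noise_cv: float = Field(default=0.05, ge=0)
    variety_cv: float = Field(default=0.08, ge=0)
    detection_prob: dict[str, float] = Field(
        default_factory=lambda: {"regular": 0.50, "tasty": 0.63, "cherry": 0.54}
    )
    aldehyde_alcohol_share: float = Field(default=0.6, gt=0, lt=1)
    seed: int = 0

    @field_validator("group_effect")
    @classmethod
    def _positive_multipliers(cls, v):
        for group, fams in v.items():
            for fam, mult in fams.items():
                if mult <= 0:
                    raise ValueError(
                        f"group_effect[{group!r}][{fam!r}] must be > 0, got {mult}"
                    )
        return v

    @field_validator("detection_prob")
    @classmethod
    def _valid_probs(cls, v):
        for group, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(
                    f"detection_prob[{group!r}] must be in [0, 1], got {p}"
                )
        return v

    def group_names(self) -> list[str]:
        if self.n_groups == 3:
            return ["regular", "tasty", "cherry"]
        return [f"group_{i + 1}" for i in range(self.n_groups)]

    def multiplier(self, group: str, family: str) -> float:
        if not family:
            return 1.0
        return self.group_effect.get(group, {}).get(family, 1.0)


@dataclass
class StudyDataset:
    """All tables of one (synthetic) study, keyed by ``variety_id``.

    ``true_concentrations`` holds the variety-level volatile
    concentrations the peak areas were constructed from — the ground
    truth for quantification round-trips.
    """

    varieties: pd.DataFrame  # variety_id, group
    physical: pd.DataFrame  # variety_id, replicate, 6 measurement columns
    color: pd.DataFrame  # variety_id, replicate, L, a, b
    composition: pd.DataFrame  # variety_id, replicate, concentration columns
    peaks: pd.DataFrame  # variety_id, replicate, compound_name, cas, area, match_score
    batches: pd.DataFrame  # variety_id, replicate, is_area, is_amount_ug, sample_mass_g
    sensory: pd.DataFrame  # variety_id, replicate, flavor_score, appearance_score
    registry: pd.DataFrame  # compound_name, cas, class, odor_threshold_ug_per_kg, descriptors
    true_concentrations: pd.DataFrame  # variety_id, compound_name, concentration

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for f in dc_fields(self):
            yield f.name, getattr(self, f.name)

    def registry_records(self) -> list[CompoundRecord]:
        return [
            CompoundRecord(
                compound_name=row.compound_name,
                cas=row.cas,
                chemical_class=row.chemical_class,
                odor_threshold=row.odor_threshold_ug_per_kg,
                aroma_descriptors=tuple(
                    d for d in str(row.descriptors).split(";") if d
                ),
            )
            for row in self.registry.itertuples()
        ]

    def to_csv_dir(self, path: str | Path) -> dict[str, Path]:
        """Write every table as an UTF-8, comma-delimited, quoted CSV."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, df in self.tables():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name] = p
        return written

    def checksum(self) -> str:
        """SHA-256 over all serialized tables (order-stable)."""
        h = hashlib.sha256()
        for name, df in self.tables():
            h.update(name.encode())
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _truncated_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative Gaussian factors, mean 1, sd cv, truncated at 0."""
    if cv == 0:
        return np.ones(size)
    return np.clip(rng.normal(1.0, cv, size=size), 0.0, None)


def _class_counts(n_compounds: int) -> list[tuple[str, int]]:
    """Allocate n compounds to chemical classes by largest remainder."""
    total = sum(c for _, c in _CLASS_MIX)
    raw = [(name, n_compounds * c / total) for name, c in _CLASS_MIX]
    counts = {name: int(x) for name, x in raw}
    short = n_compounds - sum(counts.values())
    for name, x in sorted(raw, key=lambda t: t[1] - int(t[1]), reverse=True):
        if short <= 0:
            break
        counts[name] += 1
        short -= 1
    return [(name, counts[name]) for name, _ in _CLASS_MIX if counts[name] > 0]


def generate_study(config: SyntheticConfig) -> StudyDataset:
    """Draw a complete synthetic study under the configured conditions.

    Deterministic given the config (all randomness flows from
    ``config.seed``); identical configs yield byte-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    groups = config.group_names()

    # --- variety roster -------------------------------------------------
    variety_rows = []
    for g in groups:
        prefix = _GROUP_PREFIX.get(g, g + "_")
        for i in range(config.varieties_per_group):
            variety_rows.append({"variety_id": f"{prefix}{i + 1}", "group": g})
    varieties = pd.DataFrame(variety_rows)

    # --- compound registry ----------------------------------------------
    comp_rows = []
    idx = 1
    for cls, count in _class_counts(config.n_compounds):
        for _ in range(count):
            n_desc = rng.integers(1, 4)
            desc = rng.choice(CANONICAL_AROMA_TYPES, size=n_desc, replace=False)
            comp_rows.append(
                {
                    "compound_name": f"{cls}_{idx:03d}",
                    "cas": f"{idx:06d}-00-0",
                    "chemical_class": cls,
                    "odor_threshold_ug_per_kg": float(10 ** rng.uniform(-2, 2)),
                    "descriptors": ";".join(desc.tolist()),
                }
            )
            idx += 1
    registry = pd.DataFrame(comp_rows)
    n_comp = len(registry)
    is_ald_alc = registry["chemical_class"].isin(["aldehyde", "alcohol"]).to_numpy()

    # compound abundance weights with a fixed aldehyde+alcohol share
    w = rng.lognormal(0.0, 1.0, size=n_comp)
    share = config.aldehyde_alcohol_share
    if is_ald_alc.any() and (~is_ald_alc).any():
        w[is_ald_alc] *= share / w[is_ald_alc].sum()
        w[~is_ald_alc] *= (1.0 - share) / w[~is_ald_alc].sum()
    else:
        w /= w.sum()

    # --- per-variety trait means ----------------------------------------
    trait_names = list(TRAIT_BASELINES)
    means = {}
    for row in varieties.itertuples():
        vfac = _truncated_noise(rng, config.variety_cv, len(trait_names))
        means[row.variety_id] = {
            t: TRAIT_BASELINES[t][1]
            * config.multiplier(row.group, TRAIT_BASELINES[t][0])
            * vfac[k]
            for k, t in enumerate(trait_names)
        }

    # --- replicate tables -----------------------------------------------
    physical_rows, color_rows, comp_rows2, sensory_rows = [], [], [], []
    peak_rows, batch_rows, truth_rows = [], [], []
    composition_traits = [
        "soluble_solids",
        "vitamin_c",
        "lycopene",
        "fructose",
        "glucose",
        "citric_acid",
        "malic_acid",
        "tartaric_acid",
        "fumaric_acid",
        "ketoglutaric_acid",
        "oxalic_acid",
    ]
    is_area_base = 5.0e5

    for row in varieties.itertuples():
        vid, group = row.variety_id, row.group
        m = means[vid]

        # volatile ground truth: detection thinning, weights renormalised
        # over the detected compounds so the variety total matches its
        # configured (group-scaled) total
        p_det = config.detection_prob.get(group, 1.0)
        detected = rng.random(n_comp) < p_det
        if not detected.any():
            detected[int(rng.integers(n_comp))] = True
        w_det = w * detected
        conc = m["total_volatiles"] * w_det / w_det.sum()
        for name, c in zip(registry["compound_name"], conc):
            truth_rows.append(
                {"variety_id": vid, "compound_name": name, "concentration": float(c)}
            )

        for rep in range(1, config.replicates + 1):
            nz = lambda: float(_truncated_noise(rng, config.noise_cv, 1)[0])

            moisture = min(m["moisture"] * nz(), 99.9)
            fresh_w = m["fresh_w"] * nz()
            dry_w = fresh_w * (1.0 - moisture / 100.0)
            trans = 12.0 * (4.0 * fresh_w) ** (1.0 / 3.0) * nz()
            shape = m["shape_index"] * nz()
            physical_rows.append(
                {
                    "variety_id": vid,
                    "replicate": rep,
                    "firmness_with_peel": m["firmness_with_peel"] * nz(),
                    "firmness_without_peel": m["firmness_without_peel"] * nz(),
                    "long_diam": trans * shape,
                    "trans_diam": trans,
                    "fresh_w": fresh_w,
                    "dry_w": dry_w,
                }
            )
            color_rows.append(
                {
                    "variety_id": vid,
                    "replicate": rep,
                    "L": m["L_star"] * nz(),
                    "a": m["a_star"] * nz(),
                    "b": m["b_star"] * nz(),
                }
            )
            comp_rows2.append(
                {"variety_id": vid, "replicate": rep}
                | {t: m[t] * nz() for t in composition_traits}
            )
            sensory_rows.append(
                {
                    "variety_id": vid,
                    "replicate": rep,
                    "flavor_score": float(np.clip(m["flavor_score"] * nz(), 1.0, 5.0)),
                    "appearance_score": float(
                        np.clip(m["appearance_score"] * nz(), 1.0, 5.0)
                    ),
                }
            )

            # GC-MS run: invert the internal-standard formula per compound
            batch_rows.append(
                {
                    "variety_id": vid,
                    "replicate": rep,
                    "is_area": is_area_base,
                    "is_amount_ug": DEFAULT_IS_AMOUNT_UG,
                    "sample_mass_g": DEFAULT_SAMPLE_MASS_G,
                }
            )
            rep_noise = _truncated_noise(rng, config.noise_cv, n_comp)
            scores = rng.uniform(81.0, 99.9, size=n_comp)
            for j, (name, cas) in enumerate(
                zip(registry["compound_name"], registry["cas"])
            ):
                if conc[j] == 0.0:
                    continue
                c_rep = conc[j] * rep_noise[j]
                area = (
                    c_rep
                    * is_area_base
                    * DEFAULT_SAMPLE_MASS_G
                    / (DEFAULT_IS_AMOUNT_UG * 1000.0)
                )
                peak_rows.append(
                    {
                        "variety_id": vid,
                        "replicate": rep,
                        "compound_name": name,
                        "cas": cas,
                        "area": area,
                        "match_score": float(scores[j]),
                    }
                )
            # unidentified low-confidence peaks, removed by the match filter
            for j in range(2):
                peak_rows.append(
                    {
                        "variety_id": vid,
                        "replicate": rep,
                        "compound_name": f"artifact_{rep}_{j}",
                        "cas": "",
                        "area": float(rng.uniform(1e3, 1e4)),
                        "match_score": float(rng.uniform(40.0, 75.0)),
                    }
                )

    return StudyDataset(
        varieties=varieties,
        physical=pd.DataFrame(physical_rows),
        color=pd.DataFrame(color_rows),
        composition=pd.DataFrame(comp_rows2),
        peaks=pd.DataFrame(peak_rows),
        batches=pd.DataFrame(batch_rows),
        sensory=pd.DataFrame(sensory_rows),
        registry=registry,
        true_concentrations=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures

_FIXTURES = {
    "table1": "table1_physical.csv",
    "table2": "table2_oav.csv",
    "table3": "table3_sensory.csv",
    "table4": "table4_membership.csv",
    "descriptor_map": "descriptor_map.csv",
    "directions": "directions.csv",
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by short name (``table1`` … ``table4``).

    Values are verbatim from the printed tables; an OAV of 0.00 in
    ``table2`` means the compound was not detected in that variety.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    path = resources.files("tomatoq").joinpath("data", _FIXTURES[name])
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def table2_oav_matrix() -> tuple[OAVMatrix, dict[str, list[str]], pd.Series]:
    """The packaged 34-compound OAV matrix, descriptors and variety groups.

    Returns ``(matrix, descriptors, groups)`` where ``descriptors`` maps
    compound → raw descriptor tokens and ``groups`` maps variety → group
    label.
    """
    t2 = load_fixture("table2")
    variety_cols = [c for c in t2.columns if c[0] in "PTY" and c[1:].isdigit()]
    values = t2.set_index("compound")[variety_cols].astype(float)
    thresholds = t2.set_index("compound")["odor_threshold_ug_per_kg"].astype(float)
    matrix = OAVMatrix(values=values, thresholds=thresholds)
    descriptors = {
        row.compound: parse_descriptor_field(row.aroma_type) for row in t2.itertuples()
    }
    group_of = {"P": "regular", "T": "tasty", "Y": "cherry"}
    groups = pd.Series({v: group_of[v[0]] for v in variety_cols}, name="group")
    return matrix, descriptors, groups
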