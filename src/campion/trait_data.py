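"""Species trait table: loading, validation, coding, and summary statistics.

Each species carries six continuous traits recorded as (min, median, max)
ranges — stem length (cm), leaves per node, leaf length (mm), calyx height
(mm), calyx width (mm), petal limb length (mm) — three ordinal floral traits
(inflorescence class, floral tube extension from the calyx, reproductive
organ exsertion from the corolla), a three-state floral color (white / pink
/ red, binned deterministically from the raw flora description), and ploidy.
Analyses downstream consume the trait medians plus ordinal integer codes;
the encoding map used is carried with the table so outputs are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitRange",
    "SpeciesRecord",
    "TraitTable",
    "ColorSummary",
    "CONTINUOUS_TRAITS",
    "CATEGORICAL_TRAITS",
    "ANALYSIS_TRAITS",
    "COLOR_STATES",
    "DEFAULT_ENCODING",
    "COLOR_BINNING",
    "bin_floral_color",
    "load_trait_table",
    "write_trait_table",
    "encode_categorical",
    "coefficient_of_variation",
    "summarize_by_color",
]


class TraitValidationError(ValueError):
    """A trait record violates the schema or an invariant."""


class CodingError(ValueError):
    """A categorical value falls outside its declared vocabulary."""


#: Continuous traits with their units, in canonical column order.
CONTINUOUS_TRAITS: dict[str, str] = {
    "stem_length": "cm",
    "leaves_per_node": "count",
    "leaf_length": "mm",
    "calyx_height": "mm",
    "calyx_width": "mm",
    "petal_limb_length": "mm",
}

#: Ordinal traits and their ordered levels.
CATEGORICAL_TRAITS: dict[str, tuple[str, ...]] = {
    "inflorescence_class": ("one", "few", "many"),
    "tube_extension": ("below", "equal", "above"),
    "organ_exsertion": ("below", "equal", "above/equal", "above"),
}

PLOIDY_STATES = ("diploid", "diploid/polyploid", "polyploid")
COLOR_STATES = ("white", "pink", "red")

#: Columns of the encoded analysis matrix (color is the grouping variable and
#: is deliberately not part of the morphology matrix).
ANALYSIS_TRAITS = tuple(CONTINUOUS_TRAITS) + tuple(CATEGORICAL_TRAITS)

#: Monotone integer codes for the ordinal traits. The four-level exsertion
#: trait places "above/equal" midway between "equal" and "above".
DEFAULT_ENCODING: dict[str, dict[str, float]] = {
    "inflorescence_class": {"one": 1, "few": 2, "many": 3},
    "tube_extension": {"below": -1, "equal": 0, "above": 1},
    "organ_exsertion": {"below": -1, "equal": 0, "above/equal": 0.5, "above": 1},
}

#: Raw color description -> color bin. Polymorphic white/pink species are
#: coded pink (they can make petal anthocyanins); pale yellow is coded white
#: (no anthocyanins); orange shades follow their red/pink base.
COLOR_BINNING: dict[str, str] = {
    "white": "white",
    "pink": "pink",
    "red": "red",
    "white/pink": "pink",
    "pale yellow": "white",
    "orange-pink": "pink",
    "orange-red": "red",
}


def bin_floral_color(raw_description: str, overrides: dict[str, str] | None = None) -> str:
    """Deterministically bin a raw floral color description into white/pink/red."""
    key = raw_description.strip().lower()
    if overrides and key in overrides:
        value = overrides[key]
    elif key in COLOR_BINNING:
        value = COLOR_BINNING[key]
    else:
        raise CodingError(
            f"unrecognized floral color description {raw_description!r}; "
            f"known terms: {sorted(COLOR_BINNING)} (or supply an override)"
        )
    if value not in COLOR_STATES:
        raise CodingError(f"override maps {raw_description!r} to unknown bin {value!r}")
    return value


@dataclass(frozen=True)
class TraitRange:
    """A (min, median, max) phenotypic range in one trait's units."""

    min: float
    median: float
    max: float

    def __post_init__(self):
        vals = (self.min, self.median, self.max)
        if not all(math.isfinite(v) for v in vals):
            raise TraitValidationError(f"non-finite trait range {vals}")
        if not (self.min <= self.median <= self.max):
            raise TraitValidationError(
                f"trait range must satisfy min <= median <= max, got {vals}"
            )


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    traits: dict  # trait name -> TraitRange | None (missing)
    inflorescence_class: str
    tube_extension: str
    organ_exsertion: str
    color: str
    ploidy: str

    def __post_init__(self):
        for trait, levels in CATEGORICAL_TRAITS.items():
            val = getattr(self, trait)
            if val not in levels:
                raise TraitValidationError(
                    f"{self.species_id}: {trait}={val!r} not in {levels}")
        if self.color not in COLOR_STATES:
            raise TraitValidationError(f"{self.species_id}: color {self.color!r}")
        if self.ploidy not in PLOIDY_STATES:
            raise TraitValidationError(f"{self.species_id}: ploidy {self.ploidy!r}")

    def is_complete(self) -> bool:
        return all(self.traits.get(t) is not None for t in CONTINUOUS_TRAITS)


@dataclass
class TraitTable:
    """Ordered species records plus the ordinal encoding used downstream."""

    records: list
    encoding_map: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENCODING.items()})

    def __post_init__(self):
        ids = [r.species_id for r in self.records]
        dup = {s for s in ids if ids.count(s) > 1}
        if dup:
            raise TraitValidationError(f"duplicate species ids: {sorted(dup)}")

    def __len__(self):
        return len(self.records)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    @property
    def colors(self) -> pd.Series:
        return pd.Series({r.species_id: r.color for r in self.records}, name="color")

    @property
    def ploidy(self) -> pd.Series:
        return pd.Series({r.species_id: r.ploidy for r in self.records}, name="ploidy")

    def complete_subset(self) -> "TraitTable":
        """Species with every continuous trait present (multivariate stages)."""
        kept = [r for r in self.records if r.is_complete()]
        return TraitTable(records=kept, encoding_map=self.encoding_map)

    def medians(self) -> pd.DataFrame:
        """Species x continuous-trait matrix of range medians (NaN if missing)."""
        data = {
            r.species_id: {
                t: (r.traits.get(t).median if r.traits.get(t) is not None else np.nan)
                for t in CONTINUOUS_TRAITS
            }
            for r in self.records
        }
        return pd.DataFrame(data).T.loc[self.species_ids, list(CONTINUOUS_TRAITS)]

    def ranges(self, trait: str) -> pd.DataFrame:
        rows = {}
        for r in self.records:
            tr = r.traits.get(trait)
            rows[r.species_id] = (
                {"min": np.nan, "median": np.nan, "max": np.nan}
                if tr is None else {"min": tr.min, "median": tr.median, "max": tr.max}
            )
        return pd.DataFrame(rows).T.loc[self.species_ids]

    def encoded_matrix(self) -> pd.DataFrame:
        """Numeric species x trait matrix: continuous medians + ordinal codes."""
        return encode_categorical(self, self.encoding_map)


def encode_categorical(table: TraitTable, scheme: dict | None = None) -> pd.DataFrame:
    """Continuous medians joined with monotone integer codes for ordinals.

    The scheme must cover every categorical level present; it is stored on
    the table so the same coding can be serialized alongside any output.
    """
    scheme = scheme if scheme is not None else table.encoding_map
    out = table.medians()
    for trait in CATEGORICAL_TRAITS:
        mapping = scheme.get(trait)
        if mapping is None:
            raise CodingError(f"encoding scheme missing trait {trait!r}")
        col = []
        for r in table.records:
            val = getattr(r, trait)
            if val not in mapping:
                raise CodingError(
                    f"{r.species_id}: no code for {trait}={val!r} in scheme")
            col.append(float(mapping[val]))
        out[trait] = col
    return out


def coefficient_of_variation(values) -> float:
    """CV as a percentage: 100 * sample SD (n-1) / mean."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise TraitValidationError("CV needs at least 2 finite values")
    m = x.mean()
    if m == 0:
        raise TraitValidationError("CV undefined: mean is zero")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class ColorSummary:
    """Per-color-group summary tables (the Table 1 / Table 2 surface)."""

    continuous: pd.DataFrame   # trait, group, n, grand_mean, sd, grand_median, cv
    categorical: pd.DataFrame  # trait, group, level, proportion
    absent_groups: list


def summarize_by_color(table: TraitTable, groups=COLOR_STATES) -> ColorSummary:
    """Grand mean/SD/median/CV of species medians per color group and overall,
    plus per-group level proportions for the categorical traits and ploidy."""
    med = table.medians()
    colors = table.colors
    group_masks = {g: (colors == g).to_numpy() for g in groups}
    absent = [g for g, m in group_masks.items() if not m.any()]
    group_masks = {g: m for g, m in group_masks.items() if m.any()}
    group_masks["all"] = np.ones(len(table), dtype=bool)

    cont_rows = []
    for trait in CONTINUOUS_TRAITS:
        col = med[trait].to_numpy()
        for g, mask in group_masks.items():
            x = col[mask]
            x = x[np.isfinite(x)]
            if x.size == 0:
                continue
            sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
            mean = float(x.mean())
            cv = 0.0 if sd == 0 else float(100.0 * sd / mean)
            cont_rows.append({
                "trait": trait, "group": g, "n": int(x.size),
                "grand_mean": mean, "sd": sd,
                "grand_median": float(np.median(x)), "cv": cv,
            })

    cat_rows = []
    cat_specs = dict(CATEGORICAL_TRAITS)
    cat_specs["ploidy"] = PLOIDY_STATES
    for trait, levels in cat_specs.items():
        vals = np.asarray([getattr(r, trait) for r in table.records])
        for g, mask in group_masks.items():
            sub = vals[mask]
            n = len(sub)
            for level in levels:
                cat_rows.append({
                    "trait": trait, "group": g, "level": level,
                    "proportion": float(np.sum(sub == level)) / n,
                })

    return ColorSummary(
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
        absent_groups=absent,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_CATEG = list(CATEGORICAL_TRAITS) + ["color", "ploidy"]


def _default_schema() -> dict[str, str]:
    cols = {"species_id": "species_id"}
    for t in CONTINUOUS_TRAITS:
        for part in ("min", "median", "max"):
            cols[f"{t}_{part}"] = f"{t}_{part}"
    for c in _CSV_CATEG:
        cols[c] = c
    return cols


def load_trait_table(path, schema: dict[str, str] | None = None,
                     encoding_map: dict | None = None,
                     color_overrides: dict[str, str] | None = None) -> TraitTable:
    """Read and validate a trait CSV.

    ``schema`` maps canonical column names to the file's column names. The
    ``color`` column may hold either a binned value or a raw description
    (e.g. "white/pink"); raw descriptions are binned on load. Rows violating
    an invariant are reported with the species and trait named.
    """
    cols = _default_schema()
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise TraitValidationError(f"trait CSV missing columns: {missing}")

    records, errors = [], []
    for _, row in df.iterrows():
        sid = str(row[cols["species_id"]]).strip()
        traits = {}
        try:
            for t in CONTINUOUS_TRAITS:
                raw = [row[cols[f"{t}_{p}"]] for p in ("min", "median", "max")]
                if all(pd.isna(v) or str(v).strip() == "" for v in raw):
                    traits[t] = None
                    continue
                try:
                    lo, md, hi = (float(v) for v in raw)
                except (TypeError, ValueError) as exc:
                    raise TraitValidationError(
                        f"{sid}: unparseable {t} range {raw!r}") from exc
                try:
                    traits[t] = TraitRange(lo, md, hi)
                except TraitValidationError as exc:
                    raise TraitValidationError(f"{sid}: {t}: {exc}") from exc
            color = bin_floral_color(str(row[cols["color"]]), overrides=color_overrides)
            rec = SpeciesRecord(
                species_id=sid,
                traits=traits,
                inflorescence_class=str(row[cols["inflorescence_class"]]).strip(),
                tube_extension=str(row[cols["tube_extension"]]).strip(),
                organ_exsertion=str(row[cols["organ_exsertion"]]).strip(),
                color=color,
                ploidy=str(row[cols["ploidy"]]).strip(),
            )
        except (TraitValidationError, CodingError) as exc:
            errors.append(str(exc))
            continue
        records.append(rec)
    if errors:
        raise TraitValidationError(
            "trait table validation failed:\n  " + "\n  ".join(errors))
    table = TraitTable(records=records)
    if encoding_map is not None:
        table.encoding_map = encoding_map
    return table


def write_trait_table(table: TraitTable, path, encoding_path=None) -> None:
    """Serialize a table back to CSV (and optionally its encoding map as JSON);
    round-trips bit-for-bit through load_trait_table."""
    rows = []
    for r in table.records:
        row = {"species_id": r.species_id}
        for t in CONTINUOUS_TRAITS:
            tr = r.traits.get(t)
            for part in ("min", "median", "max"):
                row[f"{t}_{part}"] = "" if tr is None else repr(getattr(tr, part))
        for c in _CSV_CATEG:
            row[c] = getattr(r, c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if encoding_path is not None:
        with open(encoding_path, "w", encoding="utf-8") as fh:
            json.dump(table.encoding_map, fh, indent=2, sort_keys=True)
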