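"""Ingestion and preparation of dive-duration records.

The raw material is a table of dive observations — species, taxonomy, body
mass (g), temperature (°C, with a provenance flag), and median/maximum dive
duration (min) — typically with multiple individuals per species measured at
different temperatures.  Preparation applies, in order:

1. exclusions (leatherback turtles, which are functionally endothermic and
   lack body-temperature measurements, are removed);
2. temperature imputation for endotherms through a hierarchy of
   species-specific body temperature, genus mean, then class default
   (41.5 °C for birds, 37 °C for mammals); ectotherms must already carry a
   measured body temperature or an ambient temperature used as its proxy;
3. Q10 normalization of both duration columns to a reference temperature;
4. optional reduction to one point per species (or two, when body mass
   differs substantially between sexes or life stages), using within-unit
   medians.

Every step is a pure transformation returning a new dataset, and every step
appends a before/after entry to the dataset's provenance log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import normalize_species_name
from .scaling_model import ScalingParams, normalize_duration

__all__ = [
    "DiveDataset",
    "SchemaError",
    "RowError",
    "PipelineStateError",
    "REQUIRED_COLUMNS",
    "CLASS_TO_GROUP",
    "DEFAULT_CLASS_TEMPS",
    "EXCLUDED_SPECIES",
    "load_records",
    "apply_exclusions",
    "impute_temperature",
    "normalize_dataset",
    "reduce_per_species",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "species",
    "genus",
    "taxon_class",
    "mass_g",
    "temp_C",
    "temp_source",
    "median_dive_min",
    "max_dive_min",
    "life_stage_sex",
)

CLASS_TO_GROUP = {
    "bird": "endotherm",
    "mammal": "endotherm",
    "reptile": "ectotherm",
    "amphibian": "ectotherm",
}

#: Mean body temperatures (°C) used as the last imputation fallback.
DEFAULT_CLASS_TEMPS = {"bird": 41.5, "mammal": 37.0}

#: Species removed outright: functionally endothermic ectotherms whose body
#: temperature can exceed ambient by up to ~18 °C.
EXCLUDED_SPECIES = ("dermochelys_coriacea",)

TEMP_SOURCES = ("measured_body", "genus_mean", "class_default", "ambient_proxy")


class SchemaError(ValueError):
    """The input table is missing mandatory columns."""


class RowError(ValueError):
    """One or more rows violate record invariants; messages carry line numbers."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


class PipelineStateError(RuntimeError):
    """A preparation step was invoked out of order (e.g. double normalization)."""


@dataclass(frozen=True)
class DiveDataset:
    """An immutable collection of dive records plus a provenance log.

    ``frame`` holds one row per observation with the canonical column set
    (species and genus names normalized to underscore/casefold form, a derived
    ``group`` column of endotherm/ectotherm).  ``provenance`` accumulates one
    entry per applied step; ``normalized`` records whether durations have been
    Q10-adjusted to the reference temperature.
    """

    frame: pd.DataFrame
    provenance: tuple = ()
    normalized: bool = False

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> tuple:
        return tuple(pd.unique(self.frame["species"]))

    @property
    def n_species(self) -> int:
        return self.frame["species"].nunique()

    def _log(self, step: str, before: int, after: int, **details) -> tuple:
        return self.provenance + (
            {"step": step, "before": before, "after": after, **details},
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def provenance_json(self) -> str:
        return json.dumps(list(self.provenance), indent=2)


def _coerce_float(value, line: int, column: str, errors: list):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return np.nan
    try:
        return float(s)
    except ValueError:
        errors.append(f"line {line}: column {column!r}: unparseable numeric {s!r}")
        return np.nan


def load_records(source) -> DiveDataset:
    """Read a CSV of dive records and validate every row.

    ``source`` is a path or file-like object.  Mandatory columns are checked
    first (:class:`SchemaError`); then each row must have positive mass, at
    least one of median/maximum duration, maximum ≥ median when both are
    present, a recognized taxonomic class, and a recognized temperature source
    when one is given.  Violations raise :class:`RowError` listing the
    offending CSV line numbers (header = line 1).
    """
    if isinstance(source, (str,)) or hasattr(source, "read"):
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    else:
        raw = pd.read_csv(str(source), dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    if raw.empty:
        logger.warning("input CSV contains a header but no records")

    errors: list[str] = []
    rows = []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        species = normalize_species_name(row["species"])
        genus = normalize_species_name(row["genus"])
        taxon_class = str(row["taxon_class"]).strip().lower()
        if not species:
            errors.append(f"line {line}: empty species name")
        if taxon_class not in CLASS_TO_GROUP:
            errors.append(
                f"line {line}: unknown taxon_class {row['taxon_class']!r}"
            )
            continue
        mass = _coerce_float(row["mass_g"], line, "mass_g", errors)
        temp = _coerce_float(row["temp_C"], line, "temp_C", errors)
        med = _coerce_float(row["median_dive_min"], line, "median_dive_min", errors)
        mx = _coerce_float(row["max_dive_min"], line, "max_dive_min", errors)
        if not np.isnan(mass) and mass <= 0:
            errors.append(f"line {line}: mass_g must be positive, got {mass}")
        if np.isnan(mass):
            errors.append(f"line {line}: mass_g is required")
        if np.isnan(med) and np.isnan(mx):
            errors.append(
                f"line {line}: at least one of median/max dive duration required"
            )
        if not np.isnan(med) and med <= 0:
            errors.append(f"line {line}: median_dive_min must be positive")
        if not np.isnan(mx) and mx <= 0:
            errors.append(f"line {line}: max_dive_min must be positive")
        if not np.isnan(med) and not np.isnan(mx) and mx < med:
            errors.append(
                f"line {line}: max_dive_min {mx} < median_dive_min {med}"
            )
        source_flag = str(row["temp_source"]).strip().lower()
        if source_flag and source_flag not in TEMP_SOURCES:
            errors.append(
                f"line {line}: unknown temp_source {row['temp_source']!r}"
            )
        rows.append(
            {
                "species": species,
                "genus": genus,
                "taxon_class": taxon_class,
                "group": CLASS_TO_GROUP[taxon_class],
                "mass_g": mass,
                "temp_C": temp,
                "temp_source": source_flag or pd.NA,
                "median_dive_min": med,
                "max_dive_min": mx,
                "life_stage_sex": str(row["life_stage_sex"]).strip() or pd.NA,
            }
        )
    if errors:
        raise RowError(errors)

    frame = pd.DataFrame(
        rows,
        columns=[
            "species", "genus", "taxon_class", "group", "mass_g", "temp_C",
            "temp_source", "median_dive_min", "max_dive_min", "life_stage_sex",
        ],
    )
    ds = DiveDataset(frame=frame)
    return replace(ds, provenance=ds._log("load_records", len(raw), len(frame)))


def apply_exclusions(ds: DiveDataset) -> DiveDataset:
    """Remove species excluded a priori (leatherback turtles)."""
    mask = ds.frame["species"].isin(EXCLUDED_SPECIES)
    n = int(mask.sum())
    frame = ds.frame.loc[~mask].reset_index(drop=True)
    logger.info("excluded %d records of %s", n, ", ".join(EXCLUDED_SPECIES))
    return replace(
        ds,
        frame=frame,
        provenance=ds._log(
            "apply_exclusions", ds.n_records, len(frame),
            excluded_records=n, species=list(EXCLUDED_SPECIES),
        ),
    )


def impute_temperature(
    ds: DiveDataset,
    genus_means=None,
    class_defaults=None,
) -> DiveDataset:
    """Fill missing endotherm temperatures through the imputation hierarchy.

    Endotherm records keep a measured body temperature when present; otherwise
    the genus mean body temperature is used, and failing that the class
    default (birds 41.5 °C, mammals 37 °C).  ``temp_source`` records which
    level fired.  Ectotherms receive no fallback: a record without a measured
    body or ambient-proxy temperature is an error.

    ``genus_means`` may be a mapping ``genus -> °C`` or a DataFrame with
    columns ``genus`` and ``mean_body_temp_C``.
    """
    if class_defaults is None:
        class_defaults = DEFAULT_CLASS_TEMPS
    if genus_means is None:
        genus_table: dict[str, float] = {}
    elif isinstance(genus_means, pd.DataFrame):
        genus_table = {
            normalize_species_name(g): float(t)
            for g, t in zip(genus_means["genus"], genus_means["mean_body_temp_C"])
        }
    else:
        genus_table = {
            normalize_species_name(g): float(t) for g, t in dict(genus_means).items()
        }

    frame = ds.frame.copy()
    counts = {"measured_body": 0, "genus_mean": 0, "class_default": 0,
              "ambient_proxy": 0}
    problems = []
    for i, row in frame.iterrows():
        has_temp = not pd.isna(row["temp_C"])
        if row["group"] == "ectotherm":
            if not has_temp:
                problems.append(
                    f"ectotherm {row['species']} has no body or ambient "
                    "temperature and no fallback exists"
                )
                continue
            src = row["temp_source"]
            if pd.isna(src):
                src = "ambient_proxy"
                frame.at[i, "temp_source"] = src
            counts[src] += 1
            continue
        # endotherm hierarchy
        if has_temp:
            frame.at[i, "temp_source"] = "measured_body"
            counts["measured_body"] += 1
        elif row["genus"] in genus_table:
            frame.at[i, "temp_C"] = genus_table[row["genus"]]
            frame.at[i, "temp_source"] = "genus_mean"
            counts["genus_mean"] += 1
        elif row["taxon_class"] in class_defaults:
            frame.at[i, "temp_C"] = float(class_defaults[row["taxon_class"]])
            frame.at[i, "temp_source"] = "class_default"
            counts["class_default"] += 1
        else:
            problems.append(
                f"endotherm {row['species']}: no temperature and no default "
                f"for class {row['taxon_class']!r}"
            )
    if problems:
        raise RowError(problems)
    return replace(
        ds,
        frame=frame,
        provenance=ds._log(
            "impute_temperature", ds.n_records, len(frame), sources=counts
        ),
    )


def normalize_dataset(
    ds: DiveDataset, params: ScalingParams = ScalingParams()
) -> DiveDataset:
    """Q10-normalize both duration columns to ``params.T_ref``.

    Original values are retained in ``*_raw`` shadow columns and the dataset's
    ``normalized`` flag is set; applying the step twice is an error.
    """
    if ds.normalized:
        raise PipelineStateError("dataset durations are already normalized")
    missing = ds.frame.loc[ds.frame["temp_C"].isna(), "species"]
    if len(missing):
        raise RowError(
            [f"missing temperature for species {s}" for s in sorted(set(missing))]
        )
    frame = ds.frame.copy()
    factor = params.Q10 ** ((frame["temp_C"].astype(float) - params.T_ref) / 10.0)
    for col in ("median_dive_min", "max_dive_min"):
        frame[col + "_raw"] = frame[col]
        frame[col] = frame[col] * factor
    return replace(
        ds,
        frame=frame,
        normalized=True,
        provenance=ds._log(
            "normalize_dataset", ds.n_records, len(frame),
            Q10=params.Q10, T_ref=params.T_ref,
        ),
    )


def _aggregate(unit: pd.DataFrame, stat: str) -> dict:
    agg = np.nanmedian if stat == "median" else np.nanmean
    first = unit.iloc[0]
    out = {
        "species": first["species"],
        "genus": first["genus"],
        "taxon_class": first["taxon_class"],
        "group": first["group"],
        "mass_g": float(agg(unit["mass_g"].to_numpy(float))),
        "temp_C": float(agg(unit["temp_C"].to_numpy(float))),
        "temp_source": first["temp_source"],
        "life_stage_sex": first["life_stage_sex"],
    }
    for col in unit.columns:
        if col.startswith(("median_dive_min", "max_dive_min")):
            vals = unit[col].to_numpy(float)
            out[col] = float(agg(vals)) if not np.all(np.isnan(vals)) else np.nan
    return out


def reduce_per_species(
    ds: DiveDataset, mass_split_ratio: float = 1.5, stat: str = "median"
) -> DiveDataset:
    """Collapse records to one point per species, splitting on body-mass classes.

    Requires temperature-normalized durations (records of one species occur at
    different temperatures, so aggregation before normalization would mix
    scales).  Within a species, records are grouped by the ``life_stage_sex``
    tag; when the heaviest and lightest group mean masses differ by at least
    ``mass_split_ratio``-fold, the species contributes two points (a light and
    a heavy mass class), otherwise one.  Each retained unit is summarized by
    the ``stat`` ("median" by default, "mean" optional) of its masses and
    durations.
    """
    if not ds.normalized:
        raise PipelineStateError(
            "reduce_per_species requires temperature-normalized durations"
        )
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")

    rows = []
    n_split = 0
    for _, sp_frame in ds.frame.groupby("species", sort=False):
        tags = sp_frame["life_stage_sex"].fillna("")
        group_mass = sp_frame.groupby(tags)["mass_g"].mean()
        split = (
            len(group_mass) > 1
            and group_mass.max() / group_mass.min() >= mass_split_ratio
        )
        if split:
            n_split += 1
            # partition tags into light/heavy classes around the geometric
            # midpoint of the extreme group means
            cut = float(np.sqrt(group_mass.max() * group_mass.min()))
            heavy_tags = set(group_mass.index[group_mass.to_numpy() > cut])
            is_heavy = tags.isin(heavy_tags)
            for _, unit in sp_frame.groupby(is_heavy):
                rows.append(_aggregate(unit, stat))
        else:
            rows.append(_aggregate(sp_frame, stat))
    frame = pd.DataFrame(rows).reset_index(drop=True)
    if n_split:
        logger.info(
            "mass-class split (ratio >= %.2f) fired for %d species",
            mass_split_ratio, n_split,
        )
    return replace(
        ds,
        frame=frame,
        provenance=ds._log(
            "reduce_per_species", ds.n_records, len(frame),
            species_split=n_split, mass_split_ratio=mass_split_ratio, stat=stat,
        ),
    )
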