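"""Mortality tables, standard populations, age-group schemes and the unspecified-cause map.

The package's universal currency is the :class:`MortalityTable`: a long-format
table of death counts and population denominators indexed by
(year, age stratum, intent, cause).  Counts are canonical — rates are always
derived — because redistribution and direct standardization are exact on
counts.  All label matching is case-insensitive after trimming, so toy tables
in tests and real exports with inconsistent capitalization join
deterministically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .exceptions import (
    CoverageError,
    IntegrityError,
    SchemaError,
    ValidationError,
)

#: Manner-of-death strata used throughout (ICD-10 external-cause intents).
INTENTS = ("unintentional", "homicide", "suicide", "legal", "undetermined")

#: The four analysis age groups.
DEFAULT_AGE_GROUPS = ("0-24", "25-44", "45-64", "65+")

#: Canonical column names of the mortality CSV dialect.
COLUMNS = ("year", "age_group", "intent", "cause", "deaths", "population")

KEY_COLUMNS = ("year", "age_group", "intent", "cause")


def _norm(label: object) -> str:
    return str(label).strip()


def _key(label: object) -> str:
    """Canonical join key for a free-text label."""
    return _norm(label).casefold()


# ---------------------------------------------------------------------------
# MortalityTable


@dataclass(frozen=True)
class MortalityTable:
    """Long-format death counts and populations.

    Parameters
    ----------
    df : DataFrame
        Columns ``year, age_group, intent, cause, deaths, population``.
        ``deaths`` may be fractional (redistributed tables are real-valued).
    age_strata : tuple of str
        Ordered stratum labels; every record's ``age_group`` must be one of
        them.  Population is a shared denominator: it must be constant across
        all rows of a (year, age_group) cell.
    provenance : str
        Free-text note on where the table came from.
    """

    df: pd.DataFrame
    age_strata: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        _validate_frame(self.df, self.age_strata)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        age_strata: Iterable[str] | None = None,
        provenance: str = "",
    ) -> "MortalityTable":
        """Build a validated table from any frame with the canonical columns."""
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        out = df.loc[:, list(COLUMNS)].copy()
        try:
            out["year"] = out["year"].astype(int)
            out["deaths"] = pd.to_numeric(out["deaths"])
            out["population"] = pd.to_numeric(out["population"])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric year/deaths/population: {exc}") from exc
        for col in ("age_group", "intent", "cause"):
            out[col] = out[col].map(_norm)
        if age_strata is None:
            age_strata = tuple(dict.fromkeys(out["age_group"]))
        out = out.reset_index(drop=True)
        return cls(out, tuple(_norm(s) for s in age_strata), provenance)

    # -- accessors ----------------------------------------------------------

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.df["year"].unique()))

    @property
    def intents(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["intent"]))

    def populations(self) -> pd.DataFrame:
        """One row per (year, age_group) with the shared population."""
        return (
            self.df.drop_duplicates(["year", "age_group"])
            .loc[:, ["year", "age_group", "population"]]
            .reset_index(drop=True)
        )

    def filter(
        self,
        intent: str | None = None,
        age_groups: Iterable[str] | None = None,
        year: int | None = None,
    ) -> pd.DataFrame:
        """Rows matching the given labels (case-insensitive)."""
        df = self.df
        mask = pd.Series(True, index=df.index)
        if intent is not None:
            mask &= df["intent"].map(_key) == _key(intent)
        if age_groups is not None:
            keys = {_key(g) for g in age_groups}
            mask &= df["age_group"].map(_key).isin(keys)
        if year is not None:
            mask &= df["year"] == year
        return df.loc[mask]

    def total_deaths(self) -> float:
        return float(self.df["deaths"].sum())

    def equals(self, other: "MortalityTable") -> bool:
        """Value equality up to row order."""
        a = self.df.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.df.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b) and self.age_strata == other.age_strata


def _validate_frame(df: pd.DataFrame, age_strata: tuple[str, ...]) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if (df["deaths"] < 0).any():
        bad = df.loc[df["deaths"] < 0].iloc[0]
        raise ValidationError(
            f"negative deaths at (year={bad['year']}, age_group={bad['age_group']}, "
            f"intent={bad['intent']}, cause={bad['cause']})"
        )
    if (df["population"] <= 0).any():
        bad = df.loc[df["population"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive population at (year={bad['year']}, age_group={bad['age_group']})"
        )
    keys = df[list(KEY_COLUMNS)].copy()
    for col in ("age_group", "intent", "cause"):
        keys[col] = keys[col].map(_key)
    dup = keys.duplicated()
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise IntegrityError(
            f"duplicate record key (year={bad['year']}, age_group={bad['age_group']}, "
            f"intent={bad['intent']}, cause={bad['cause']})"
        )
    npop = df.groupby(["year", "age_group"])["population"].nunique()
    if (npop > 1).any():
        year, stratum = npop[npop > 1].index[0]
        raise IntegrityError(
            f"inconsistent population within (year={year}, age_group={stratum})"
        )
    allowed = {_key(s) for s in age_strata}
    unknown = set(df["age_group"].map(_key)) - allowed
    if unknown:
        raise ValidationError(f"age_group label(s) not in age_strata: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# CSV I/O


def read_mortality_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    age_strata: Iterable[str] | None = None,
) -> MortalityTable:
    """Read a mortality CSV.

    ``schema`` maps canonical names to the file's column headers, e.g.
    ``{"deaths": "Deaths", "population": "Population"}``; unmapped columns use
    the canonical names.  Validation (non-negative counts, positive
    populations, unique keys, shared denominators) happens on load.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path)
    rename = {}
    for canonical in COLUMNS:
        actual = schema.get(canonical, canonical)
        if actual not in raw.columns:
            raise SchemaError(f"column '{actual}' (for '{canonical}') not found in {path}")
        rename[actual] = canonical
    return MortalityTable.from_dataframe(
        raw.rename(columns=rename), age_strata=age_strata, provenance=str(path)
    )


def write_mortality_csv(table: MortalityTable, path: str | Path) -> None:
    """Write the mortality CSV dialect; ``read_mortality_csv`` round-trips it."""
    table.df.loc[:, list(COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Unspecified-cause code map


#: ICD-10 residual ("unspecified") external-cause codes per intent.
DEFAULT_ICD_ANNOTATION = {
    "unintentional": "X59",
    "homicide": "Y09,*U01.9",
    "legal": "Y35.7",
    "suicide": "X84,*U03.9",
    "undetermined": "Y34,Y89.9",
}


@dataclass(frozen=True)
class UnspecifiedCodeMap:
    """Which cause labels count as "unspecified" within each intent.

    The membership is data-driven rather than hard-coded so tests can build
    minimal toy intents; the ICD-10 annotation is documentation only.
    """

    mapping: Mapping[str, frozenset[str]]
    icd_annotation: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ICD_ANNOTATION))

    @classmethod
    def default(cls) -> "UnspecifiedCodeMap":
        """Every intent's unspecified bucket is the single label "unspecified"."""
        return cls({intent: frozenset({"unspecified"}) for intent in INTENTS})

    @classmethod
    def from_dict(cls, data: Mapping[str, Iterable[str]]) -> "UnspecifiedCodeMap":
        return cls({_key(k): frozenset(_key(c) for c in v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "UnspecifiedCodeMap":
        """Load a YAML/JSON mapping intent -> list of unspecified cause labels."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"code map {path} must be a mapping intent -> [causes]")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        data = {k: sorted(v) for k, v in self.mapping.items()}
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")

    def causes_for(self, intent: str) -> frozenset[str]:
        return frozenset(_key(c) for c in self.mapping.get(_key(intent), frozenset()))

    def is_unspecified(self, intent: str, cause: str) -> bool:
        return _key(cause) in self.causes_for(intent)

    def unspecified_mask(self, df: pd.DataFrame) -> pd.Series:
        """Boolean mask over a mortality frame's rows."""
        causes = {k: self.causes_for(k) for k in set(df["intent"].map(_key))}
        return pd.Series(
            [c in causes[i] for i, c in zip(df["intent"].map(_key), df["cause"].map(_key))],
            index=df.index,
        )


# ---------------------------------------------------------------------------
# Standard population


#: U.S. 2000 standard population collapsed to the four analysis age groups.
US2000_FOUR_GROUP_WEIGHTS = {
    "0-24": 0.353346,
    "25-44": 0.298186,
    "45-64": 0.222081,
    "65+": 0.126387,
}


@dataclass(frozen=True)
class StandardPopulation:
    """Age-stratum weights for direct standardization (normalized to sum 1)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = {_norm(k): float(v) for k, v in self.weights.items()}
        if any(v < 0 for v in w.values()):
            raise ValidationError("standard-population weights must be non-negative")
        total = sum(w.values())
        if total <= 0:
            raise ValidationError("standard-population weights sum to zero")
        object.__setattr__(self, "weights", {k: v / total for k, v in w.items()})

    @classmethod
    def us2000_four_groups(cls) -> "StandardPopulation":
        return cls(dict(US2000_FOUR_GROUP_WEIGHTS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardPopulation":
        """Read an ``age_group, weight`` CSV (weights normalized on load)."""
        df = pd.read_csv(path)
        for col in ("age_group", "weight"):
            if col not in df.columns:
                raise SchemaError(f"standard-population CSV missing column '{col}'")
        return cls(dict(zip(df["age_group"].map(_norm), df["weight"].astype(float))))

    def weight_for(self, stratum: str) -> float:
        for k, v in self.weights.items():
            if _key(k) == _key(stratum):
                return v
        return 0.0

    def restricted(self, strata: Iterable[str]) -> "StandardPopulation":
        """Weights renormalized within a subset of strata (for per-group rates)."""
        sub = {s: self.weight_for(s) for s in strata}
        if sum(sub.values()) <= 0:
            # group carries no standard weight: fall back to equal weights so a
            # within-group rate is still defined
            sub = {s: 1.0 for s in sub}
        return StandardPopulation(sub)


# ---------------------------------------------------------------------------
# Age-group scheme


@dataclass(frozen=True)
class AgeGroupScheme:
    """Partition of age strata into analysis groups."""

    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        groups = {_norm(g): frozenset(_norm(s) for s in strata) for g, strata in self.groups.items()}
        seen: dict[str, str] = {}
        for g, strata in groups.items():
            for s in strata:
                if _key(s) in seen:
                    raise ValidationError(
                        f"stratum '{s}' assigned to both '{seen[_key(s)]}' and '{g}'"
                    )
                seen[_key(s)] = g
        object.__setattr__(self, "groups", groups)

    @classmethod
    def identity(cls, strata: Iterable[str]) -> "AgeGroupScheme":
        return cls({s: frozenset({s}) for s in strata})

    @classmethod
    def four_groups(cls) -> "AgeGroupScheme":
        """The default analysis grouping (strata already equal to the groups)."""
        return cls.identity(DEFAULT_AGE_GROUPS)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, stratum: str) -> str | None:
        for g, strata in self.groups.items():
            if _key(stratum) in {_key(s) for s in strata}:
                return g
        return None

    def strata_of(self, group: str) -> frozenset[str]:
        for g, strata in self.groups.items():
            if _key(g) == _key(group):
                return strata
        raise CoverageError(f"unknown age group '{group}'")


def aggregate_to_groups(table: MortalityTable, scheme: AgeGroupScheme) -> MortalityTable:
    """Collapse age strata into the scheme's groups, summing deaths and populations.

    Total deaths and total population are conserved exactly; the output's
    ``age_strata`` are the group labels.
    """
    df = table.df
    mapped = df["age_group"].map(lambda s: scheme.group_of(s))
    if mapped.isna().any():
        missing = sorted(set(df.loc[mapped.isna(), "age_group"]))
        raise CoverageError(f"scheme does not cover strata: {missing}")
    pops = table.populations()
    pops["group"] = pops["age_group"].map(lambda s: scheme.group_of(s))
    group_pop = pops.groupby(["year", "group"])["population"].sum()
    out = (
        df.assign(age_group=mapped)
        .groupby(["year", "age_group", "intent", "cause"], as_index=False, sort=False)["deaths"]
        .sum()
    )
    out["population"] = [
        group_pop.loc[(y, g)] for y, g in zip(out["year"], out["age_group"])
    ]
    labels = tuple(g for g in scheme.group_labels if g in set(out["age_group"]))
    return MortalityTable.from_dataframe(out, age_strata=labels, provenance=table.provenance)
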