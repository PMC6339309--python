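"""Survey-domain containers and I/O.

A :class:`SurveyDataset` bundles the polytomous indicator responses
(integer-coded, ``-1`` marks item nonresponse), household cluster ids and
the individual/household covariates used by the structural regressions.
"Don't know" is a substantive third response category, not missingness —
item nonresponse gets its own sentinel and is handled downstream by
full-information maximum likelihood.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import study

MISSING_CODE = -1
MISSING_LABEL = ""

COVARIATE_COLUMNS = [
    "age", "sex", "ethnicity", "education", "payment_type",
    "cement_walls", "asset_deprived", "sanitation",
]

#: Closed category sets for the categorical covariates ("missing" is a
#: legal code retained at load time and resolved at regression time).
COVARIATE_CATEGORIES = {
    "sex": ["female", "male"],
    "ethnicity": ["afro_ecuadorian", "mestizo_other", "chachi"],
    "education": ["less_than_primary", "primary", "less_than_secondary",
                  "secondary", "missing"],
    "payment_type": ["cash", "cash_and_kind", "not_paid", "not_employed"],
    "cement_walls": ["yes", "no", "missing"],
    "asset_deprived": ["yes", "no", "missing"],
    "sanitation": ["basic", "shared", "unimproved", "none", "missing"],
}


class SchemaError(ValueError):
    """A required column is absent or the file layout is wrong."""


class ValidationError(ValueError):
    """A cell holds a value outside its closed category set."""


@dataclass(frozen=True)
class Indicator:
    """One survey item: a short id, the full statement, and its ordered
    response categories (default agree / disagree / don't know)."""

    id: str
    text: str = ""
    categories: tuple[str, ...] = study.CATEGORIES

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"indicator {self.id!r} needs >=2 categories")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class Codebook:
    """Indicator definitions plus the category -> integer encodings."""

    indicators: tuple[Indicator, ...]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.indicators]
        if len(set(ids)) != len(ids):
            raise ValueError("indicator ids must be unique")

    @property
    def indicator_ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def indicator(self, indicator_id: str) -> Indicator:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def encode(self, indicator_id: str, label: str) -> int:
        """Category label -> integer code; '' -> the missing sentinel."""
        if label == MISSING_LABEL:
            return MISSING_CODE
        cats = self.indicator(indicator_id).categories
        try:
            return cats.index(label)
        except ValueError:
            raise ValidationError(
                f"invalid category {label!r} for indicator {indicator_id!r}; "
                f"expected one of {cats}"
            ) from None

    def decode(self, indicator_id: str, code: int) -> str:
        if code == MISSING_CODE:
            return MISSING_LABEL
        return self.indicator(indicator_id).categories[code]

    def subset(self, indicator_ids: list[str]) -> "Codebook":
        return Codebook(tuple(self.indicator(i) for i in indicator_ids))

    def to_yaml(self, path) -> None:
        payload = {
            "indicators": [
                {"id": ind.id, "text": ind.text, "categories": list(ind.categories)}
                for ind in self.indicators
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(tuple(
            Indicator(d["id"], d.get("text", ""), tuple(d["categories"]))
            for d in payload["indicators"]
        ))


def default_codebook() -> Codebook:
    """The 16-indicator reference-study codebook."""
    return Codebook(tuple(
        Indicator(iid, text) for iid, text, _ in study.INDICATOR_TABLE
    ))


@dataclass
class SurveyDataset:
    """N individuals x J polytomous indicators plus covariates.

    ``responses`` is an int8 array with category codes per the codebook and
    ``-1`` for item nonresponse.  ``covariates`` is indexed 0..N-1 and holds
    the columns in :data:`COVARIATE_COLUMNS` (categoricals as strings with
    an explicit ``"missing"`` code, age as float).
    """

    individual_id: np.ndarray
    household_id: np.ndarray
    responses: np.ndarray
    codebook: Codebook
    covariates: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.household_id = np.asarray(self.household_id, dtype=object)
        self.responses = np.asarray(self.responses, dtype=np.int8)
        n = len(self.individual_id)
        if n < 1:
            # an empty dataset is legal only for generator edge cases
            pass
        if len(set(self.individual_id.tolist())) != n:
            raise ValidationError("individual ids must be unique")
        if self.responses.shape != (n, self.codebook.n_indicators):
            raise ValidationError(
                f"responses shape {self.responses.shape} does not match "
                f"N={n}, J={self.codebook.n_indicators}"
            )
        for j, ind in enumerate(self.codebook.indicators):
            col = self.responses[:, j]
            bad = (col != MISSING_CODE) & ((col < 0) | (col >= ind.n_categories))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"invalid response code {col[row]} for indicator "
                    f"{ind.id!r} at row {row}"
                )
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=pd.RangeIndex(n))
        else:
            self.covariates = self.covariates.reset_index(drop=True)
            for col, cats in COVARIATE_CATEGORIES.items():
                if col not in self.covariates.columns:
                    continue
                vals = self.covariates[col].astype(str)
                bad = ~vals.isin(cats)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValidationError(
                        f"invalid value {vals.iloc[row]!r} for covariate "
                        f"{col!r} at row {row}"
                    )

    @property
    def n(self) -> int:
        return len(self.individual_id)

    @property
    def n_indicators(self) -> int:
        return self.codebook.n_indicators

    @property
    def n_households(self) -> int:
        return len(set(self.household_id.tolist()))

    def select_indicators(self, indicator_ids: list[str]) -> "SurveyDataset":
        """Dataset restricted to a subset of indicators (covariates kept)."""
        idx = [self.codebook.indicator_ids.index(i) for i in indicator_ids]
        return SurveyDataset(
            individual_id=self.individual_id,
            household_id=self.household_id,
            responses=self.responses[:, idx],
            codebook=self.codebook.subset(indicator_ids),
            covariates=self.covariates.copy(),
        )


def read_survey(path, codebook: Codebook) -> SurveyDataset:
    """Read a survey CSV validated against ``codebook``.

    The file must carry ``individual_id``, ``household_id``, one column per
    indicator id, and any of the standard covariate columns.  Unknown
    category strings are rejected, never coerced.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["individual_id", "household_id"] + codebook.indicator_ids
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    n = len(df)
    responses = np.empty((n, codebook.n_indicators), dtype=np.int8)
    for j, iid in enumerate(codebook.indicator_ids):
        col = df[iid].tolist()
        for i, label in enumerate(col):
            try:
                responses[i, j] = codebook.encode(iid, label)
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    covariates = df[cov_cols].copy() if cov_cols else None
    if covariates is not None and "age" in covariates:
        covariates["age"] = pd.to_numeric(
            covariates["age"].replace(MISSING_LABEL, np.nan))
    return SurveyDataset(
        individual_id=df["individual_id"].to_numpy(dtype=object),
        household_id=df["household_id"].to_numpy(dtype=object),
        responses=responses,
        codebook=codebook,
        covariates=covariates,
    )


def write_survey(dataset: SurveyDataset, path) -> None:
    """Inverse of :func:`read_survey`; round-trips category codes bit-exactly."""
    cols = ["individual_id", "household_id"]
    cov_cols = [c for c in COVARIATE_COLUMNS if c in dataset.covariates.columns]
    header = cols + cov_cols + dataset.codebook.indicator_ids
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(dataset.n):
            row = [dataset.individual_id[i], dataset.household_id[i]]
            for c in cov_cols:
                v = dataset.covariates[c].iloc[i]
                if c == "age":
                    v = "" if pd.isna(v) else (f"{v:g}")
                row.append(v)
            row += [
                dataset.codebook.decode(iid, int(dataset.responses[i, j]))
                for j, iid in enumerate(dataset.codebook.indicator_ids)
            ]
            writer.writerow(row)


def binarize_sanitation(dataset: SurveyDataset) -> pd.Series:
    """Household sanitation access -> binary exposure.

    ``basic`` (private improved facility) -> 1; shared, unimproved or no
    facility -> 0; missing propagates as NaN.  This is the referent coding
    of the structural regressions (less-than-basic = 0 is the referent).
    """
    if "sanitation" not in dataset.covariates.columns:
        raise SchemaError("dataset has no 'sanitation' covariate")
    s = dataset.covariates["sanitation"].astype(str)
    out = pd.Series(np.nan, index=s.index, name="basic_sanitation")
    out[s == "basic"] = 1.0
    out[s.isin(["shared", "unimproved", "none"])] = 0.0
    return out


def descriptive_table(dataset: SurveyDataset) -> pd.DataFrame:
    """Covariate frequency table in the published convention.

    Proportions are over all N with ``missing`` kept as a category, so the
    rows of each variable (missing included) sum to 1.
    """
    rows = []
    n = dataset.n
    for var, cats in COVARIATE_CATEGORIES.items():
        if var not in dataset.covariates.columns:
            continue
        vals = dataset.covariates[var].astype(str)
        counts = vals.value_counts()
        seen = set(counts.index)
        order = cats + sorted(seen - set(cats))
        for cat in order:
            c = int(counts.get(cat, 0))
            if cat == "missing" and c == 0:
                continue
            rows.append({"variable": var, "category": cat,
                         "proportion": c / n, "n": c})
    if "age" in dataset.covariates.columns:
        age = pd.to_numeric(dataset.covariates["age"], errors="coerce")
        rows.insert(0, {"variable": "age", "category": "median (SD)",
                        "proportion": np.nan, "n": int(age.notna().sum()),
                        })
        rows[0]["median"] = float(age.median())
        rows[0]["sd"] = float(age.std(ddof=1)) if age.notna().sum() > 1 else np.nan
    return pd.DataFrame(rows)
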