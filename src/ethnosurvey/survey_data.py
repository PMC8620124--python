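"""Data model, file I/O, validation and descriptive cross-tabulation for
miracle-plant ethnobotanical survey tables.

Two tables describe a survey: a *respondents* table (one row per interviewee
with demographics, tree-ownership facts, perceptions and cultivation-intent
outcomes) and a *use-reports* table (one row per respondent x cited use, with
the use category, body system, plant part, preparation and knowledge-source
descriptors).  Both are plain UTF-8 CSV with a mandatory header row.

Free-text labels found on disk are normalised to the canonical vocabulary
through a :class:`CodebookConfig` synonym map, so files produced by different
field teams can be loaded without manual recoding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Respondent",
    "UseReport",
    "SurveyDataset",
    "CodebookConfig",
    "Violation",
    "DataLoadError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "demographic_crosstab",
    "age_category_for",
]

# ---------------------------------------------------------------------------
# Canonical vocabularies
# ---------------------------------------------------------------------------

COUNTRIES = ("Benin", "Ghana")
GROUPS = (
    "Adja", "Aizo", "Fon", "Holli", "Sahouè", "Wémé",   # Benin
    "Akan", "Ewe", "Ga-adangbe",                        # Ghana
)
GROUP_COUNTRY: Mapping[str, str] = {
    g: ("Ghana" if g in ("Akan", "Ewe", "Ga-adangbe") else "Benin") for g in GROUPS
}
GENDERS = ("man", "woman")
AGE_CATEGORIES = ("young", "adult", "old")
# "literate" (reads/writes without formal schooling) sits between none and primary.
SCHOOLING_LEVELS = ("none", "literate", "primary", "secondary", "university")
ACTIVITIES = ("farming", "handcraft", "teaching", "trading", "traditional_healing")
RELIGIONS = ("christian", "indigenous", "muslim")
MIGRATORY_STATUSES = ("autochthon", "allochthon")
OWNERSHIP_MODES = ("legacy", "self", "legacy_and_self", "spontaneous")
HABITATS = ("home_garden", "farm")
GROWTH_PERCEPTIONS = ("slow", "moderate", "fast")
AVAILABILITY_PERCEPTIONS = ("decline", "stable", "increase")

USE_CATEGORIES = ("food", "medicinal", "magico_spiritual", "sales", "social", "firewood")
BODY_SYSTEMS = (
    "blood", "circulatory", "digestive", "endocrine_metabolic_nutritional",
    "eye", "female_genital", "general_health", "male_genital",
    "musculoskeletal", "neurological", "pregnancy_childbearing",
    "psychological", "respiratory", "skin", "urinary",
    "non_medicinal",  # sentinel for non-medicinal use categories
)
PLANT_PARTS = ("flower", "fruit", "seed", "leaf", "twig", "bark", "root")
PREPARATIONS = ("decoction", "grinding", "direct", "infusion", "other")
SOURCE_RELATIONS = (
    "father", "mother", "grandfather", "grandmother", "uncle_aunt",
    "sibling", "cousin", "spouse", "friend", "community", "healer",
    "self_learning",
)
SOURCE_GENDERS = ("man", "woman", "not_applicable")

#: age-class boundaries: young < 30, adult 30-59, old >= 60
def age_category_for(age_years: int | float) -> str:
    if age_years < 30:
        return "young"
    if age_years < 60:
        return "adult"
    return "old"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class Respondent:
    respondent_id: str
    country: str
    group: str
    gender: str
    age_years: int
    age_category: str
    schooling: str
    activity: str
    religion: str
    migratory_status: str
    owns_trees: bool
    n_trees: int
    perceived_growth: str
    perceived_time_to_fruiting_years: float
    perceived_availability: str
    knows_taboo: bool
    knows_superstition: bool
    perceives_market: bool
    willing_to_cultivate: bool
    land_area_ha: float = 0.0
    ownership_mode: str | None = None
    habitat: str | None = None
    max_acreage_ha: float | None = None
    max_price_usd: float | None = None


@dataclass
class UseReport:
    respondent_id: str
    use_label: str
    category: str
    body_system: str
    plant_part: str
    preparation: str
    source_relation: str
    source_gender: str


@dataclass
class SurveyDataset:
    """A loaded or generated survey: respondents plus their use reports."""

    respondents: list[Respondent]
    use_reports: list[UseReport]
    provenance: dict = field(default_factory=dict)

    def respondent_ids(self) -> list[str]:
        return [r.respondent_id for r in self.respondents]

    def respondents_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.respondents])

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(u) for u in self.use_reports])

    def reports_by_respondent(self) -> dict[str, list[UseReport]]:
        out: dict[str, list[UseReport]] = {r.respondent_id: [] for r in self.respondents}
        for u in self.use_reports:
            out.setdefault(u.respondent_id, []).append(u)
        return out


# categorical Respondent fields eligible for cross-tabulation
_CATEGORICAL_FIELDS: Mapping[str, tuple[str, ...]] = {
    "country": COUNTRIES,
    "group": GROUPS,
    "gender": GENDERS,
    "age_category": AGE_CATEGORIES,
    "schooling": SCHOOLING_LEVELS,
    "activity": ACTIVITIES,
    "religion": RELIGIONS,
    "migratory_status": MIGRATORY_STATUSES,
    "ownership_mode": OWNERSHIP_MODES,
    "habitat": HABITATS,
    "perceived_growth": GROWTH_PERCEPTIONS,
    "perceived_availability": AVAILABILITY_PERCEPTIONS,
}

_RESPONDENT_ENUMS: Mapping[str, tuple[str, ...]] = {
    **_CATEGORICAL_FIELDS,
}
_REPORT_ENUMS: Mapping[str, tuple[str, ...]] = {
    "category": USE_CATEGORIES,
    "body_system": BODY_SYSTEMS,
    "plant_part": PLANT_PARTS,
    "preparation": PREPARATIONS,
    "source_relation": SOURCE_RELATIONS,
    "source_gender": SOURCE_GENDERS,
}

_BOOL_FIELDS = ("owns_trees", "knows_taboo", "knows_superstition",
                "perceives_market", "willing_to_cultivate")
_OPTIONAL_FIELDS = ("ownership_mode", "habitat", "max_acreage_ha", "max_price_usd")


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

def _slugify(label: str) -> str:
    return label.strip().lower().replace("-", "_").replace(" ", "_").replace("/", "_")


@dataclass
class CodebookConfig:
    """Delimiter and label-synonym configuration for reading survey files.

    ``synonyms`` maps a column name to ``{observed label: canonical label}``;
    matching is attempted on the raw label first, then on its lower-cased,
    underscore-normalised form.
    """

    delimiter: str = ","
    synonyms: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodebookConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(delimiter=raw.get("delimiter", ","),
                   synonyms={k: dict(v) for k, v in raw.get("synonyms", {}).items()})

    def canonical(self, column: str, label: str, allowed: Iterable[str]) -> str:
        allowed = tuple(allowed)
        if label in allowed:
            return label
        table = self.synonyms.get(column, {})
        if label in table:
            return table[label]
        slug = _slugify(label)
        if slug in allowed:
            return slug
        lowered = {k.lower(): v for k, v in table.items()}
        if label.lower() in lowered:
            return lowered[label.lower()]
        if slug in {_slugify(k): v for k, v in table.items()}.keys():
            return {_slugify(k): v for k, v in table.items()}[slug]
        raise DataLoadError(f"unknown label {label!r} in column {column!r} "
                            f"(no codebook mapping)")


def default_codebook() -> CodebookConfig:
    """Codebook carrying the synonym spellings common in field files."""
    return CodebookConfig(synonyms={
        "category": {
            "Magico-spiritual": "magico_spiritual",
            "Medicines": "medicinal",
            "Fuelwood": "firewood",
        },
        "schooling": {"No-schooling": "none", ">Bac": "university"},
        "gender": {"Men": "man", "Women": "woman"},
        "plant_part": {
            "Fruits": "fruit", "Leaves": "leaf", "Roots": "root",
            "Seeds": "seed", "Twigs": "twig", "Branches/twigs": "twig",
            "Flowers": "flower", "Bark": "bark",
        },
    })


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

class DataLoadError(ValueError):
    """Raised when a survey file cannot be parsed into a valid dataset."""


def _parse_bool(raw: str, column: str) -> bool:
    v = raw.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise DataLoadError(f"cannot parse boolean {raw!r} in column {column!r}")


def read_dataset(respondents_path: str | Path,
                 reports_path: str | Path,
                 codebook: CodebookConfig | None = None) -> SurveyDataset:
    """Load and validate a survey from its two CSV files.

    Raises :class:`DataLoadError` on duplicate respondent ids, use reports
    referencing an unknown respondent, labels with no codebook mapping, or a
    missing/renamed header column.
    """
    codebook = codebook or default_codebook()
    expected_r = [f.name for f in dataclasses.fields(Respondent)]
    expected_u = [f.name for f in dataclasses.fields(UseReport)]

    rdf = pd.read_csv(respondents_path, sep=codebook.delimiter, dtype=str,
                      keep_default_na=False)
    udf = pd.read_csv(reports_path, sep=codebook.delimiter, dtype=str,
                      keep_default_na=False)
    for name, df, expected in (("respondents", rdf, expected_r),
                               ("use_reports", udf, expected_u)):
        missing = set(expected) - set(df.columns)
        if missing:
            raise DataLoadError(f"{name} file is missing columns: {sorted(missing)}")

    respondents: list[Respondent] = []
    seen: set[str] = set()
    for i, row in enumerate(rdf.to_dict("records")):
        rid = row["respondent_id"].strip()
        if rid in seen:
            raise DataLoadError(f"duplicate respondent_id {rid!r} (row {i + 2})")
        seen.add(rid)
        try:
            kwargs: dict = {"respondent_id": rid}
            for col in ("country",):
                kwargs[col] = codebook.canonical(col, row[col], COUNTRIES)
            for col, allowed in _RESPONDENT_ENUMS.items():
                raw = row[col].strip()
                if col in ("ownership_mode", "habitat") and raw == "":
                    kwargs[col] = None
                else:
                    kwargs[col] = codebook.canonical(col, raw, allowed)
            for col in _BOOL_FIELDS:
                kwargs[col] = _parse_bool(row[col], col)
            kwargs["age_years"] = int(row["age_years"])
            kwargs["n_trees"] = int(row["n_trees"])
            kwargs["land_area_ha"] = float(row["land_area_ha"])
            kwargs["perceived_time_to_fruiting_years"] = float(
                row["perceived_time_to_fruiting_years"])
            for col in ("max_acreage_ha", "max_price_usd"):
                raw = row[col].strip()
                kwargs[col] = None if raw == "" else float(raw)
            respondents.append(Respondent(**kwargs))
        except DataLoadError:
            raise
        except (ValueError, KeyError) as exc:  # numeric parse failures
            raise DataLoadError(f"respondents row {i + 2} ({rid!r}): {exc}") from exc

    reports: list[UseReport] = []
    for i, row in enumerate(udf.to_dict("records")):
        rid = row["respondent_id"].strip()
        if rid not in seen:
            raise DataLoadError(
                f"use_reports row {i + 2} references unknown respondent {rid!r}")
        kwargs = {"respondent_id": rid, "use_label": row["use_label"].strip()}
        for col, allowed in _REPORT_ENUMS.items():
            kwargs[col] = codebook.canonical(col, row[col].strip(), allowed)
        reports.append(UseReport(**kwargs))

    return SurveyDataset(respondents=respondents, use_reports=reports,
                         provenance={"source": str(respondents_path)})


def _serialise(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_dataset(ds: SurveyDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``respondents.csv`` and ``use_reports.csv`` under *out_dir*.

    ``read_dataset`` applied to the written files reproduces the dataset
    field-for-field (floats are serialised with ``repr`` so round-trips are
    exact); absent optional fields are written as empty strings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r_path = out_dir / "respondents.csv"
    u_path = out_dir / "use_reports.csv"
    r_cols = [f.name for f in dataclasses.fields(Respondent)]
    u_cols = [f.name for f in dataclasses.fields(UseReport)]
    rdf = pd.DataFrame(
        [{c: _serialise(getattr(r, c)) for c in r_cols} for r in ds.respondents],
        columns=r_cols)
    udf = pd.DataFrame(
        [{c: _serialise(getattr(u, c)) for c in u_cols} for u in ds.use_reports],
        columns=u_cols)
    rdf.to_csv(r_path, index=False)
    udf.to_csv(u_path, index=False)
    return r_path, u_path


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    respondent_id: str
    rule: str
    message: str


def validate_dataset(ds: SurveyDataset) -> list[Violation]:
    """Check every record against the survey invariants.

    Violations are data, not exceptions: the returned list is empty iff the
    dataset is internally consistent.  The stored ``age_category`` label is
    recomputed from ``age_years`` and checked, never trusted.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for r in ds.respondents:
        rid = r.respondent_id
        if rid in seen:
            out.append(Violation(rid, "respondent_id", "duplicate respondent_id"))
        seen.add(rid)
        expected = age_category_for(r.age_years)
        if r.age_category != expected:
            out.append(Violation(rid, "age_category",
                                 f"age {r.age_years} implies {expected!r}, "
                                 f"found {r.age_category!r}"))
        if r.age_years <= 0:
            out.append(Violation(rid, "age_years", "age must be positive"))
        if (r.n_trees == 0) != (not r.owns_trees):
            out.append(Violation(rid, "n_trees",
                                 f"owns_trees={r.owns_trees} but n_trees={r.n_trees}"))
        for opt in ("ownership_mode", "habitat"):
            present = getattr(r, opt) is not None
            if present != r.owns_trees:
                out.append(Violation(rid, opt,
                                     f"{opt} must be present iff owns_trees"))
        for opt in ("max_acreage_ha", "max_price_usd"):
            present = getattr(r, opt) is not None
            if present != r.willing_to_cultivate:
                out.append(Violation(
                    rid, opt, f"{opt} must be present iff willing_to_cultivate"))
        if GROUP_COUNTRY.get(r.group) != r.country:
            out.append(Violation(rid, "country",
                                 f"group {r.group!r} belongs to "
                                 f"{GROUP_COUNTRY.get(r.group)!r}, found {r.country!r}"))
    for u in ds.use_reports:
        rid = u.respondent_id
        if rid not in seen:
            out.append(Violation(rid, "respondent_id", "unresolved foreign key"))
        medicinal = u.category == "medicinal"
        if medicinal == (u.body_system == "non_medicinal"):
            out.append(Violation(rid, "body_system",
                                 f"category {u.category!r} inconsistent with "
                                 f"body_system {u.body_system!r}"))
        if (u.source_relation == "self_learning") != (u.source_gender == "not_applicable"):
            out.append(Violation(rid, "source_gender",
                                 "source_gender must be not_applicable iff "
                                 "source_relation is self_learning"))
    return out


# ---------------------------------------------------------------------------
# Descriptive cross-tabulation
# ---------------------------------------------------------------------------

def demographic_crosstab(ds: SurveyDataset, factor: str) -> pd.DataFrame:
    """Percentage of each *factor* level within each sociolinguistic group.

    Returns a DataFrame with one row per factor level and one column per
    group present in the data plus a ``Total`` column; every column sums to
    100 (within floating precision).  Only categorical respondent fields are
    accepted.
    """
    if factor not in _CATEGORICAL_FIELDS:
        raise ValueError(f"{factor!r} is not a categorical respondent field; "
                         f"choose one of {sorted(_CATEGORICAL_FIELDS)}")
    df = ds.respondents_frame()
    sub = df[df[factor].notna()]
    if sub.empty:
        raise ValueError(f"no observations carry a value for {factor!r}")
    tab = pd.crosstab(sub[factor], sub["group"])
    tab = tab.loc[:, [g for g in GROUPS if g in tab.columns]]
    tab["Total"] = tab.sum(axis=1)
    pct = tab / tab.sum(axis=0) * 100.0
    levels = [lv for lv in _CATEGORICAL_FIELDS[factor] if lv in pct.index]
    return pct.loc[levels]
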