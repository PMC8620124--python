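"""KMTO knowledge-acquisition coding.

Each knowledge-acquisition event is coded as a four-attribute path:

* **Kernel** — ``internal`` when the knowledge travelled along the
  respondent's family line, ``external`` for community sources (a friend,
  the community at large, a healer).
* **Mutation** — ``transition`` when transmitter and respondent share a
  gender, ``transversion`` when they differ.
* **Type** — ``vertical`` for cross-generation transfer, ``horizontal``
  within a generation, ``transversal`` for self-learning (books,
  experimentation).
* **Order** — 1 for a direct progenitor (father/mother), 2 for a
  grandparent, 0 otherwise (the rule reserved for horizontal and
  transversal transfer).

The full attribute product has 2 x 2 x 3 x 3 = 36 paths; requiring the
order to be consistent with the type (vertical with order 1 or 2,
horizontal/transversal with order 0) leaves 16 structurally valid ones.

Coding conventions for the relations the attribute definitions leave open
(kept in one place, :data:`_RELATION_CODES`): spouses are internal and
horizontal; uncles/aunts are internal vertical with order 0 — the one
relation whose path is structurally flagged, since orders 1-2 are reserved
for progenitors and grandparents; cousins are internal horizontal;
self-learning is internal with a same-gender ("transition") mutation by
convention.  Community-type sources carry the gender the informant reported
for whoever taught them; nothing is inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .survey_data import SOURCE_RELATIONS, SurveyDataset

__all__ = [
    "KMTOPath",
    "PathTally",
    "classify_kmto",
    "enumerate_paths",
    "path_frequencies",
    "attribute_state_tests",
    "kmto_category_tests",
]

KERNELS = ("internal", "external")
MUTATIONS = ("transition", "transversion")
TYPES = ("vertical", "horizontal", "transversal")
ORDERS = (0, 1, 2)


@dataclass(frozen=True, order=True)
class KMTOPath:
    kernel: str
    mutation: str
    type: str
    order: int

    @property
    def structurally_valid(self) -> bool:
        if self.type == "vertical":
            return self.order in (1, 2)
        return self.order == 0

    def label(self) -> str:
        return f"{self.kernel}/{self.mutation}/{self.type}/{self.order}"


@dataclass(frozen=True)
class PathTally:
    path: KMTOPath
    count: int
    proportion: float


# relation -> (kernel, type, order); mutation depends on genders
_RELATION_CODES: dict[str, tuple[str, str, int]] = {
    "father": ("internal", "vertical", 1),
    "mother": ("internal", "vertical", 1),
    "grandfather": ("internal", "vertical", 2),
    "grandmother": ("internal", "vertical", 2),
    "uncle_aunt": ("internal", "vertical", 0),
    "sibling": ("internal", "horizontal", 0),
    "cousin": ("internal", "horizontal", 0),
    "spouse": ("internal", "horizontal", 0),
    "friend": ("external", "horizontal", 0),
    "community": ("external", "horizontal", 0),
    "healer": ("external", "horizontal", 0),
    "self_learning": ("internal", "transversal", 0),
}
assert set(_RELATION_CODES) == set(SOURCE_RELATIONS)


def classify_kmto(source_relation: str, source_gender: str,
                  respondent_gender: str) -> KMTOPath:
    """Code one knowledge-acquisition event as a KMTO path."""
    if source_relation not in _RELATION_CODES:
        raise ValueError(f"unknown source relation {source_relation!r}")
    if source_relation == "self_learning":
        if source_gender != "not_applicable":
            raise ValueError("self-learning admits no transmitter gender; "
                             "source_gender must be 'not_applicable'")
        # self-transfer: same person, hence same gender -> transition
        mutation = "transition"
    else:
        if source_gender not in ("man", "woman"):
            raise ValueError(f"invalid source_gender {source_gender!r}")
        mutation = ("transition" if source_gender == respondent_gender
                    else "transversion")
    kernel, type_, order = _RELATION_CODES[source_relation]
    return KMTOPath(kernel, mutation, type_, order)


def enumerate_paths(constrained: bool = False) -> list[KMTOPath]:
    """All 36 attribute combinations, or the 16 structurally valid paths."""
    paths = [KMTOPath(k, m, t, o)
             for k, m, t, o in product(KERNELS, MUTATIONS, TYPES, ORDERS)]
    if constrained:
        paths = [p for p in paths if p.structurally_valid]
    return paths


def _tally(paths: list[KMTOPath]) -> list[PathTally]:
    counts: dict[KMTOPath, int] = {}
    for p in paths:
        counts[p] = counts.get(p, 0) + 1
    total = sum(counts.values())
    return [PathTally(p, c, c / total) for p, c in sorted(counts.items())]


def path_frequencies(ds: SurveyDataset, by_category: bool = False):
    """Observed path tallies, overall or per use category.

    Zero-count paths are omitted; proportions are normalised within each
    grouping (so they sum to 1 overall, or within every category).
    """
    if by_category:
        per_cat: dict[str, list[KMTOPath]] = {}
        for u in ds.use_reports:
            r_gender = _respondent_gender(ds, u.respondent_id)
            per_cat.setdefault(u.category, []).append(
                classify_kmto(u.source_relation, u.source_gender, r_gender))
        return {cat: _tally(paths) for cat, paths in sorted(per_cat.items())}
    paths = [classify_kmto(u.source_relation, u.source_gender,
                           _respondent_gender(ds, u.respondent_id))
             for u in ds.use_reports]
    return _tally(paths)


def _respondent_gender(ds: SurveyDataset, rid: str) -> str:
    if not hasattr(ds, "_gender_cache"):
        ds._gender_cache = {r.respondent_id: r.gender for r in ds.respondents}
    return ds._gender_cache[rid]


def _attribute_states(ds: SurveyDataset):
    """Per-report attribute states as four parallel lists."""
    out = {"kernel": [], "mutation": [], "type": [], "order": []}
    cats = []
    for u in ds.use_reports:
        p = classify_kmto(u.source_relation, u.source_gender,
                          _respondent_gender(ds, u.respondent_id))
        out["kernel"].append(p.kernel)
        out["mutation"].append(p.mutation)
        out["type"].append(p.type)
        out["order"].append(str(p.order))
        cats.append(u.category)
    return out, cats


_ATTRIBUTE_DOMAINS = {
    "kernel": KERNELS,
    "mutation": MUTATIONS,
    "type": TYPES,
    "order": tuple(str(o) for o in ORDERS),
}


def attribute_state_tests(ds: SurveyDataset) -> dict:
    """Equal-proportions chi-square across the states of each attribute.

    Counts are tallied over the attribute's full state space, so a state
    never observed contributes a zero cell (and evidence against equal
    proportions), rather than silently shrinking the test."""
    from .association import equal_proportions_test

    states, _ = _attribute_states(ds)
    results = {}
    for attr, values in states.items():
        counts = [values.count(lv) for lv in _ATTRIBUTE_DOMAINS[attr]]
        results[attr] = equal_proportions_test(counts)
    return results


def kmto_category_tests(ds: SurveyDataset, seed: int = 0) -> dict:
    """Independence of each attribute's state vs the use category."""
    import pandas as pd

    from .association import independence_test

    states, cats = _attribute_states(ds)
    results = {}
    for attr, values in states.items():
        table = pd.crosstab(pd.Series(values, name=attr),
                            pd.Series(cats, name="category"))
        results[attr] = independence_test(table.to_numpy(), seed=seed)
    return results
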