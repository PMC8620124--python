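"""Ethnobotanical indices: use value, informant agreement, and the
use-value / tree-count correlation analysis.

The use value of the species for respondent j is the number of distinct use
reports that respondent cites,

    UV_j = sum_i UR_i ,

and the species-level use value is its mean over all N respondents,

    UV = sum_j UV_j / N        (Phillips & Gentry index).

A use report is counted once per distinct (use label, plant part) pair, so
UV_j is independent of row ordering and of accidental duplicate rows.

The informant agreement ratio for a scope (a use category or a body system)
with nr citations spread over na distinct plant parts is

    IAR = (nr - na) / (nr - 1) ,

1 when every citation names the same part, 0 when every citation names a
different part, and undefined for a single citation (serialised as "NA").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .survey_data import PLANT_PARTS, SurveyDataset, USE_CATEGORIES

__all__ = [
    "UVRecord",
    "IARRecord",
    "respondent_use_value",
    "total_use_value",
    "use_value_by",
    "informant_agreement_ratio",
    "iar_table",
    "uv_trees_correlation",
    "compare_correlations_fisher_z",
]


@dataclass(frozen=True)
class UVRecord:
    scope: str
    n_respondents: int
    uv: float
    sem: float


@dataclass(frozen=True)
class IARRecord:
    scope: str
    nr: int
    na: int
    iar: float | None  # None = undefined (single citation)

    def iar_display(self, ndigits: int = 2) -> str:
        """Half-up rounding for display; several published tables instead
        truncate (e.g. 90/94 = 0.9574 shown as 0.95), so comparisons should
        use cells where the conventions agree."""
        if self.iar is None:
            return "NA"
        q = 10 ** ndigits
        return f"{math.floor(self.iar * q + 0.5) / q:.{ndigits}f}"


def _distinct_pairs(reports) -> set[tuple[str, str]]:
    return {(u.use_label, u.plant_part) for u in reports}


def respondent_use_value(ds: SurveyDataset, respondent_id: str) -> int:
    """UV_j: the respondent's count of distinct (use label, plant part) citations."""
    if respondent_id not in set(ds.respondent_ids()):
        raise KeyError(respondent_id)
    return len(_distinct_pairs(
        u for u in ds.use_reports if u.respondent_id == respondent_id))


def _uv_vector(ds: SurveyDataset) -> dict[str, int]:
    pairs: dict[str, set] = {rid: set() for rid in ds.respondent_ids()}
    for u in ds.use_reports:
        pairs[u.respondent_id].add((u.use_label, u.plant_part))
    return {rid: len(s) for rid, s in pairs.items()}


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, sem


def total_use_value(ds: SurveyDataset) -> UVRecord:
    """Overall UV with its standard error of the mean."""
    if not ds.respondents:
        raise ValueError("dataset has no respondents")
    uvj = np.array(list(_uv_vector(ds).values()), dtype=float)
    uv, sem = _mean_sem(uvj)
    return UVRecord("overall", len(uvj), uv, sem)


_RESPONDENT_AXES = ("group", "gender", "age_category", "schooling", "activity",
                    "religion", "migratory_status", "country", "owns_trees",
                    "habitat", "knows_taboo")


def use_value_by(ds: SurveyDataset, axis: str) -> list[UVRecord]:
    """Disaggregated use values.

    ``axis`` may be ``"category"`` or ``"plant_part"`` (numerator restricted
    to qualifying reports, denominator always the full N, so category UVs
    sum to the overall UV), or a categorical respondent field (respondents
    partitioned by level, per-level mean of UV_j).
    """
    if not ds.respondents:
        raise ValueError("dataset has no respondents")
    n_all = len(ds.respondents)
    if axis in ("category", "plant_part"):
        levels = USE_CATEGORIES if axis == "category" else PLANT_PARTS
        out = []
        for level in levels:
            counts: dict[str, set] = {}
            for u in ds.use_reports:
                if getattr(u, "category" if axis == "category" else "plant_part") == level:
                    counts.setdefault(u.respondent_id, set()).add(
                        (u.use_label, u.plant_part))
            per_r = np.zeros(n_all)
            index = {rid: i for i, rid in enumerate(ds.respondent_ids())}
            for rid, s in counts.items():
                per_r[index[rid]] = len(s)
            uv, sem = _mean_sem(per_r)
            out.append(UVRecord(level, n_all, uv, sem))
        return out
    if axis not in _RESPONDENT_AXES:
        raise ValueError(f"unknown axis {axis!r}")
    uvj = _uv_vector(ds)
    out = []
    levels: dict[str, list[float]] = {}
    for r in ds.respondents:
        key = str(getattr(r, axis))
        levels.setdefault(key, []).append(uvj[r.respondent_id])
    for level in sorted(levels):
        vals = np.array(levels[level], dtype=float)
        uv, sem = _mean_sem(vals)
        out.append(UVRecord(level, len(vals), uv, sem))
    return out


def informant_agreement_ratio(nr: int, na: int) -> float | None:
    """(nr - na)/(nr - 1); None (undefined) when nr = 1."""
    if nr < 1:
        raise ValueError(f"nr must be >= 1, got {nr}")
    if not 1 <= na <= nr:
        raise ValueError(f"na must lie in [1, nr={nr}], got {na}")
    if nr == 1:
        return None
    return (nr - na) / (nr - 1)


def iar_table(ds: SurveyDataset, level: str = "category") -> list[IARRecord]:
    """Agreement ratios per use category or per (medicinal) body system.

    ``nr`` is the raw citation count in scope, ``na`` the number of distinct
    plant parts cited there; scopes with no citations are omitted and rows
    are sorted by scope label.
    """
    if level not in ("category", "body_system"):
        raise ValueError(f"level must be 'category' or 'body_system', got {level!r}")
    buckets: dict[str, list] = {}
    for u in ds.use_reports:
        if level == "body_system":
            if u.category != "medicinal":
                continue
            key = u.body_system
        else:
            key = u.category
        buckets.setdefault(key, []).append(u)
    out = []
    for scope in sorted(buckets):
        reports = buckets[scope]
        nr = len(reports)
        na = len({u.plant_part for u in reports})
        out.append(IARRecord(scope, nr, na, informant_agreement_ratio(nr, na)))
    return out


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (small n).

    All n! rank pairings share the same marginal moments, so each permuted
    rho reduces to a dot product; the full distribution is evaluated in one
    vectorised pass.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(ry)))
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    sx = rx.std()
    sy = ry.std()
    rhos = (perms @ rx / n - mx * my) / (sx * sy)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def uv_trees_correlation(ds: SurveyDataset, subset=None,
                         method: str = "spearman") -> tuple[float, float, int]:
    """Correlation between UV_j and the number of trees owned.

    ``subset`` is an optional predicate over respondents.  Spearman p-values
    use an exact permutation distribution for n <= 10 and the t
    approximation above; a constant vector makes the correlation undefined
    and raises ValueError.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    uvj = _uv_vector(ds)
    rows = [r for r in ds.respondents if subset is None or subset(r)]
    if len(rows) < 4:
        raise ValueError("subset must contain at least 4 respondents")
    x = np.array([uvj[r.respondent_id] for r in rows], dtype=float)
    y = np.array([r.n_trees for r in rows], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant vector")
    n = len(rows)
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue), n
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = _spearman_exact_p(x, y, rho) if n <= 10 else float(res.pvalue)
    return rho, p, n


def compare_correlations_fisher_z(r1: float, n1: int, r2: float, n2: int
                                  ) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), with a two-sided
    normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p
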