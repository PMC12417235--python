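"""Cohort agreement and comparison statistics.

Implements the analysis battery used to compare downstream-restricted and
whole-territory collateral scores and to quantify rater agreement:
quadratically weighted Cohen's kappa on a fixed ordinal category set, paired
one-sided Wilcoxon signed-rank tests, Bland-Altman limits of agreement,
confusion matrices, and the proportion of patients shifting from the good
(CS 2-3) to the poor (CS 0-1) dichotomized group.  Undefined scores are
excluded pairwise with counts reported; no multiple-testing correction is
applied (raw p-values per occlusion location).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

TAN_LEVELS = (0, 1, 2, 3)
EXTENDED_LEVELS = ("0", "1a", "1b", "2a", "2b", "3")
OCCLUSION_LOCATIONS = ("proximal_M1", "distal_M1", "M2")

#: Columns expected in a cohort table; rater label columns are ``rater_<id>``.
COHORT_COLUMNS = (
    "patient_id",
    "occlusion_location",
    "odacs_ratio",
    "mca_ratio",
    "odacs_category",
    "mca_category",
)


class DegenerateStatisticWarning(UserWarning):
    """A statistic is undefined on this input (e.g. all-zero differences)."""


@dataclass
class AgreementReport:
    kappa: float  # NaN when undefined
    weighting: str
    confusion: np.ndarray
    n: int
    n_dropped: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "kappa": None if math.isnan(self.kappa) else self.kappa,
            "weighting": self.weighting,
            "confusion": self.confusion.tolist(),
            "n": self.n,
            "n_dropped": self.n_dropped,
        }


@dataclass
class ComparisonReport:
    mean_difference: float
    loa_low: float
    loa_high: float
    wilcoxon_statistic: float
    p_value: float
    shift_good_to_poor: tuple[int, int]  # numerator, denominator
    notes: list[str] = field(default_factory=list)


def _paired_defined(a: Sequence, b: Sequence) -> tuple[list, list, int]:
    """Drop pairs where either element is undefined (None or NaN)."""
    if len(a) != len(b):
        raise DomainError(f"paired sequences differ in length: {len(a)} vs {len(b)}")

    def ok(v) -> bool:
        if v is None:
            return False
        if isinstance(v, float) and math.isnan(v):
            return False
        return True

    xa, xb = [], []
    for va, vb in zip(a, b):
        if ok(va) and ok(vb):
            xa.append(va)
            xb.append(vb)
    return xa, xb, len(a) - len(xa)


def confusion_matrix(
    labels_a: Sequence, labels_b: Sequence, categories: Sequence = TAN_LEVELS
) -> np.ndarray:
    """K x K count matrix; entry (i, j) counts pairs (a=cat_i, b=cat_j).

    The category set is fixed by the declared scale (not the data) so matrix
    shape and kappa weights are stable across subsets.
    """
    a, b, _ = _paired_defined(labels_a, labels_b)
    cats = list(categories)
    pos = {c: i for i, c in enumerate(cats)}
    bad = [v for v in list(a) + list(b) if v not in pos]
    if bad:
        raise DomainError(f"labels outside declared categories {cats}: {sorted(set(bad))}")
    k = len(cats)
    out = np.zeros((k, k), dtype=int)
    for va, vb in zip(a, b):
        out[pos[va], pos[vb]] += 1
    return out


def weighted_kappa(
    labels_a: Sequence, labels_b: Sequence, categories: Sequence = TAN_LEVELS
) -> float:
    """Quadratically weighted Cohen's kappa on an ordered category set.

    kappa = 1 - sum(w * O) / sum(w * E) with weights
    w_ij = (i - j)^2 / (K - 1)^2, observed counts O, and chance-expected
    counts E from the marginals.  Pairs with undefined labels are dropped;
    at least two defined pairs are required.  Returns NaN with a warning in
    the degenerate case of zero expected disagreement.
    """
    a, b, _ = _paired_defined(labels_a, labels_b)
    if len(a) < 2:
        raise DomainError(f"need at least 2 defined pairs, got {len(a)}")
    obs = confusion_matrix(a, b, categories)
    n = obs.sum()
    k = len(list(categories))
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (i - j) ** 2 / (k - 1) ** 2
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    denom = float((w * expected).sum())
    num = float((w * obs).sum())
    if denom == 0:
        if num == 0:
            return 1.0
        warnings.warn(
            "zero chance-expected disagreement with nonzero observed disagreement; "
            "kappa undefined",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
        return float("nan")
    return 1.0 - num / denom


def agreement_report(
    labels_a: Sequence, labels_b: Sequence, categories: Sequence = TAN_LEVELS
) -> AgreementReport:
    a, b, dropped = _paired_defined(labels_a, labels_b)
    conf = confusion_matrix(a, b, categories)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateStatisticWarning)
        kappa = weighted_kappa(a, b, categories) if len(a) >= 2 else float("nan")
    return AgreementReport(
        kappa=kappa, weighting="quadratic", confusion=conf, n=int(conf.sum()),
        n_dropped=dropped,
    )


EXACT_WILCOXON_MAX_N = 25


def wilcoxon_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "less"
) -> tuple[float, float]:
    """Paired one-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences are mid-ranked.
    The p-value is computed by exact enumeration of sign assignments when at
    most 25 nonzero tie-free differences remain, and by the normal
    approximation with tie correction otherwise.  Returns (NaN, NaN) with a
    warning when all differences are zero.
    """
    if alternative not in ("less", "greater"):
        raise DomainError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    xs, ys, _ = _paired_defined(x, y)
    d = np.asarray(xs, dtype=float) - np.asarray(ys, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn(
            "all paired differences are zero; Wilcoxon statistic undefined",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
        return float("nan"), float("nan")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= EXACT_WILCOXON_MAX_N and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method, correction=False)
    return float(res.statistic), float(res.pvalue)


def bland_altman(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Bland-Altman agreement summary of paired measurements.

    Differences are ``d = x - y``; returns (mean difference, lower and upper
    1.96 * SD limits of agreement with sample (n-1) standard deviation, the
    per-pair means, and the per-pair differences).
    """
    xs, ys, _ = _paired_defined(x, y)
    if len(xs) < 2:
        raise DomainError(f"need at least 2 defined pairs, got {len(xs)}")
    xa = np.asarray(xs, dtype=float)
    ya = np.asarray(ys, dtype=float)
    d = xa - ya
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd, (xa + ya) / 2.0, d


def shift_proportion(
    reference_cats: Sequence, new_cats: Sequence
) -> tuple[int, int, float]:
    """Fraction of patients shifting good (CS 2-3) -> poor (CS 0-1).

    The numerator counts pairs whose reference category is good but whose
    new-method category is poor; the denominator is all defined pairs.
    """
    ref, new, _ = _paired_defined(reference_cats, new_cats)
    if not ref:
        raise DomainError("no defined category pairs")
    num = sum(1 for r, n in zip(ref, new) if r in (2, 3) and n in (0, 1))
    den = len(ref)
    return num, den, num / den


def _median_iqr(values: Sequence[float]) -> dict[str, float | None]:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return {"median": None, "iqr_low": None, "iqr_high": None, "n": 0}
    arr = np.asarray(vals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3), "n": len(vals)}


def validate_cohort_table(table: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DomainError(f"cohort table missing columns: {missing}")
    if table["patient_id"].duplicated().any():
        raise DomainError("patient_id values must be unique")
    bad_loc = set(table["occlusion_location"]) - set(OCCLUSION_LOCATIONS)
    if bad_loc:
        raise DomainError(f"unknown occlusion locations: {sorted(bad_loc)}")
    for col in ("odacs_ratio", "mca_ratio"):
        vals = table[col].dropna()
        if (vals < 0).any():
            raise DomainError(f"{col} contains negative values")
    for col in ("odacs_category", "mca_category"):
        vals = table[col].dropna()
        if not vals.isin(TAN_LEVELS).all():
            raise DomainError(f"{col} contains values outside {TAN_LEVELS}")


def _subset_analysis(sub: pd.DataFrame, rater_cols: list[str]) -> dict[str, Any]:
    out: dict[str, Any] = {"n": int(len(sub))}
    out["quantitative_odacs"] = _median_iqr(sub["odacs_ratio"].tolist())
    out["quantitative_mca"] = _median_iqr(sub["mca_ratio"].tolist())
    out["categorical_odacs"] = _median_iqr(sub["odacs_category"].tolist())
    out["categorical_mca"] = _median_iqr(sub["mca_category"].tolist())

    mca = sub["mca_ratio"].tolist()
    oda = sub["odacs_ratio"].tolist()
    defined_x, defined_y, _ = _paired_defined(mca, oda)
    if len(defined_x) >= 2:
        mean_diff, lo, hi, _, _ = bland_altman(mca, oda)  # difference = MCA-CS - ODACS
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateStatisticWarning)
            stat, p = wilcoxon_one_sided(oda, mca, alternative="less")
        out["bland_altman"] = {
            "mean_difference": mean_diff, "loa_low": lo, "loa_high": hi,
            "n": len(defined_x),
        }
        out["wilcoxon_odacs_less_than_mca"] = {
            "statistic": None if math.isnan(stat) else stat,
            "p_value": None if math.isnan(p) else p,
        }
    else:
        out["bland_altman"] = None
        out["wilcoxon_odacs_less_than_mca"] = None

    try:
        num, den, frac = shift_proportion(
            sub["mca_category"].tolist(), sub["odacs_category"].tolist()
        )
        out["shift_good_to_poor"] = {"numerator": num, "denominator": den, "fraction": frac}
    except DomainError:
        out["shift_good_to_poor"] = None

    agreements: dict[str, Any] = {}
    pairs = [("odacs", "odacs_category"), ("mca", "mca_category")]
    pairs += [(c.removeprefix("rater_"), c) for c in rater_cols]
    for i, (name_a, col_a) in enumerate(pairs):
        for name_b, col_b in pairs[i + 1:]:
            a, b, _ = _paired_defined(sub[col_a].tolist(), sub[col_b].tolist())
            if len(a) >= 2:
                agreements[f"{name_a}_vs_{name_b}"] = agreement_report(a, b).to_dict()
    out["agreement"] = agreements
    return out


def cohort_analysis(table: pd.DataFrame) -> dict[str, Any]:
    """Per-occlusion-location and overall comparison of ODACS vs MCA-CS.

    For each group: median (IQR) of quantitative and categorical scores,
    Bland-Altman of (MCA-CS - ODACS), a one-sided Wilcoxon signed-rank test
    of ODACS < MCA-CS, the good -> poor shift proportion, and quadratically
    weighted kappa agreements (including any ``rater_*`` columns present).
    Groups with fewer than two patients get their inferential statistics
    flagged as undefined (null).
    """
    validate_cohort_table(table)
    rater_cols = sorted(c for c in table.columns if c.startswith("rater_"))
    report: dict[str, Any] = {"overall": _subset_analysis(table, rater_cols)}
    for loc in OCCLUSION_LOCATIONS:
        sub = table[table["occlusion_location"] == loc]
        report[loc] = _subset_analysis(sub, rater_cols) if len(sub) > 0 else None
    return report
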