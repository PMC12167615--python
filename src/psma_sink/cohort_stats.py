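"""Cohort-level statistics: summaries, Spearman correlations, TLV strata.

The analysis mirrors how tumour-sink studies report their cohorts: median
and interquartile range per organ, tie-corrected Spearman rank correlations
of tumour burden (TLV, TLU) against organ-at-risk SUVmean with a two-tailed
significance test, stratification of patients into six TLV groups, and
scatter data with burden logarithmized after adding 1 (visualization only —
the rank correlation is invariant under that transform).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .voi_placement import ORGANS

#: Cohort-table column holding each organ's sphere SUVmean.
ORGAN_COLUMNS = {o: f"suv_{o}" for o in ORGANS}


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with a two-tailed p-value over n complete pairs.

    ``p`` is None (and ``note`` set) when rho is undefined, e.g. for a
    constant input vector.
    """

    rho: float
    p: float | None
    n: int
    note: str | None = None


@dataclass(frozen=True)
class StratificationScheme:
    """Six TLV groups: zero, then half-open intervals (a, b] in cm^3.

    Default cut-offs 25 / 189 / 532 / 1355 cm^3 follow the convention used in
    tumour-sink PET studies, enabling cross-study comparison.
    """

    upper_bounds: tuple[float, ...] = (25.0, 189.0, 532.0, 1355.0)
    labels: tuple[str, ...] = ("zero", "very_low", "low", "moderate",
                               "high", "very_high")

    def __post_init__(self) -> None:
        if list(self.upper_bounds) != sorted(set(self.upper_bounds)):
            raise ValueError("bounds must be strictly increasing")
        if len(self.labels) != len(self.upper_bounds) + 2:
            raise ValueError("need one label per interval plus zero and top")


DEFAULT_SCHEME = StratificationScheme()


def spearman(x, y) -> CorrelationResult:
    """Tie-corrected Spearman correlation with a two-tailed t-test p-value.

    Pairs with a missing value in either vector are removed first.  rho is
    the Pearson correlation of average ranks; significance uses the
    t-approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of
    freedom (for small n an exact permutation p is available via
    :func:`spearman_exact_p`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), None, n, "constant input")
    rx = sps.rankdata(x)  # average ranks handle ties
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return CorrelationResult(rho, 0.0, n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, min(p, 1.0), n)


def spearman_exact_p(x, y, max_n: int = 8) -> float:
    """Exact two-tailed permutation p-value for Spearman rho (small n).

    Enumerates all n! pairings of y against x and counts |rho| at least as
    extreme as observed (within 1e-12 to absorb floating error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > max_n:
        raise ValueError(f"exact permutation p limited to n <= {max_n}")
    obs = abs(spearman(x, y).rho)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def stratify(tlv: float, scheme: StratificationScheme = DEFAULT_SCHEME) -> str:
    """Assign a TLV (cm^3) to its stratum label.

    0 maps to "zero"; positive values fall into half-open intervals
    (lower, upper], so a value exactly at a cut-off belongs to the lower
    group.
    """
    if not np.isfinite(tlv) or tlv < 0:
        raise ValueError("TLV must be finite and non-negative")
    if tlv == 0:
        return scheme.labels[0]
    idx = int(np.searchsorted(np.asarray(scheme.upper_bounds), tlv,
                              side="left"))
    return scheme.labels[1 + idx]


def stratify_series(tlv, scheme: StratificationScheme = DEFAULT_SCHEME) -> pd.Series:
    s = pd.Series(tlv)
    return s.map(lambda v: stratify(float(v), scheme))


def log1_transform(v, base: float = 10.0) -> np.ndarray:
    """Elementwise log_base(v + 1); requires v >= 0 so 0 maps to 0."""
    v = np.asarray(v, dtype=float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("log1 transform requires non-negative values")
    return np.log(v + 1.0) / np.log(base)


def summarize(v) -> dict:
    """Median / quartiles / IQR / range of a vector (linear interpolation).

    Quartiles use linear interpolation between order statistics (type 7),
    the convention recorded in the report metadata.
    """
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("summarize requires a non-empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"n": int(v.size), "median": float(med), "q1": float(q1),
            "q3": float(q3), "iqr": float(q3 - q1),
            "min": float(v.min()), "max": float(v.max())}


def run_cohort_analysis(table: pd.DataFrame, include_zero_tlv: bool = True,
                        scheme: StratificationScheme = DEFAULT_SCHEME,
                        log_base: float = 10.0) -> dict:
    """Full cohort report from a per-patient table.

    Expects columns ``tlv_cm3``, ``tlu`` and ``suv_<organ>`` for each organ
    at risk (missing organs allowed as NaN; an organ absent in every row is
    omitted with a warning).  Emits per-organ median/IQR summaries, the
    eight Spearman correlations ({TLV, TLU} x four organs), per-stratum
    counts and five-number SUVmean summaries, and scatter data with raw and
    log(x+1) burden axes.

    ``include_zero_tlv`` controls whether patients without lesions enter the
    correlations (they do by default; the zero ties are handled by average
    ranks).
    """
    if len(table) < 3:
        raise ValueError("cohort analysis requires at least 3 patients")
    df = table.copy()
    organs = []
    for organ, col in ORGAN_COLUMNS.items():
        if col not in df.columns or df[col].notna().sum() == 0:
            warnings.warn(f"organ {organ!r} absent from cohort; omitted")
            continue
        organs.append(organ)

    report: dict = {
        "n_patients": int(len(df)),
        "metadata": {
            "quartile_method": "linear interpolation (type 7)",
            "correlation": "Spearman (average ranks), two-tailed t-test",
            "correlation_population": ("all patients" if include_zero_tlv
                                        else "TLV > 0 only"),
            "log_base": log_base,
        },
    }

    report["organ_summaries"] = {
        o: summarize(df[ORGAN_COLUMNS[o]].dropna()) for o in organs}
    for key in ("tlv_cm3", "tlu", "pct_injected"):
        if key in df.columns:
            report.setdefault("burden_summaries", {})[key] = summarize(
                df[key].dropna())

    sub = df if include_zero_tlv else df[df["tlv_cm3"] > 0]
    correlations = []
    for burden_col in ("tlv_cm3", "tlu"):
        for o in organs:
            r = spearman(sub[burden_col], sub[ORGAN_COLUMNS[o]])
            correlations.append({
                "burden": burden_col, "organ": o, "rho": r.rho,
                "p": r.p, "n": r.n, "note": r.note})
    report["correlations"] = correlations

    if "tlv_group" in df.columns:
        groups = df["tlv_group"]
    else:
        groups = stratify_series(df["tlv_cm3"], scheme)
    strata = {}
    for label in scheme.labels:
        in_group = groups == label
        entry: dict = {"n": int(in_group.sum())}
        if entry["n"] > 0:
            entry["organs"] = {
                o: summarize(df.loc[in_group, ORGAN_COLUMNS[o]].dropna())
                for o in organs
                if df.loc[in_group, ORGAN_COLUMNS[o]].notna().any()}
        strata[label] = entry
    report["strata"] = strata

    scatter = {"tlv_cm3": df["tlv_cm3"].tolist(),
               "log_tlv": log1_transform(df["tlv_cm3"], log_base).tolist(),
               "tlu": df["tlu"].tolist(),
               "log_tlu": log1_transform(df["tlu"], log_base).tolist()}
    for o in organs:
        scatter[ORGAN_COLUMNS[o]] = df[ORGAN_COLUMNS[o]].tolist()
    report["scatter"] = scatter
    return report
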