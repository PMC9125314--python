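"""Group comparisons and correlation-structure analyses of demographics and
rumination subscale scores.

The Ruminative Responses Scale (RRS) has 22 items on a 1–4 Likert scale,
split into depressive (RRS-D, 12 items), brooding (RRS-B, 5) and reflective
(RRS-R, 5) subscales; subscale sums therefore live in [12, 48], [5, 20] and
[5, 20].  Gender contingency is tested with a Pearson chi-square (df = 1, no
continuity correction); continuous variables with a two-sided permutation
test on the difference of means; the within-group subscale structure with
Pearson correlation matrices; and pairs of independent correlations with the
Fisher z-transform, z = atanh(r), using the normal approximation with
variance 1/(n−3) per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgumentError

__all__ = [
    "CorrelationComparison",
    "chi_square_2x2",
    "permutation_mean_test",
    "pearson_corr_matrix",
    "fisher_z_compare",
    "validate_subject_table",
    "rrs_percentages",
    "demographics_table",
    "subscale_comparison_table",
]

RRS_COLUMNS = ("rrs_d", "rrs_b", "rrs_r")


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z1: float
    z2: float
    z_stat: float
    p_one_tailed: float


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on [[a, b], [c, d]], df = 1, no continuity correction."""
    for v in (a, b, c, d):
        if v < 0:
            raise InvalidArgumentError("counts must be nonnegative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise InvalidArgumentError("degenerate 2×2 table (zero margin)")
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def permutation_mean_test(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation P for the difference of means under label shuffling.

    Falls back to complete enumeration when the number of distinct splits is at
    most ``n_perm`` (then P is exact, including the observed split); otherwise
    Monte Carlo with P = (b + 1)/(n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    obs = abs(x.mean() - y.mean())
    n_distinct = comb(n, n1)
    tot = pooled.sum()
    if n_distinct <= n_perm:
        b = 0
        for pick in itertools.combinations(range(n), n1):
            m1 = pooled[list(pick)].sum() / n1
            m2 = (tot - m1 * n1) / (n - n1)
            if abs(m1 - m2) >= obs - 1e-12:
                b += 1
        return b / n_distinct
    rng = np.random.default_rng(seed)
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    m1 = pooled[picks].sum(axis=1) / n1
    m2 = (tot - m1 * n1) / (n - n1)
    b = int(np.sum(np.abs(m1 - m2) >= obs - 1e-12))
    return (b + 1) / (n_perm + 1)


def pearson_corr_matrix(tbl: pd.DataFrame, columns=RRS_COLUMNS,
                        by_group: str | None = "group"):
    """Per-group Pearson correlation matrices with two-sided P values.

    Returns ``{group: (r_matrix, p_matrix)}`` as DataFrames; a constant column
    yields NaN (flagged undefined) in its entries.
    """
    def one(frame: pd.DataFrame):
        sub = frame[list(columns)].astype(float)
        n = len(sub)
        if n < 4:
            raise InvalidArgumentError("need n ≥ 4 per group")
        r = sub.corr(method="pearson")  # constant columns give NaN
        dfree = n - 2
        rv = r.to_numpy(copy=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rv * np.sqrt(dfree / (1 - rv**2))
        p = 2 * stats.t.sf(np.abs(t), dfree)
        p[np.abs(rv) >= 1.0] = 0.0
        np.fill_diagonal(p, 0.0)
        p[np.isnan(rv)] = np.nan
        return r, pd.DataFrame(p, index=r.index, columns=r.columns)

    if by_group is None:
        return {"all": one(tbl)}
    return {g: one(frame) for g, frame in tbl.groupby(by_group, observed=True)}


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent Pearson correlations via Fisher's z.

    z_i = atanh(r_i); the test statistic is
    (z1 − z2)/√(1/(n1−3) + 1/(n2−3)) and the one-tailed P is the standard
    normal upper-tail probability of |z_stat| (0.5 when r1 = r2).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise InvalidArgumentError("|r| must be < 1")
    if n1 < 4 or n2 < 4:
        raise InvalidArgumentError("need n ≥ 4 in both samples")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = float(stats.norm.sf(abs(z_stat)))
    return CorrelationComparison(r1, r2, n1, n2, float(z1), float(z2),
                                 float(z_stat), p)


# ---------------------------------------------------------------------------
# Subject-table utilities

def validate_subject_table(tbl: pd.DataFrame) -> None:
    """Check Likert ranges and the rrs_total identity."""
    ranges = {"rrs_d": (12, 48), "rrs_b": (5, 20), "rrs_r": (5, 20)}
    for col, (lo, hi) in ranges.items():
        v = tbl[col].dropna()
        if ((v < lo) | (v > hi)).any():
            raise InvalidArgumentError(f"{col} outside Likert range [{lo}, {hi}]")
    if "rrs_total" in tbl:
        total = tbl[["rrs_d", "rrs_b", "rrs_r"]].sum(axis=1)
        mismatch = tbl["rrs_total"].notna() & (tbl["rrs_total"] != total)
        if mismatch.any():
            raise InvalidArgumentError("rrs_total ≠ rrs_d + rrs_b + rrs_r")


def rrs_percentages(tbl: pd.DataFrame) -> pd.DataFrame:
    """Subscale percentages: subscale sum / total sum × 100 (an assumption —
    the denominator of published subscale percentages is not defined)."""
    out = tbl.copy()
    total = out[["rrs_d", "rrs_b", "rrs_r"]].sum(axis=1).astype(float)
    for col in RRS_COLUMNS:
        out[col + "_pct"] = out[col].astype(float) / total * 100.0
    return out


def demographics_table(tbl: pd.DataFrame, n_perm: int = 10000,
                       seed: int = 0) -> pd.DataFrame:
    """Per-group mean ± SEM of the continuous variables plus group-difference
    P values (permutation test; chi-square for gender)."""
    tbl = rrs_percentages(tbl)
    groups = [g for g in ("MDD", "HC") if (tbl["group"] == g).any()]
    rows = []
    cont = ["age", "education", "hdrs", "rrs_total",
            "rrs_d_pct", "rrs_b_pct", "rrs_r_pct"]
    for var in cont:
        if var not in tbl:
            continue
        row = {"variable": var}
        vals = {}
        for g in groups:
            v = tbl.loc[tbl["group"] == g, var].dropna().astype(float).to_numpy()
            vals[g] = v
            row[f"{g}_mean"] = v.mean() if v.size else np.nan
            row[f"{g}_sem"] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        if len(groups) == 2 and all(v.size for v in vals.values()):
            row["p"] = permutation_mean_test(vals[groups[0]], vals[groups[1]],
                                            n_perm=n_perm, seed=seed)
        rows.append(row)
    if len(groups) == 2 and "gender" in tbl:
        cts = {
            g: (
                int(((tbl["group"] == g) & (tbl["gender"] == "man")).sum()),
                int(((tbl["group"] == g) & (tbl["gender"] == "woman")).sum()),
            )
            for g in groups
        }
        a, b = cts[groups[0]]
        c, d = cts[groups[1]]
        try:
            _, p = chi_square_2x2(a, b, c, d)
        except InvalidArgumentError:
            p = np.nan
        rows.append({"variable": "gender_men_women",
                     f"{groups[0]}_mean": a, f"{groups[0]}_sem": b,
                     f"{groups[1]}_mean": c, f"{groups[1]}_sem": d, "p": p})
    return pd.DataFrame(rows)


def subscale_comparison_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Groupwise subscale correlations plus Fisher-z comparison P values."""
    mats = pearson_corr_matrix(tbl)
    if not {"MDD", "HC"} <= set(mats):
        raise InvalidArgumentError("need both MDD and HC groups")
    n = {g: int((tbl["group"] == g).sum()) for g in ("MDD", "HC")}
    rows = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        a, b = RRS_COLUMNS[i], RRS_COLUMNS[j]
        r_mdd = float(mats["MDD"][0].loc[a, b])
        r_hc = float(mats["HC"][0].loc[a, b])
        cmpres = fisher_z_compare(r_mdd, n["MDD"], r_hc, n["HC"])
        rows.append(dict(pair=f"{a}~{b}", r_mdd=r_mdd, p_mdd=float(mats["MDD"][1].loc[a, b]),
                         r_hc=r_hc, p_hc=float(mats["HC"][1].loc[a, b]),
                         p_one_tailed=cmpres.p_one_tailed))
    return pd.DataFrame(rows)
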