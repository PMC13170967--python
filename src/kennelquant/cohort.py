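"""Cohort-level descriptive and inferential statistics.

Prevalence of binary clinical status per breed (one status per dog,
first available grade by default), odds ratios from logistic
regression with Wald confidence intervals, parent-offspring regression
heritability, testing-rate and litter summaries, and grade-progression
counts for repeatedly tested dogs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pedigree import Pedigree


@dataclass
class OddsRatioResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    reference: str = ""
    separation: bool = False


@dataclass
class MidparentResult:
    slope: float
    se: float
    h2: float
    h2_se: float
    n_pairs: int
    mode: str  # "midparent" | "single_parent"


def first_record_per_dog(records: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """First available value per dog, by test date then input order."""
    df = records.copy()
    if "test_date" in df.columns:
        df = df.sort_values(["dog_id", "test_date"], kind="stable")
    return df.groupby("dog_id")[value_col].first()


def prevalence(
    records: pd.DataFrame,
    status_rule,
    group_col: str | None = None,
    per_dog: bool = True,
) -> pd.DataFrame:
    """Share of positive dogs, overall or per group.

    ``status_rule`` maps raw values to a boolean vector (e.g.
    :func:`kennelquant.liability.to_boas_status`). With ``per_dog`` the
    first record per dog defines its status (records-based prevalence
    is available by switching it off).
    """
    df = records.copy()
    if per_dog:
        keys = [group_col] if group_col else []
        if "test_date" in df.columns:
            df = df.sort_values(["dog_id", "test_date"], kind="stable")
        df = df.groupby(["dog_id"] + keys, as_index=False).first()
    status = np.asarray(status_rule(df["value"].to_numpy()))
    df = df.assign(_pos=status)
    if group_col is None:
        return pd.DataFrame(
            {"group": ["all"], "n": [len(df)], "n_pos": [int(status.sum())],
             "prevalence": [float(status.mean()) if len(df) else np.nan]}
        )
    rows = []
    for g, sub in df.groupby(group_col):
        if len(sub) == 0:
            continue
        rows.append(
            {"group": g, "n": len(sub), "n_pos": int(sub["_pos"].sum()),
             "prevalence": float(sub["_pos"].mean())}
        )
    return pd.DataFrame(rows)


def logistic_or(
    outcome,
    predictors: pd.DataFrame,
    reference_levels: dict | None = None,
) -> list[OddsRatioResult]:
    """Odds ratios by logistic regression (binomial error, logit link).

    Categorical predictor columns are dummy-coded against the given (or
    first) reference level; numeric columns enter as-is. Wald 95% CIs
    come from exponentiating estimate +- 1.96 SE. Complete separation
    is detected and flagged with an infinite OR rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    reference_levels = reference_levels or {}
    cols, names, refs = [], [], []
    for name in predictors.columns:
        col = predictors[name]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            vals = col.astype(str)
            levels = sorted(vals.unique())
            ref = str(reference_levels.get(name, levels[0]))
            for lev in levels:
                if lev != ref:
                    cols.append((vals == lev).to_numpy(dtype=float))
                    names.append(f"{name}[{lev}]")
                    refs.append(ref)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
            refs.append("")
    X = sm.add_constant(np.column_stack(cols))

    # separation check: a predictor level perfectly determines the outcome
    separated = []
    for j, c in enumerate(cols):
        if len(np.unique(c)) <= 2:
            for v in np.unique(c):
                ys = y[c == v]
                if len(ys) and (ys.min() == ys.max()) and len(np.unique(y)) > 1:
                    separated.append(j)
    separated = sorted(set(separated))

    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params, ses, pvals = res.params[1:], res.bse[1:], res.pvalues[1:]
    except Exception:
        params = np.full(len(cols), np.nan)
        ses = np.full(len(cols), np.inf)
        pvals = np.full(len(cols), np.nan)
    out = []
    for j, name in enumerate(names):
        if j in separated or not np.isfinite(ses[j]) or ses[j] > 1e3:
            out.append(
                OddsRatioResult(name, float(np.inf), 0.0, float(np.inf), np.nan,
                                refs[j], separation=True)
            )
        else:
            b, s = params[j], ses[j]
            out.append(
                OddsRatioResult(
                    name, float(np.exp(b)), float(np.exp(b - 1.96 * s)),
                    float(np.exp(b + 1.96 * s)), float(pvals[j]), refs[j]
                )
            )
    return out


def midparent_regression(
    offspring: np.ndarray, parent_values: np.ndarray, mode: str = "midparent"
) -> MidparentResult:
    """Parent-offspring regression heritability.

    In midparent mode ``parent_values`` holds both parents' values
    (n x 2) and h2 equals the slope of offspring on midparent mean; in
    single-parent mode it is one value per pair and h2 is twice the
    slope. Requires at least 10 complete pairs.
    """
    offspring = np.asarray(offspring, dtype=float)
    pv = np.atleast_2d(np.asarray(parent_values, dtype=float))
    if pv.shape[0] == 1 and offspring.size > 1:
        pv = pv.T
    x = pv.mean(axis=1) if mode == "midparent" else pv.ravel()
    ok = np.isfinite(offspring) & np.isfinite(x)
    x, yv = x[ok], offspring[ok]
    if len(yv) < 10:
        raise ValueError(f"need >= 10 complete pairs, got {len(yv)}")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    dof = len(yv) - 2
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    slope, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    mult = 1.0 if mode == "midparent" else 2.0
    return MidparentResult(slope, se, mult * slope, mult * se, len(yv), mode)


def grade_progression(records: pd.DataFrame) -> dict:
    """First-versus-last grade comparison for dogs with repeated tests.

    Returns counts of improved/same/worsened, the number of
    single-record dogs (excluded from progression), and the day gaps
    between first and last test where dates are available.
    """
    df = records.sort_values(["dog_id", "test_date"], kind="stable")
    improved = same = worsened = 0
    single = 0
    gaps = []
    for _, sub in df.groupby("dog_id"):
        if len(sub) < 2:
            single += 1
            continue
        first, last = sub["value"].iloc[0], sub["value"].iloc[-1]
        if last < first:
            improved += 1
        elif last > first:
            worsened += 1
        else:
            same += 1
        try:
            d0 = pd.to_datetime(sub["test_date"].iloc[0])
            d1 = pd.to_datetime(sub["test_date"].iloc[-1])
            gaps.append((d1 - d0).days)
        except Exception:
            pass
    return {
        "improved": improved,
        "same": same,
        "worsened": worsened,
        "tested_once": single,
        "mean_gap_days": float(np.mean(gaps)) if gaps else np.nan,
        "sd_gap_days": float(np.std(gaps, ddof=1)) if len(gaps) > 1 else np.nan,
    }


def testing_and_litter_summaries(
    ped: Pedigree, records: pd.DataFrame, registered_only: bool = False
) -> dict:
    """Testing rates by year of birth, litter and sire summaries, and the
    breeding-versus-non-breeding grade contrast.

    A litter is a unique (sire, dam, date of birth) triple; breeding
    dogs are those appearing as a parent of any pedigree record. The
    litters-per-sire contrast between tested and untested sires uses a
    Welch two-sample t-test; the breeding contrast compares mean first
    available grades.
    """
    tested = set(records["dog_id"])
    recs = ped.records
    if registered_only:
        recs = [r for r in recs if r.registration]
    by_year: dict[int, list[int]] = {}
    for r in recs:
        if r.dob is not None:
            by_year.setdefault(r.dob.year, []).append(1 if r.id in tested else 0)
    testing_rate = {
        y: float(np.mean(v)) for y, v in sorted(by_year.items())
    }

    litters: dict[tuple, int] = {}
    for r in recs:
        if r.sire_id or r.dam_id:
            key = (r.sire_id, r.dam_id, r.dob)
            litters[key] = litters.get(key, 0) + 1
    litter_keys = list(litters)
    either = [k for k in litter_keys if (k[0] in tested) or (k[1] in tested)]
    both = [k for k in litter_keys if (k[0] in tested) and (k[1] in tested)]
    n_litters = len(litter_keys)

    sire_litters: dict[str, int] = {}
    for s, _, _ in litter_keys:
        if s is not None:
            sire_litters[s] = sire_litters.get(s, 0) + 1
    tested_counts = [c for s, c in sire_litters.items() if s in tested]
    untested_counts = [c for s, c in sire_litters.items() if s not in tested]
    if len(tested_counts) > 1 and len(untested_counts) > 1:
        tt = stats.ttest_ind(tested_counts, untested_counts, equal_var=False)
        litters_p = float(tt.pvalue)
    else:
        litters_p = np.nan

    first = first_record_per_dog(records)
    breeders = {r.sire_id for r in recs if r.sire_id} | {r.dam_id for r in recs if r.dam_id}
    grade_breeding = [v for d, v in first.items() if d in breeders]
    grade_nonbreeding = [v for d, v in first.items() if d not in breeders]

    return {
        "testing_rate_by_yob": testing_rate,
        "n_litters": n_litters,
        "pct_litters_either_parent_tested": 100.0 * len(either) / n_litters if n_litters else np.nan,
        "pct_litters_both_parents_tested": 100.0 * len(both) / n_litters if n_litters else np.nan,
        "mean_litters_tested_sire": float(np.mean(tested_counts)) if tested_counts else np.nan,
        "mean_litters_untested_sire": float(np.mean(untested_counts)) if untested_counts else np.nan,
        "litters_per_sire_welch_p": litters_p,
        "mean_first_grade_breeding": float(np.mean(grade_breeding)) if grade_breeding else np.nan,
        "mean_first_grade_nonbreeding": float(np.mean(grade_nonbreeding)) if grade_nonbreeding else np.nan,
    }
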