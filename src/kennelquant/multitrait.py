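"""Multivariate animal model: covariance matrices and trait correlations.

Stacks the trait-specific univariate designs into one system with

    u_additive ~ N(0, G (x) A),   u_assessor ~ N(0, C (x) I),
    e ~ N(0, block-diag R per test event),

where G, C and R are additive-genetic, assessor and residual
(co)variance matrices across traits. Permanent-environment effects stay
trait-specific (no cross-trait pe covariances) and are fitted only for
the traits where the univariate analysis retained them. Records missing
one trait simply contribute a smaller residual block for their event.

Genetic correlations are G off-diagonals scaled by the diagonal, tested
by a boundary likelihood-ratio test against a model with that
covariance pinned at zero; phenotypic correlations are

    r_P = (sigma_a_ij + sigma_e_ij)
          / sqrt((sigma_a_i^2 + sigma_pe_i^2 + sigma_e_i^2) *
                 (sigma_a_j^2 + sigma_pe_j^2 + sigma_e_j^2)),

with delta-method standard errors, tested by the exact-t Fisher test
with n = the number of test events at which both traits were recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import t as t_dist

from .animal_model import ModelSpec, spline_basis
from .mixedmodel import FactorBlock, FitResult, MixedModel
from .pedigree import Pedigree, a_log_determinant, build_a_inverse


@dataclass
class CovarianceStructures:
    traits: list
    G: np.ndarray
    C: np.ndarray
    R: np.ndarray
    pe_variances: dict  # trait -> sigma_pe^2 (traits without pe absent)
    se: dict  # "G"/"C"/"R" -> elementwise SE matrices
    loglik: float
    converged: bool
    fit: FitResult
    model: MixedModel
    n_joint: np.ndarray  # events with both traits recorded, per pair
    unstable: bool = False


@dataclass
class CorrelationEstimate:
    kind: str  # genetic | residual | assessor | phenotypic
    traits: tuple
    value: float
    se: float
    p: float
    n_joint: int = 0
    test: str = ""
    unstable: bool = False


def _stacked_design(
    records: pd.DataFrame,
    ped: Pedigree,
    traits: list,
    specs: dict,
    pe_traits: set,
    response: str = "value",
):
    """Assemble y, X and factor blocks for the stacked multitrait system."""
    recs = records[records["trait"].isin(traits)].reset_index(drop=True)
    n = len(recs)
    trait_of = np.array([traits.index(t) for t in recs["trait"]])
    unknown = [d for d in recs["dog_id"] if d not in ped]
    if unknown:
        raise ValueError(f"records for dogs absent from pedigree: {sorted(set(unknown))[:5]}")
    y = recs[response].to_numpy(dtype=float)

    # events: one test occasion = one dog on one date
    ev_key = recs["dog_id"].astype(str) + "@" + recs["test_date"].astype(str)
    event_id = pd.factorize(ev_key)[0]

    # trait-specific fixed designs on the stacked rows
    x_cols, x_names = [], []
    for ti, trait in enumerate(traits):
        spec = specs[trait]
        mask = trait_of == ti
        rows = np.where(mask)[0]
        sub = recs.loc[mask]
        cols = [np.ones(len(rows))]
        names = [f"{trait}:intercept"]
        cols.append((sub["sex"].astype(str) == "female").to_numpy(dtype=float))
        names.append(f"{trait}:sex_female")
        age = sub["age_days"].to_numpy(dtype=float)
        sd = age.std(ddof=1)
        cols.append((age - age.mean()) / sd if sd > 0 else age - age.mean())
        names.append(f"{trait}:age_scaled")
        for term in spec.fixed:
            vals = sub[term].astype(str)
            levels = sorted(vals.unique())
            ref = "BS" if term == "colour_group" and "BS" in levels else levels[0]
            for lev in levels:
                if lev != ref:
                    cols.append((vals == lev).to_numpy(dtype=float))
                    names.append(f"{trait}:{term}_{lev}")
        for cov in spec.covariates:
            v = sub[cov].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
            names.append(f"{trait}:{cov}")
        for j, (c, nm) in enumerate(zip(cols, names)):
            if j > 0 and np.ptp(c) == 0:
                continue  # degenerate column (single-sex data etc.)
            full = np.zeros(n)
            full[rows] = c
            x_cols.append(full)
            x_names.append(nm)
    X = np.column_stack(x_cols)

    factors = []
    n_ped = len(ped)
    animal_pos = np.array([ped.index[d] for d in recs["dog_id"]])
    Za = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), trait_of * n_ped + animal_pos)),
        shape=(n, len(traits) * n_ped),
    )
    factors.append(
        FactorBlock("additive", Za, n_ped, len(traits), build_a_inverse(ped), a_log_determinant(ped))
    )

    for ti, trait in enumerate(traits):
        if trait not in pe_traits:
            continue
        mask = trait_of == ti
        dogs = sorted(set(recs.loc[mask, "dog_id"]))
        dmap = {d: i for i, d in enumerate(dogs)}
        rows = np.where(mask)[0]
        Zpe = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, [dmap[d] for d in recs.loc[mask, "dog_id"]])),
            shape=(n, len(dogs)),
        )
        factors.append(FactorBlock(f"pe_{trait}", Zpe, len(dogs)))

    raw = recs.get("assessor", pd.Series([""] * n)).fillna("").astype(str)
    levels = sorted({a for a in raw if a.strip()})
    amap = {a: i for i, a in enumerate(levels)}
    idx = np.empty(n, dtype=int)
    nxt = len(levels)
    for i, a in enumerate(raw):
        if a.strip():
            idx[i] = amap[a]
        else:
            levels.append(f"_dummy_{i}")
            idx[i] = nxt
            nxt += 1
    q_as = len(levels)
    Zas = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), trait_of * q_as + idx)), shape=(n, len(traits) * q_as)
    )
    factors.append(FactorBlock("assessor", Zas, q_as, len(traits)))

    for ti, trait in enumerate(traits):
        spec = specs[trait]
        mask = trait_of == ti
        age = recs.loc[mask, "age_days"].to_numpy(dtype=float)
        n_distinct = len(np.unique(age))
        knots = spec.spline_knots if spec.spline_knots is not None else min(50, max(n_distinct - 2, 0))
        if knots >= 1 and n_distinct >= knots + 2:
            S = spline_basis(age, knots)
            rows = np.where(mask)[0]
            full = np.zeros((n, S.shape[1]))
            full[rows] = S
            factors.append(FactorBlock(f"spline_{trait}", sparse.csr_matrix(full), S.shape[1]))

    return recs, y, X, x_names, factors, trait_of, event_id


def multitrait_reml(
    records: pd.DataFrame,
    ped: Pedigree,
    traits: list,
    specs: dict | None = None,
    pe_traits: set | None = None,
    response: str = "value",
    max_iter: int = 100,
) -> CovarianceStructures:
    """Fit the multivariate model by AI-REML and return G, C, R.

    ``records`` is long format with a ``trait`` column; ``specs`` maps
    trait name to its univariately finalized :class:`ModelSpec`;
    ``pe_traits`` lists the traits whose permanent-environment term was
    univariately significant.
    """
    specs = specs or {t: ModelSpec() for t in traits}
    pe_traits = set(pe_traits or ())
    recs, y, X, x_names, factors, trait_of, event_id = _stacked_design(
        records, ped, traits, specs, pe_traits, response
    )
    mm = MixedModel(y, X, factors, obs_trait=trait_of, event_id=event_id, n_traits=len(traits))
    res = mm.fit_reml(max_iter=max_iter)
    t = len(traits)
    n_joint = np.zeros((t, t), dtype=int)
    for (a, b), (ra, _) in mm._em_rows.items():
        n_joint[a, b] = n_joint[b, a] = len(ra)
    pe = {tr: float(res.theta[f"pe_{tr}"][0, 0]) for tr in traits if f"pe_{tr}" in res.theta}
    se = {
        "G": res.se["additive"],
        "C": res.se["assessor"],
        "R": res.se["residual"],
    }
    # unstable: non-convergence, or a genetic covariance whose information is
    # degenerate (zero SE from a singular AI matrix) or whose SE swamps the
    # corresponding variance product
    G = res.theta["additive"]
    iu = np.triu_indices(t, 1)
    gprod = np.sqrt(np.outer(np.diag(G), np.diag(G)))[iu]
    se_off = se["G"][iu]
    unstable = (not res.converged) or bool(
        t > 1 and np.any((se_off <= 0) | (se_off > 0.75 * np.maximum(gprod, 1e-12)))
    )
    return CovarianceStructures(
        traits=list(traits),
        G=res.theta["additive"],
        C=res.theta["assessor"],
        R=res.theta["residual"],
        pe_variances=pe,
        se=se,
        loglik=res.loglik,
        converged=res.converged,
        fit=res,
        model=mm,
        n_joint=n_joint,
        unstable=unstable,
    )


def _param_pos(fit: FitResult, name: str) -> int:
    return fit.param_names.index(name)


def _corr_delta_se(fit: FitResult, num_names, den_i_names, den_j_names, value) -> float:
    """Delta-method SE for r = num / sqrt(den_i * den_j) with each piece a
    sum of parameters."""
    names = fit.param_names
    cov = fit.param_cov
    num = sum(fit.param_values[names.index(n)] for n in num_names)
    den_i = sum(fit.param_values[names.index(n)] for n in den_i_names)
    den_j = sum(fit.param_values[names.index(n)] for n in den_j_names)
    g = np.zeros(len(names))
    for n in num_names:
        g[names.index(n)] += 1.0 / np.sqrt(den_i * den_j)
    for n in den_i_names:
        g[names.index(n)] += -0.5 * num / (den_i ** 1.5 * np.sqrt(den_j))
    for n in den_j_names:
        g[names.index(n)] += -0.5 * num / (np.sqrt(den_i) * den_j ** 1.5)
    return float(np.sqrt(max(g @ cov @ g, 0.0)))


def _covariance_lrt(structs: CovarianceStructures, param_name: str) -> float:
    """Boundary LRT p-value for one covariance pinned at zero."""
    from scipy.stats import chi2

    mm = structs.model
    pi = mm.param_index  # noqa: F841 (documented ordering)
    pos = structs.fit.param_names.index(param_name)
    res0 = mm.fit_reml(pinned={pos: 0.0})
    stat = max(0.0, 2.0 * (structs.loglik - res0.loglik))
    return float(chi2.sf(stat, df=1)) if stat > 0 else 1.0


def genetic_correlation(structs: CovarianceStructures, i: int, j: int, lrt: bool = True) -> CorrelationEstimate:
    """r_g between traits i and j from G, with delta-method SE and LRT p."""
    G = structs.G
    if G[i, i] <= 0 or G[j, j] <= 0:
        raise ValueError("zero genetic variance: correlation undefined")
    r = float(G[i, j] / np.sqrt(G[i, i] * G[j, j]))
    se = _corr_delta_se(
        structs.fit,
        [f"additive[{min(i,j)},{max(i,j)}]"],
        [f"additive[{i},{i}]"],
        [f"additive[{j},{j}]"],
        r,
    )
    p = _covariance_lrt(structs, f"additive[{min(i,j)},{max(i,j)}]") if lrt else np.nan
    return CorrelationEstimate(
        "genetic", (structs.traits[i], structs.traits[j]), r, se, p,
        n_joint=int(structs.n_joint[i, j]), test="lrt", unstable=structs.unstable,
    )


def residual_correlation(structs: CovarianceStructures, i: int, j: int, lrt: bool = True) -> CorrelationEstimate:
    R = structs.R
    r = float(R[i, j] / np.sqrt(R[i, i] * R[j, j]))
    se = _corr_delta_se(
        structs.fit,
        [f"residual[{min(i,j)},{max(i,j)}]"],
        [f"residual[{i},{i}]"],
        [f"residual[{j},{j}]"],
        r,
    )
    p = _covariance_lrt(structs, f"residual[{min(i,j)},{max(i,j)}]") if lrt else np.nan
    return CorrelationEstimate(
        "residual", (structs.traits[i], structs.traits[j]), r, se, p,
        n_joint=int(structs.n_joint[i, j]), test="lrt", unstable=structs.unstable,
    )


def assessor_correlation(structs: CovarianceStructures, i: int, j: int, lrt: bool = True) -> CorrelationEstimate:
    C = structs.C
    r = float(C[i, j] / np.sqrt(C[i, i] * C[j, j]))
    se = _corr_delta_se(
        structs.fit,
        [f"assessor[{min(i,j)},{max(i,j)}]"],
        [f"assessor[{i},{i}]"],
        [f"assessor[{j},{j}]"],
        r,
    )
    p = _covariance_lrt(structs, f"assessor[{min(i,j)},{max(i,j)}]") if lrt else np.nan
    return CorrelationEstimate(
        "assessor", (structs.traits[i], structs.traits[j]), r, se, p,
        n_joint=int(structs.n_joint[i, j]), test="lrt", unstable=structs.unstable,
    )


def fisher_correlation_test(r: float, n: int) -> tuple[float, float]:
    """Exact-t test for a correlation: t = r sqrt(n-2) / sqrt(1-r^2).

    Two-sided p from the t distribution with n-2 degrees of freedom.
    |r| = 1 gives an infinite statistic and p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(t), float(2 * t_dist.sf(abs(t), df=n - 2))


def phenotypic_correlation(structs: CovarianceStructures, i: int, j: int) -> CorrelationEstimate:
    """r_P from (G + R) off-diagonals over the per-trait phenotypic
    variances (pe variance included where fitted), Fisher-t tested."""
    ti, tj = structs.traits[i], structs.traits[j]
    num_names = [f"additive[{min(i,j)},{max(i,j)}]", f"residual[{min(i,j)},{max(i,j)}]"]
    den_i = [f"additive[{i},{i}]", f"residual[{i},{i}]"]
    den_j = [f"additive[{j},{j}]", f"residual[{j},{j}]"]
    names = structs.fit.param_names
    if f"pe_{ti}[0,0]" in names:
        den_i.append(f"pe_{ti}[0,0]")
    if f"pe_{tj}[0,0]" in names:
        den_j.append(f"pe_{tj}[0,0]")
    vals = structs.fit.param_values
    num = sum(vals[names.index(n)] for n in num_names)
    di = sum(vals[names.index(n)] for n in den_i)
    dj = sum(vals[names.index(n)] for n in den_j)
    if di <= 0 or dj <= 0:
        raise ValueError("non-positive phenotypic variance")
    r = float(num / np.sqrt(di * dj))
    se = _corr_delta_se(structs.fit, num_names, den_i, den_j, r)
    n_joint = int(structs.n_joint[i, j])
    _, p = fisher_correlation_test(r, max(n_joint, 3))
    return CorrelationEstimate(
        "phenotypic", (ti, tj), r, se, p, n_joint=n_joint, test="fisher-t",
        unstable=structs.unstable,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_report(structs: CovarianceStructures) -> pd.DataFrame:
    """All pairwise correlations of every kind as one tidy table."""
    rows = []
    t = len(structs.traits)
    for i in range(t):
        for j in range(i + 1, t):
            for fn in (genetic_correlation, residual_correlation, assessor_correlation):
                est = fn(structs, i, j)
                rows.append(est)
            rows.append(phenotypic_correlation(structs, i, j))
    return pd.DataFrame(
        {
            "kind": [e.kind for e in rows],
            "trait_i": [e.traits[0] for e in rows],
            "trait_j": [e.traits[1] for e in rows],
            "value": [e.value for e in rows],
            "se": [e.se for e in rows],
            "p": [e.p for e in rows],
            "test": [e.test for e in rows],
            "n_joint": [e.n_joint for e in rows],
            "stars": [significance_stars(e.p) for e in rows],
        }
    )
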