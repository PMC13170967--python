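"""Univariate pedigree animal model for liability-scale trait records.

The observation model is

    y = X beta + Z1 a + Z2 pe + Z3 as + f(age) + e,

with a ~ N(0, A sigma_a^2) the additive genetic effect over the
pedigree, pe ~ N(0, I sigma_pe^2) a per-dog permanent-environment
effect shared by repeated records, as ~ N(0, I sigma_as^2) an assessor
effect, f(age) a natural cubic spline fitted as a random smooth term,
and e ~ N(0, I sigma_e^2). Sex (male reference) and linear age are
always in the fixed part; further covariates (colour group with the
breed-standard colour as reference, show-breeding score, year of
birth/test, ordinal dates, inbreeding, obesity, body condition) are
optional and can be pruned by BIC backward elimination on
maximum-likelihood fits.

Heritability is sigma_a^2 over the phenotypic variance, where the
phenotypic variance is sigma_a^2 + sigma_e^2 plus sigma_pe^2 when the
permanent-environment term is fitted; the assessor and spline terms are
nuisance components and never enter the denominator. Repeatability is
(sigma_a^2 + sigma_pe^2) over the same denominator and is only defined
when the permanent-environment term is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import chi2, norm

from .mixedmodel import FactorBlock, FitResult, MixedModel
from .pedigree import Pedigree, a_log_determinant, build_a_inverse


@dataclass
class ModelSpec:
    """Declarative description of one univariate animal model.

    ``fixed`` are categorical effects (sex is mandatory and implied),
    ``covariates`` numeric columns (linear age is mandatory and
    implied), ``random`` the optional variance components beyond the
    always-present additive effect.
    """

    response: str = "value"
    fixed: list = field(default_factory=list)  # e.g. ["colour_group"]
    covariates: list = field(default_factory=list)  # e.g. ["f", "yob_centred"]
    random: set = field(default_factory=lambda: {"permanent_env", "assessor"})
    spline_knots: int | None = None  # interior knots; None -> min(50, distinct ages - 2)

    def without_fixed_term(self, term: str) -> "ModelSpec":
        return replace(
            self,
            fixed=[t for t in self.fixed if t != term],
            covariates=[t for t in self.covariates if t != term],
        )


@dataclass
class DesignSystem:
    """Assembled response, fixed design and incidence structures."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    factors: list  # FactorBlocks in engine order
    record_to_animal: np.ndarray  # pedigree positions per record
    pe_levels: list  # dog ids indexing the permanent-environment effect
    assessor_levels: list
    spline_dim: int
    n_records: int


def spline_basis(age: np.ndarray, knots: int) -> np.ndarray:
    """Natural cubic spline basis for a random smooth term in age.

    ``knots`` interior knots are placed at quantiles of the distinct
    ages, with boundary knots at the extremes. The natural-spline
    truncated-power basis is residualized against the intercept and
    linear age so the random smooth never absorbs the fixed linear
    trend, and columns are scaled to unit norm.
    """
    age = np.asarray(age, dtype=float)
    xs = np.unique(age)
    if len(xs) < knots + 2:
        raise ValueError(f"need at least {knots + 2} distinct ages for {knots} interior knots")
    qs = np.linspace(0, 1, knots + 2)[1:-1]
    interior = np.quantile(xs, qs, method="nearest")
    t = np.unique(np.concatenate([[xs[0]], interior, [xs[-1]]]))
    K = len(t)
    if K < 3:
        raise ValueError("degenerate knot sequence")

    def d(j: int, x: np.ndarray) -> np.ndarray:
        num = np.clip(x - t[j], 0, None) ** 3 - np.clip(x - t[K - 1], 0, None) ** 3
        return num / (t[K - 1] - t[j])

    cols = [d(j, age) - d(K - 2, age) for j in range(K - 2)]
    S = np.column_stack(cols)
    # residualize on [1, age]
    Q = np.column_stack([np.ones_like(age), age])
    S = S - Q @ np.linalg.lstsq(Q, S, rcond=None)[0]
    norms = np.linalg.norm(S, axis=0)
    keep = norms > 1e-10 * max(norms.max(), 1.0)
    # mean-square-one columns: the spline variance component then reads as
    # a per-record variance, comparable with the other components
    S = S[:, keep] / norms[keep] * np.sqrt(len(age))
    return S


def build_design(records: pd.DataFrame, ped: Pedigree, spec: ModelSpec) -> DesignSystem:
    """Build the fixed design and incidence matrices for ``records``.

    ``records`` needs columns ``dog_id``, the response column named by
    ``spec.response``, ``age_days``, optionally ``assessor`` (missing or
    empty assessors get a unique singleton level each, so they carry no
    information about the assessor variance), ``sex`` (taken from the
    pedigree when absent) and any column named in ``spec.fixed`` /
    ``spec.covariates``. Numeric covariates are centred and scaled here.
    """
    records = records.reset_index(drop=True)
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    unknown = [d for d in records["dog_id"] if d not in ped]
    if unknown:
        raise ValueError(f"records for dogs absent from pedigree: {sorted(set(unknown))[:5]}")

    y = records[spec.response].to_numpy(dtype=float)
    animal_pos = np.array([ped.index[d] for d in records["dog_id"]])

    # fixed part: intercept, sex (male reference), scaled linear age, extras
    cols = [np.ones(n)]
    names = ["intercept"]
    if "sex" in records.columns:
        sex = records["sex"].astype(str)
    else:
        sex = pd.Series([ped[d].sex for d in records["dog_id"]])
    cols.append((sex.to_numpy() == "female").astype(float))
    names.append("sex:female")
    age = records["age_days"].to_numpy(dtype=float)
    age_sd = age.std(ddof=1)
    age_scaled = (age - age.mean()) / age_sd if age_sd > 0 else age - age.mean()
    cols.append(age_scaled)
    names.append("age_scaled")
    for term in spec.fixed:
        vals = records[term].astype(str)
        levels = sorted(vals.unique())
        ref = "BS" if term == "colour_group" and "BS" in levels else levels[0]
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{term}:{lev}")
    for cov in spec.covariates:
        v = records[cov].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd > 0:
            v = (v - v.mean()) / sd
        cols.append(v)
        names.append(cov)
    X = np.column_stack(cols)
    # drop degenerate columns (single-sex data, constant covariates) so the
    # fixed design keeps full column rank after reference coding
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    names = [names[j] for j in keep]

    factors: list[FactorBlock] = []
    # additive over the whole pedigree
    Za = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), animal_pos)), shape=(n, len(ped))
    )
    factors.append(FactorBlock("additive", Za, len(ped)))

    pe_levels: list = []
    if "permanent_env" in spec.random:
        pe_levels = sorted(set(records["dog_id"]))
        pe_map = {d: i for i, d in enumerate(pe_levels)}
        Zpe = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), [pe_map[d] for d in records["dog_id"]])),
            shape=(n, len(pe_levels)),
        )
        factors.append(FactorBlock("permanent_env", Zpe, len(pe_levels)))

    assessor_levels: list = []
    if "assessor" in spec.random:
        raw = records.get("assessor", pd.Series([""] * n)).fillna("").astype(str)
        assessor_levels = sorted({a for a in raw if a.strip()})
        amap = {a: i for i, a in enumerate(assessor_levels)}
        idx = np.empty(n, dtype=int)
        next_dummy = len(assessor_levels)
        for i, a in enumerate(raw):
            if a.strip():
                idx[i] = amap[a]
            else:  # unique dummy level per record with missing assessor
                assessor_levels.append(f"_dummy_{i}")
                idx[i] = next_dummy
                next_dummy += 1
        Zas = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), idx)), shape=(n, len(assessor_levels))
        )
        factors.append(FactorBlock("assessor", Zas, len(assessor_levels)))

    spline_dim = 0
    n_distinct = len(np.unique(age))
    knots = spec.spline_knots if spec.spline_knots is not None else min(50, max(n_distinct - 2, 0))
    if knots >= 1 and n_distinct >= knots + 2:
        S = spline_basis(age, knots)
        if S.shape[1] > 0:
            factors.append(FactorBlock("spline", sparse.csr_matrix(S), S.shape[1]))
            spline_dim = S.shape[1]

    return DesignSystem(
        y=y,
        X=X,
        x_names=names,
        factors=factors,
        record_to_animal=animal_pos,
        pe_levels=pe_levels,
        assessor_levels=assessor_levels,
        spline_dim=spline_dim,
        n_records=n,
    )


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    sigma2_pe: float | None = None
    sigma2_as: float | None = None
    sigma2_spline: float | None = None
    se: dict = field(default_factory=dict)


@dataclass
class AnimalModelFit:
    """REML fit of one univariate animal model."""

    components: VarianceComponents
    beta: pd.DataFrame  # term, estimate, se, wald_p
    spline_variance: float | None
    reml_loglik: float
    ml_loglik: float
    converged: bool
    iterations: int
    fit: FitResult  # engine-level result (parameter covariances etc.)
    design: DesignSystem
    spec: ModelSpec
    model: MixedModel


def _engine(ds: DesignSystem, a_inverse: sparse.spmatrix, a_logdet: float) -> MixedModel:
    factors = []
    for f in ds.factors:
        if f.name == "additive":
            factors.append(
                FactorBlock("additive", f.Z, f.n_levels, 1, a_inverse, a_logdet)
            )
        else:
            factors.append(f)
    return MixedModel(ds.y, ds.X, factors)


def reml_fit(
    ds: DesignSystem,
    ped: Pedigree,
    spec: ModelSpec | None = None,
    a_inverse: sparse.spmatrix | None = None,
    max_iter: int = 100,
) -> AnimalModelFit:
    """Fit the univariate animal model by AI-REML with EM fallback.

    ``ped`` must be the trimmed pedigree the design was built against,
    with inbreeding computed. Non-convergence is flagged on the result,
    not raised.
    """
    if a_inverse is None:
        a_inverse = build_a_inverse(ped)
    mm = _engine(ds, a_inverse, a_log_determinant(ped))
    res = mm.fit_reml(max_iter=max_iter)
    ml_ll = mm.ml_loglik([res.theta[f.name] for f in mm.factors], res.theta["residual"])

    def comp(name):
        return float(res.theta[name][0, 0]) if name in res.theta else None

    se = {k: float(v[0, 0]) for k, v in res.se.items()}
    components = VarianceComponents(
        sigma2_a=float(res.theta["additive"][0, 0]),
        sigma2_e=float(res.theta["residual"][0, 0]),
        sigma2_pe=comp("permanent_env"),
        sigma2_as=comp("assessor"),
        sigma2_spline=comp("spline"),
        se=se,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = res.beta / res.beta_se
    beta = pd.DataFrame(
        {
            "term": ds.x_names,
            "estimate": res.beta,
            "se": res.beta_se,
            "wald_p": 2 * norm.sf(np.abs(zval)),
        }
    )
    return AnimalModelFit(
        components=components,
        beta=beta,
        spline_variance=comp("spline"),
        reml_loglik=res.loglik,
        ml_loglik=ml_ll,
        converged=res.converged,
        iterations=res.iterations,
        fit=res,
        design=ds,
        spec=spec or ModelSpec(),
        model=mm,
    )


def lrt_random_term(full: AnimalModelFit, reduced: AnimalModelFit) -> tuple[float, float]:
    """Likelihood-ratio test for one variance component on the boundary.

    The reduced model must drop exactly one random term of the full
    model. The statistic 2*(logL_full - logL_reduced) is floored at 0
    and referred to the equal mixture of a point mass at zero and a
    chi-square with 1 df, so equal likelihoods give p = 0.5.
    """
    full_terms = {f.name for f in full.design.factors}
    red_terms = {f.name for f in reduced.design.factors}
    if not (red_terms < full_terms and len(full_terms - red_terms) == 1):
        raise ValueError(
            f"models not nested by one random term: {sorted(full_terms)} vs {sorted(red_terms)}"
        )
    stat = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return stat, p


def bic_backward_elimination(
    records: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    candidates: list,
    a_inverse: sparse.spmatrix | None = None,
    threshold: float = 2.0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Prune nuisance fixed terms whose removal improves BIC by >= 2.

    BIC is computed from the maximum-likelihood (not REML)
    log-likelihood with n = number of records, since REML likelihoods
    are not comparable across fixed-effect sets. Sex, linear age, the
    additive effect and the spline are never candidates. One term is
    removed per sweep (the best improvement); the trace records every
    evaluated model.
    """
    protected = {"sex", "age", "additive", "spline"}
    candidates = [c for c in candidates if c not in protected]
    if a_inverse is None:
        a_inverse = build_a_inverse(ped)
    a_ld = a_log_determinant(ped)
    n = len(records)

    def bic_of(s: ModelSpec) -> float:
        ds = build_design(records, ped, s)
        mm = _engine(ds, a_inverse, a_ld)
        ll, _, _ = mm.fit_ml_univariate()
        k = ds.X.shape[1] + mm.n_params
        return -2.0 * ll + k * np.log(n)

    current = spec
    current_bic = bic_of(current)
    rows = [{"step": 0, "action": "initial", "term": "", "bic": current_bic}]
    step = 0
    while candidates:
        step += 1
        best_term, best_bic = None, current_bic
        for term in candidates:
            b = bic_of(current.without_fixed_term(term))
            rows.append({"step": step, "action": "try-drop", "term": term, "bic": b})
            if current_bic - b >= threshold and b < best_bic:
                best_term, best_bic = term, b
        if best_term is None:
            break
        current = current.without_fixed_term(best_term)
        current_bic = best_bic
        candidates = [c for c in candidates if c != best_term]
        rows.append({"step": step, "action": "drop", "term": best_term, "bic": current_bic})
    return current, pd.DataFrame(rows)


def heritability_repeatability(fit: AnimalModelFit) -> dict:
    """Heritability and (where defined) repeatability with delta-method SEs.

    Phenotypic variance = sigma_a^2 + sigma_e^2 (+ sigma_pe^2 when the
    permanent-environment term was fitted); assessor and spline
    variances are nuisance components and excluded. Repeatability is
    absent (not zero) without a permanent-environment term.
    """
    c = fit.components
    names = fit.fit.param_names
    cov = fit.fit.param_cov

    def pidx(name: str) -> int | None:
        tag = f"{name}[0,0]"
        return names.index(tag) if tag in names else None

    ia, ie, ipe = pidx("additive"), pidx("residual"), pidx("permanent_env")
    sa, se_ = c.sigma2_a, c.sigma2_e
    spe = c.sigma2_pe if c.sigma2_pe is not None else 0.0
    sp = sa + se_ + (spe if c.sigma2_pe is not None else 0.0)
    h2 = sa / sp

    def delta_se(grad_map: dict) -> float:
        g = np.zeros(len(names))
        for i, v in grad_map.items():
            if i is not None:
                g[i] = v
        return float(np.sqrt(max(g @ cov @ g, 0.0)))

    h2_se = delta_se({ia: (sp - sa) / sp**2, ie: -sa / sp**2, ipe: -sa / sp**2})
    out = {"h2": h2, "h2_se": h2_se, "sigma2_p": sp}
    if c.sigma2_pe is not None:
        rep = (sa + spe) / sp
        rep_se = delta_se(
            {ia: se_ / sp**2, ipe: se_ / sp**2, ie: -(sa + spe) / sp**2}
        )
        out["repeatability"] = rep
        out["repeatability_se"] = rep_se
    return out
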