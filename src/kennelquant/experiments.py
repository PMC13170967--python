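"""Seeded validation experiments exercising the whole pipeline.

These drive the package end to end under the default study conditions
and measure how well known inputs are recovered: oracle agreement for
the pedigree algebra, closed-form REML limits, parameter recovery over
replicates, null calibration of the boundary likelihood-ratio test,
and determinism/accuracy of the randomized PCA. Both the test suite
and the acceptance script are thin layers over these functions.

All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .animal_model import (
    ModelSpec,
    build_design,
    heritability_repeatability,
    reml_fit,
)
from .breeding_values import accuracy_summary, pev_and_accuracy, solve_blup
from .cohort import logistic_or, prevalence
from .liability import grade_to_liability, to_boas_status
from .mixedmodel import FactorBlock, MixedModel
from .multitrait import genetic_correlation, multitrait_reml
from .pedigree import (
    build_a_inverse,
    cholesky_factor,
    compute_inbreeding,
    tabular_relationship,
    trim_to_phenotyped,
)
from .pedpca import randomized_pc_scores
from .simulate import SimConfig, simulate_pedigree, simulate_phenotypes, two_trait_config

# default study-condition sizes for the recovery replicates; chosen so a
# replicate set runs in minutes on one CPU while leaving informative SEs
UNI_SIZES = dict(n_founders=100, n_generations=4, generation_size=200, phenotyped_generations=2)
BIV_SIZES = dict(n_founders=90, n_generations=3, generation_size=170, phenotyped_generations=2)


def pedigree_oracle_errors(n_pedigrees: int = 100, seed: int = 0, max_size: int = 500) -> dict:
    """Max deviations of the fast pedigree algebra from the dense oracle.

    For each random pedigree: Meuwissen-Luo f vs diag(A)-1, Henderson
    A^-1 times tabular A vs identity, and L L' vs A.
    """
    rng = np.random.default_rng(seed)
    worst = {"inbreeding": 0.0, "a_inverse": 0.0, "cholesky": 0.0, "n_max": 0}
    for _ in range(n_pedigrees):
        gen_size = int(rng.integers(10, max(11, max_size // 4)))
        cfg = SimConfig(
            n_founders=int(rng.integers(6, 40)),
            n_generations=int(rng.integers(1, 4)),
            generation_size=gen_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ped = compute_inbreeding(simulate_pedigree(cfg))
        if len(ped) > max_size:
            continue
        A = tabular_relationship(ped)
        n = len(ped)
        worst["n_max"] = max(worst["n_max"], n)
        worst["inbreeding"] = max(
            worst["inbreeding"], float(np.max(np.abs(ped.inbreeding - (np.diag(A) - 1.0))))
        )
        Ai = build_a_inverse(ped).toarray()
        worst["a_inverse"] = max(
            worst["a_inverse"], float(np.max(np.abs(Ai @ A - np.eye(n))))
        )
        L = cholesky_factor(ped).toarray()
        worst["cholesky"] = max(worst["cholesky"], float(np.max(np.abs(L @ L.T - A))))
    return worst


def halfsib_anova_gap(seed: int = 0, n_sires: int = 40, k: int = 6) -> dict:
    """|REML - ANOVA| for the additive variance on a balanced half-sib design."""
    from .pedigree import Pedigree, PedigreeRecord

    rng = np.random.default_rng(seed)
    sa2, se2 = 0.8, 1.2
    rows = [PedigreeRecord(f"S{i}", None, None, "male") for i in range(n_sires)]
    rows += [
        PedigreeRecord(f"P{i}_{j}", f"S{i}", None)
        for i in range(n_sires)
        for j in range(k)
    ]
    ped = compute_inbreeding(Pedigree(rows))
    sires = rng.normal(size=n_sires) * np.sqrt(sa2)
    y = (
        0.5 * sires[:, None]
        + rng.normal(size=(n_sires, k)) * np.sqrt(0.75 * sa2)
        + rng.normal(size=(n_sires, k)) * np.sqrt(se2)
    )
    recs = pd.DataFrame(
        {
            "dog_id": [f"P{i}_{j}" for i in range(n_sires) for j in range(k)],
            "value": y.ravel(),
            "age_days": 500.0,
            "sex": "male",
        }
    )
    msb = k * np.var(y.mean(axis=1), ddof=1)
    msw = np.mean(np.var(y, axis=1, ddof=1))
    # constrained closed form: REML on a balanced one-way layout equals the
    # ANOVA estimator when interior, and sits on the zero boundary otherwise
    sa2_anova = max(4.0 * (msb - msw) / k, 0.0)
    spec = ModelSpec(response="value", random=set(), spline_knots=0)
    fit = reml_fit(build_design(recs, ped, spec), ped, spec)
    return {
        "sigma2_a_reml": fit.components.sigma2_a,
        "sigma2_a_anova": sa2_anova,
        "gap": abs(fit.components.sigma2_a - sa2_anova),
    }


def blup_dense_oracle_gap(seed: int = 0) -> float:
    """Max |MME solution - dense GLS solution| on a small instance."""
    cfg = SimConfig(n_founders=16, n_generations=2, generation_size=16,
                    phenotyped_generations=1, seed=seed, category_probs=(None,),
                    missing_rate=0.0)
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, _ = simulate_phenotypes(ped, cfg)
    recs = recs.assign(liab=recs["value"].astype(float))
    spec = ModelSpec(response="liab", random={"permanent_env"}, spline_knots=0)
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    fit = reml_fit(build_design(recs, trimmed, spec), trimmed, spec)
    tbl, mm, st = solve_blup(recs, ped, fit, spec)
    A = tabular_relationship(ped)
    ds = build_design(recs, ped, spec)
    n = len(recs)
    Za = np.zeros((n, len(ped)))
    Za[np.arange(n), ds.record_to_animal] = 1.0
    Zpe = next(f for f in ds.factors if f.name == "permanent_env").Z.toarray()
    sa, spe, se_ = (fit.components.sigma2_a, fit.components.sigma2_pe,
                    fit.components.sigma2_e)
    V = sa * Za @ A @ Za.T + spe * Zpe @ Zpe.T + se_ * np.eye(n)
    Vi = np.linalg.inv(V)
    X, y = ds.X, ds.y
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = sa * A @ Za.T @ Vi @ (y - X @ beta)
    return float(np.max(np.abs(tbl["ebv"].to_numpy() - u)))


def univariate_recovery(seed: int, sizes: dict | None = None) -> dict:
    """One continuous-trait replicate: h2 and repeatability with SEs."""
    cfg = SimConfig(**(sizes or UNI_SIZES), seed=seed, category_probs=(None,))
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, _ = simulate_phenotypes(ped, cfg)
    recs = recs.assign(liab=recs["value"].astype(float))
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    spec = ModelSpec(response="liab", spline_knots=6)
    fit = reml_fit(build_design(recs, trimmed, spec), trimmed, spec)
    hr = heritability_repeatability(fit)
    hr["converged"] = fit.converged
    hr["n_records"] = len(recs)
    return hr


def bivariate_recovery(seed: int, sizes: dict | None = None) -> dict:
    """One bivariate replicate: genetic correlation with SE."""
    cfg = two_trait_config(**(sizes or BIV_SIZES), seed=seed,
                           category_probs=(None, None))
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, _ = simulate_phenotypes(ped, cfg)
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    specs = {"trait1": ModelSpec(spline_knots=4), "trait2": ModelSpec(spline_knots=4)}
    structs = multitrait_reml(recs, trimmed, ["trait1", "trait2"], specs,
                              pe_traits={"trait1"})
    rg = genetic_correlation(structs, 0, 1, lrt=False)
    return {"rg": rg.value, "rg_se": rg.se, "converged": structs.converged,
            "n_records": len(recs)}


def recovery_experiment(n_reps: int = 20, seed: int = 1) -> dict:
    """Recovery of h2 = 0.45, repeatability = 0.61, r_g = 0.6 over replicates."""
    rng = np.random.default_rng(seed)
    uni = [univariate_recovery(int(rng.integers(0, 2**31 - 1))) for _ in range(n_reps)]
    biv = [bivariate_recovery(int(rng.integers(0, 2**31 - 1))) for _ in range(n_reps)]
    h2_hits = [abs(r["h2"] - 0.45) <= 2 * r["h2_se"] for r in uni]
    rep_hits = [abs(r["repeatability"] - 0.61) <= 2 * r["repeatability_se"] for r in uni]
    rg_hits = [abs(r["rg"] - 0.6) <= 2 * r["rg_se"] for r in biv]
    return {
        "h2_mean": float(np.mean([r["h2"] for r in uni])),
        "repeatability_mean": float(np.mean([r["repeatability"] for r in uni])),
        "rg_mean": float(np.mean([r["rg"] for r in biv])),
        "h2_rate": float(np.mean(h2_hits)),
        "repeatability_rate": float(np.mean(rep_hits)),
        "rg_rate": float(np.mean(rg_hits)),
        "n_reps": n_reps,
        "n_records_uni": int(np.mean([r["n_records"] for r in uni])),
        "n_records_biv": int(np.mean([r["n_records"] for r in biv])),
    }


def lrt_null_experiment(n_reps: int = 500, seed: int = 2) -> dict:
    """Empirical size of the boundary-mixture LRT for sigma_a^2 = 0.

    A fixed pedigree; each replicate draws iid phenotypes (no genetic
    signal), fits the model with and without the additive term, and
    rejects when the mixture p-value is below 0.05 (statistic above
    2.706).
    """
    from .pedigree import Pedigree, PedigreeRecord

    rng = np.random.default_rng(seed)
    # large full-sib groups: the half-half mixture reference distribution is
    # asymptotic and needs substantial per-family information to hold
    n_fam, sibs = 25, 10
    rows = []
    for i in range(n_fam):
        rows.append(PedigreeRecord(f"S{i}", None, None, "male"))
        rows.append(PedigreeRecord(f"D{i}", None, None, "female"))
    for i in range(n_fam):
        for j in range(sibs):
            rows.append(PedigreeRecord(f"O{i}_{j}", f"S{i}", f"D{i}", "male"))
    n_o = n_fam * sibs
    ped = compute_inbreeding(Pedigree(rows))
    a_inv = build_a_inverse(ped)
    from .pedigree import a_log_determinant

    a_ld = a_log_determinant(ped)
    phen = [f"O{i}_{j}" for i in range(n_fam) for j in range(sibs)]
    pos = np.array([ped.index[p] for p in phen])
    n = n_o
    Za = sparse.csr_matrix((np.ones(n), (np.arange(n), pos)), shape=(n, len(ped)))
    X = np.ones((n, 1))
    rejections = 0
    for _ in range(n_reps):
        y = rng.standard_normal(n)
        full = MixedModel(y, X, [FactorBlock("additive", Za, len(ped), 1, a_inv, a_ld)])
        res_full = full.fit_reml(max_iter=50)
        res_red = MixedModel(y, X, []).fit_reml(max_iter=50)
        stat = max(0.0, 2.0 * (res_full.loglik - res_red.loglik))
        if stat > 2.706:  # mixture 5% critical value
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def odds_ratio_cross_product_gap(n_tables: int = 50, seed: int = 3) -> float:
    """Max relative gap between the logistic OR and the 2x2 cross-product."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(5, 80, size=4)
        exposure = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
        outcome = np.repeat([1, 0, 1, 0], [a, b, c, d])
        est = logistic_or(outcome, pd.DataFrame({"x": exposure}))[0].odds_ratio
        target = (a * d) / (b * c)
        worst = max(worst, abs(est - target) / target)
    return worst


def pca_determinism_and_angle(seed: int = 4, size: int = 300) -> dict:
    """Bit-reproducibility under a fixed seed and top-2 principal angle
    against the dense SVD of the centred Cholesky factor."""
    from scipy.linalg import subspace_angles

    cfg = SimConfig(n_founders=60, n_generations=3, generation_size=size // 3, seed=seed)
    ped = compute_inbreeding(simulate_pedigree(cfg))
    L = cholesky_factor(ped)
    a = randomized_pc_scores(L, k=2, seed=seed)
    b = randomized_pc_scores(L, k=2, seed=seed)
    Ld = L.toarray()
    Lc = Ld - Ld.mean(axis=0)
    U, s, _ = np.linalg.svd(Lc, full_matrices=False)
    ang = float(np.max(subspace_angles(a.scores, U[:, :2])))
    return {
        "bit_identical": bool(np.array_equal(a.scores, b.scores)),
        "principal_angle": ang,
        "n": len(ped),
    }


def full_study_run(seed: int = 5, sizes: dict | None = None) -> dict:
    """One complete ordinal-pipeline study under the default conditions:
    prevalence, liability fit, EBV accuracies, obesity odds recovery."""
    cfg = SimConfig(**(sizes or UNI_SIZES), seed=seed)
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, truth = simulate_phenotypes(ped, cfg)
    out = {}
    prev = prevalence(recs, to_boas_status)
    out["prevalence_pct"] = 100.0 * float(prev["prevalence"].iloc[0])
    out["n_dogs"] = int(recs["dog_id"].nunique())

    lmap, liab = grade_to_liability(recs["value"].to_numpy())
    recs = recs.assign(liab=liab)
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    spec = ModelSpec(response="liab", spline_knots=6)
    fit = reml_fit(build_design(recs, trimmed, spec), trimmed, spec)
    hr = heritability_repeatability(fit)
    out["h2_liability"] = hr["h2"]
    out["repeatability_liability"] = hr.get("repeatability")

    tbl, mm, st = solve_blup(recs, ped, fit, spec)
    tbl = pev_and_accuracy(tbl, mm, st, fit.components.sigma2_a)
    summ = accuracy_summary(tbl, born_since=None, h2=hr["h2"])
    out["median_ebv_accuracy"] = summ["median_accuracy"]
    out["n_pedigree"] = len(ped)
    return out


def obesity_or_recovery(seed: int = 6, n_dogs: int = 60000, true_or: float = 3.8,
                        base_prev: float = 0.12) -> dict:
    """Simulated obesity -> clinical-status cohort with a known odds ratio."""
    rng = np.random.default_rng(seed)
    obese = rng.random(n_dogs) < 0.09  # realistic obesity share
    base_odds = base_prev / (1 - base_prev)
    odds = np.where(obese, base_odds * true_or, base_odds)
    p = odds / (1 + odds)
    boas = rng.random(n_dogs) < p
    est = logistic_or(boas, pd.DataFrame({"obese": obese.astype(float)}))[0]
    return {"or": est.odds_ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "n": n_dogs, "true_or": true_or}
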