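"""End-to-end per-breed analysis of health-scheme pedigree + phenotype files.

Runs the full pipeline on one breed's registry exports: parse and
repair the pedigree, compute inbreeding, transform ordinal grades to
the liability scale, fit the univariate animal model on the trimmed
pedigree, re-solve over the full pedigree for breeding values and
accuracies, fit the bivariate model with nostril stenosis, and compute
the cohort statistics (prevalence, odds ratios, litter summaries).

Expected phenotype file: columns ``dog_id, trait, value, assessor,
test_date`` with trait names ``rfgs`` (0-3 ordinal respiratory grade),
``sten`` (open/mild/moderate/severe), ``bw`` (kg), ``bcs`` (1-9).
Age at test is derived from the pedigree date of birth.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from . import cohort, liability
from .animal_model import ModelSpec, build_design, heritability_repeatability, reml_fit
from .breeding_values import accuracy_summary, pev_and_accuracy, solve_blup
from .multitrait import genetic_correlation, multitrait_reml, phenotypic_correlation
from .pedigree import compute_inbreeding, parse_pedigree, trim_to_phenotyped, validate_and_correct


def load_phenotypes(path, ped) -> pd.DataFrame:
    """Read a phenotype CSV and derive age in days from pedigree dates."""
    df = pd.read_csv(path, dtype={"dog_id": str, "trait": str, "assessor": str}, keep_default_na=False)
    df["test_date"] = pd.to_datetime(df["test_date"]).dt.date
    ages, sexes = [], []
    for _, row in df.iterrows():
        rec = ped[row["dog_id"]] if row["dog_id"] in ped else None
        if rec is None or rec.dob is None:
            ages.append(np.nan)
        else:
            ages.append((row["test_date"] - rec.dob).days)
        sexes.append(rec.sex if rec is not None else "unknown")
    df["age_days"] = ages
    df["sex"] = sexes
    return df


def run_breed_analysis(
    pedigree_csv,
    phenotypes_csv,
    colour_map: dict | None = None,
    born_since: int = 2016,
    spline_knots: int | None = None,
) -> dict:
    """Full single-breed analysis; returns the headline quantities."""
    ped = parse_pedigree(pedigree_csv, colour_map)
    ped, corrections = validate_and_correct(ped)
    ped = compute_inbreeding(ped)
    pheno = load_phenotypes(phenotypes_csv, ped)

    rfgs = pheno[pheno["trait"] == "rfgs"].copy()
    rfgs["value"] = rfgs["value"].astype(float).astype(int)
    out: dict = {"n_corrections": len(corrections), "n_pedigree": len(ped)}

    prev = cohort.prevalence(rfgs, liability.to_boas_status)
    out["boas_prevalence_pct"] = 100.0 * float(prev["prevalence"].iloc[0])
    out["progression"] = cohort.grade_progression(rfgs)

    # univariate liability animal model
    lmap, liab = liability.grade_to_liability(rfgs["value"].to_numpy())
    rfgs = rfgs.assign(liab=liab).dropna(subset=["age_days"])
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(rfgs["dog_id"])))
    spec = ModelSpec(response="liab", spline_knots=spline_knots)
    fit = reml_fit(build_design(rfgs, trimmed, spec), trimmed, spec)
    hr = heritability_repeatability(fit)
    out["h2"] = hr["h2"]
    out["h2_se"] = hr["h2_se"]
    out["repeatability"] = hr.get("repeatability")
    out["repeatability_se"] = hr.get("repeatability_se")

    # breeding values over the entire pedigree
    tbl, mm, st = solve_blup(rfgs, ped, fit, spec)
    tbl = pev_and_accuracy(tbl, mm, st, fit.components.sigma2_a)
    out["accuracy_summary"] = accuracy_summary(tbl, born_since=born_since, h2=hr["h2"])

    # bivariate model with nostril stenosis, where present
    sten = pheno[pheno["trait"] == "sten"].copy()
    if len(sten) >= 50:
        order = ["open", "mild", "moderate", "severe"]
        _, sten_liab = liability.grade_to_liability(
            sten["value"].str.lower().to_numpy(), categories=order
        )
        sten = sten.assign(liab=sten_liab).dropna(subset=["age_days"])
        both = pd.concat(
            [rfgs.assign(trait="rfgs"), sten.assign(trait="sten")], ignore_index=True
        )
        tr2 = compute_inbreeding(trim_to_phenotyped(ped, set(both["dog_id"])))
        specs = {
            "rfgs": ModelSpec(response="liab", spline_knots=spline_knots),
            "sten": ModelSpec(response="liab", spline_knots=spline_knots),
        }
        structs = multitrait_reml(both, tr2, ["rfgs", "sten"], specs,
                                  pe_traits={"rfgs"}, response="liab")
        rg = genetic_correlation(structs, 0, 1, lrt=False)
        rp = phenotypic_correlation(structs, 0, 1)
        out["rg_rfgs_sten"] = rg.value
        out["rg_rfgs_sten_se"] = rg.se
        out["rp_rfgs_sten"] = rp.value

    # obesity / stenosis odds on clinical status
    bcs = pheno[pheno["trait"] == "bcs"]
    if len(bcs):
        first_bcs = cohort.first_record_per_dog(bcs)
        first_grade = cohort.first_record_per_dog(rfgs)
        dogs = first_bcs.index.intersection(first_grade.index)
        if len(dogs) >= 20:
            obese = liability.is_obese(first_bcs.loc[dogs].astype(float).to_numpy())
            boas = liability.to_boas_status(first_grade.loc[dogs].to_numpy())
            ors = cohort.logistic_or(boas, pd.DataFrame({"obese": obese}))
            out["or_obesity"] = ors[0].odds_ratio
    return out


def pooled_odds_ratio(breed_frames: dict, predictor: str = "obese") -> float:
    """Pooled odds ratio across breeds with breed as a fixed covariate.

    ``breed_frames`` maps breed name to a frame with boolean columns
    ``boas`` and the predictor.
    """
    rows = []
    for breed, df in breed_frames.items():
        d = df.copy()
        d["breed"] = breed
        rows.append(d)
    data = pd.concat(rows, ignore_index=True)
    ors = cohort.logistic_or(
        data["boas"].to_numpy(), data[[predictor, "breed"]],
    )
    return next(o.odds_ratio for o in ors if o.term.startswith(predictor))
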