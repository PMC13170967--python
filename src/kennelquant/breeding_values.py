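"""BLUP breeding values, prediction error variances and accuracies.

After variance components are estimated on the trimmed pedigree, the
final model is re-solved over the entire pedigree so every animal —
phenotyped or not — receives an estimated breeding value (EBV). The
prediction error variance (PEV) of an EBV is the corresponding diagonal
element of the inverse mixed-model coefficient matrix, and accuracy is

    r = sqrt(1 - PEV / ((1 + f) sigma_a^2)),

where f is the animal's inbreeding coefficient; an animal about which
the data carry no information has PEV = (1 + f) sigma_a^2 and accuracy
0. The no-square-root variant (reliability, r^2) is available via
``reliability=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .animal_model import AnimalModelFit, ModelSpec, _engine, build_design
from .mixedmodel import MixedModel
from .pedigree import Pedigree, a_log_determinant, build_a_inverse


def solve_blup(
    records: pd.DataFrame,
    full_ped: Pedigree,
    fit: AnimalModelFit,
    spec: ModelSpec | None = None,
) -> tuple[pd.DataFrame, MixedModel, object]:
    """Solve the mixed-model equations over the full pedigree at the
    converged variance components.

    Returns a per-animal table (id, ebv, phenotyped flag, cohort
    annotations) plus the engine and its solved state for PEV work.
    """
    spec = spec or fit.spec
    ds = build_design(records, full_ped, spec)
    a_inv = build_a_inverse(full_ped)
    mm = _engine(ds, a_inv, a_log_determinant(full_ped))
    thetas = [fit.fit.theta[f.name] for f in mm.factors]
    R = fit.fit.theta["residual"]
    sol, st = mm.solve_at(thetas, R)
    fi = [f.name for f in mm.factors].index("additive")
    off = mm.offsets[fi]
    ebv = sol[off : off + len(full_ped)]
    phenotyped = np.zeros(len(full_ped), dtype=bool)
    phenotyped[ds.record_to_animal] = True
    tbl = pd.DataFrame(
        {
            "id": full_ped.ids,
            "ebv": ebv,
            "phenotyped": phenotyped,
            "f": full_ped.inbreeding,
            "yob": [r.dob.year if r.dob else np.nan for r in full_ped.records],
            "colour_group": [r.colour_group for r in full_ped.records],
        }
    )
    return tbl, mm, st


def pev_and_accuracy(
    tbl: pd.DataFrame,
    mm: MixedModel,
    st,
    sigma2_a: float,
    reliability: bool = False,
) -> pd.DataFrame:
    """Fill PEV, SE and accuracy columns of an EBV table.

    Raises if any PEV exceeds (1 + f) sigma_a^2 beyond rounding, which
    would indicate an inconsistent system.
    """
    pev = mm.pev(st, "additive")
    bound = (1.0 + tbl["f"].to_numpy()) * sigma2_a
    if np.any(pev > bound * (1.0 + 1e-6) + 1e-12):
        worst = int(np.argmax(pev - bound))
        raise ValueError(
            f"PEV {pev[worst]:.6g} exceeds (1+f)*sigma_a^2 {bound[worst]:.6g} "
            f"for animal {tbl['id'].iloc[worst]}"
        )
    rel = np.clip(1.0 - pev / bound, 0.0, 1.0)
    out = tbl.copy()
    out["pev"] = pev
    out["se_ebv"] = np.sqrt(pev)
    out["accuracy"] = rel if reliability else np.sqrt(rel)
    return out


def accuracy_summary(tbl: pd.DataFrame, born_since: int | None = None, h2: float | None = None) -> dict:
    """Median accuracies overall and by colour group for a birth cohort.

    When ``h2`` is given, also reports the fraction of the cohort whose
    accuracy exceeds sqrt(h2) (selection on own phenotype) and
    sqrt(h2/2) (parental average only); both thresholds are emitted
    because the reference lines can be read on either the accuracy or
    the reliability scale.
    """
    sub = tbl if born_since is None else tbl[tbl["yob"] >= born_since]
    if len(sub) == 0:
        return {"n": 0}
    out = {
        "n": int(len(sub)),
        "median_accuracy": float(sub["accuracy"].median()),
        "median_by_colour": {
            g: float(d["accuracy"].median()) for g, d in sub.groupby("colour_group")
        },
    }
    if h2 is not None:
        own = np.sqrt(h2)
        parent_avg = np.sqrt(0.5 * h2)
        acc = sub["accuracy"].to_numpy()
        out["frac_above_own_phenotype"] = float(np.mean(acc > own))
        out["frac_above_parent_average"] = float(np.mean(acc > parent_avg))
        out["thresholds"] = {"own_phenotype": own, "parent_average": parent_avg}
    return out
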