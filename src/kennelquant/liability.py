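"""Threshold-model liability transform for ordinal traits.

An ordinal grade with observed category proportions p_1..p_J is assumed
to arise from a latent standard-normal liability cut at thresholds
z_j = Phi^-1(p_1 + ... + p_j). Each category j is replaced by the
conditional mean of the liability within its slice,

    y_j = (phi(z_{j-1}) - phi(z_j)) / (Phi(z_j) - Phi(z_{j-1})),

with phi(+-inf) = 0, Phi(-inf) = 0, Phi(+inf) = 1. The transformed
scores have zero mean under the observed category distribution and are
strictly increasing in category order. Variance-component ratios
(heritability, repeatability) are invariant to the overall scale, so the
scores are used raw.

Also houses the binary clinical-status rules for the respiratory grade
(grades 2-3 affected) and nostril stenosis (moderate/severe affected),
the obesity rule (body condition score >= 7) and covariate
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

STEN_CATEGORIES = ("open", "mild", "moderate", "severe")


@dataclass
class LiabilityMap:
    """Per-trait mapping from ordinal category to liability-scale value."""

    trait: str
    categories: list  # observed (non-empty) categories, in order
    p: np.ndarray  # category proportions, sum to 1
    z: np.ndarray  # thresholds incl. -inf / +inf, length len(categories)+1
    y: np.ndarray  # liability value per category

    def transform(self, grades) -> np.ndarray:
        lookup = {c: self.y[j] for j, c in enumerate(self.categories)}
        try:
            return np.array([lookup[g] for g in np.asarray(grades).tolist()])
        except KeyError as err:
            raise ValueError(f"grade {err.args[0]!r} not in fitted categories") from None


def grade_to_liability(grades, trait: str = "grade", categories=None) -> tuple[LiabilityMap, np.ndarray]:
    """Fit the liability map from observed grades and transform them.

    ``categories`` fixes the category order (defaults to sorted unique
    values); empty categories are dropped before thresholds are
    computed. Raises on fewer than two non-empty categories.
    """
    grades = np.asarray(grades)
    if grades.size == 0:
        raise ValueError("no grades supplied")
    if categories is None:
        categories = sorted(set(grades.tolist()))
    counts = np.array([(grades == c).sum() for c in categories], dtype=float)
    keep = counts > 0
    cats = [c for c, k in zip(categories, keep) if k]
    counts = counts[keep]
    if len(cats) < 2:
        raise ValueError("no variation: fewer than two non-empty categories")
    p = counts / counts.sum()
    cum = np.cumsum(p)
    z_inner = norm.ppf(cum[:-1])
    z = np.concatenate([[-np.inf], z_inner, [np.inf]])
    phi = np.where(np.isfinite(z), norm.pdf(z), 0.0)
    Phi = norm.cdf(z)
    y = (phi[:-1] - phi[1:]) / (Phi[1:] - Phi[:-1])
    lmap = LiabilityMap(trait=trait, categories=cats, p=p, z=z, y=y)
    return lmap, lmap.transform(grades)


def to_boas_status(grades) -> np.ndarray:
    """Binary clinical status from the 0-3 respiratory grade.

    Grades 2 and 3 are clinically affected.
    """
    g = np.asarray(grades, dtype=float)
    if np.any(~np.isin(g, [0, 1, 2, 3])):
        bad = sorted(set(g[~np.isin(g, [0, 1, 2, 3])].tolist()))
        raise ValueError(f"grades out of range 0..3: {bad}")
    return g >= 2


def to_stenosis_status(grades) -> np.ndarray:
    """Binary stenotic-nares status: moderate or severe is affected."""
    out = []
    for g in np.asarray(grades).tolist():
        label = str(g).strip().lower()
        if label not in STEN_CATEGORIES:
            raise ValueError(f"unknown stenosis category: {g!r}")
        out.append(label in ("moderate", "severe"))
    return np.array(out)


def is_obese(bcs) -> np.ndarray:
    """Obesity flag: body condition score of 7 or more on the 9-point scale."""
    return np.asarray(bcs, dtype=float) >= 7


def standardize(x) -> np.ndarray:
    """Centre and scale to sample standard deviation 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
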