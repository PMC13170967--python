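"""Synthetic pedigrees and phenotypes with known variance components.

The generator mirrors the generative structure the estimation pipeline
assumes: a multi-generation pedigree with founders; additive genetic
values drawn with covariance proportional to the numerator relationship
matrix via its pedigree Cholesky factor (u = L z sigma_a, so cov(u) =
A sigma_a^2, including cross-trait covariances through a genetic
correlation matrix); per-dog permanent-environment and per-assessor
effects; fixed sex and linear-age effects; and a latent Gaussian
liability cut at thresholds to produce 4-category ordinal grades, with
repeated records per dog.

Default parameter values are the study conditions the package is
exercised under: trait 1 is a respiratory-grade analogue with
sigma_a^2 = 0.45, sigma_pe^2 = 0.16, sigma_as^2 = 0.30,
sigma_e^2 = 0.39 (heritability 0.45, repeatability 0.61 on the latent
scale) and category probabilities (0.454, 0.390, 0.126, 0.030), i.e. a
15.6% clinical prevalence under the grades-2-and-3-affected rule;
trait 2 is a nostril-stenosis analogue with heritability 0.39,
category probabilities (0.062, 0.426, 0.452, 0.060) and genetic
correlation 0.6 with trait 1. The sex effect is -0.33 (females lower)
and the linear age slope 0.05 per SD of age. Records per dog average
1.25. Generations are non-overlapping for simplicity; the estimation
code never assumes that.

All randomness flows from one seed through a single generator, so
every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedigree import Pedigree, PedigreeRecord, cholesky_factor, compute_inbreeding

# breed-standard / non-breed-standard colour labels used in fixtures
DEFAULT_COLOUR_MAP = {
    "brindle": "BS",
    "fawn": "BS",
    "pied": "BS",
    "blue": "NBS",
    "merle": "NBS",
    "chocolate": "NBS",
}

TRAIT1_PROBS = (0.454, 0.390, 0.126, 0.030)  # grade analogue, 15.6% grades 2-3
TRAIT2_PROBS = (0.062, 0.426, 0.452, 0.060)  # stenosis analogue


def _thresholds(probs, total_sd: float) -> np.ndarray:
    return norm.ppf(np.cumsum(probs)[:-1]) * total_sd


@dataclass
class SimConfig:
    """Study conditions for one simulated data set.

    Scalar variance fields describe a single trait; sequences describe
    one value per trait. ``thresholds`` of None means a continuous
    trait (no ordinal cut). ``g_corr`` is the genetic correlation
    matrix across traits.
    """

    n_founders: int = 80
    n_generations: int = 4
    generation_size: int = 80
    litter_size_mean: float = 4.0  # 1 + Poisson(mean - 1)
    mating: str = "random"  # or "assortative-by-ebv"
    sigma2_a: tuple = (0.45,)
    sigma2_pe: tuple = (0.16,)
    sigma2_as: tuple = (0.30,)
    sigma2_e: tuple = (0.39,)
    category_probs: tuple = (TRAIT1_PROBS,)  # per trait; None entry -> continuous
    g_corr: np.ndarray = field(default_factory=lambda: np.eye(1))
    n_assessors: int = 30
    records_per_dog: dict = field(default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05})
    record_prob: tuple = (1.0,)  # chance each trait is scored at an event
    sex_effect: float = -0.33  # shift for females
    age_slope: float = 0.05  # per SD of age at test
    missing_rate: float = 0.10  # blank assessor fields
    phenotyped_generations: int = 2  # youngest generations carry records
    nbs_fraction: float = 0.3
    sbn_prob: float = 0.2
    seed: int = 1

    def __post_init__(self):
        as_tuple = lambda v: tuple(v) if np.iterable(v) else (v,)
        self.sigma2_a = as_tuple(self.sigma2_a)
        self.sigma2_pe = as_tuple(self.sigma2_pe)
        self.sigma2_as = as_tuple(self.sigma2_as)
        self.sigma2_e = as_tuple(self.sigma2_e)
        self.record_prob = as_tuple(self.record_prob)
        self.g_corr = np.atleast_2d(np.asarray(self.g_corr, dtype=float))
        if not isinstance(self.category_probs, tuple) or (
            self.category_probs and np.isscalar(self.category_probs[0])
        ):
            self.category_probs = (self.category_probs,)
        t = self.n_traits
        for name in ("sigma2_pe", "sigma2_as", "sigma2_e", "record_prob"):
            v = getattr(self, name)
            if len(v) == 1 and t > 1:
                setattr(self, name, v * t)
        if len(self.category_probs) == 1 and t > 1:
            self.category_probs = self.category_probs * t
        h2 = np.array(self.sigma2_a) / (
            np.array(self.sigma2_a) + np.array(self.sigma2_pe) + np.array(self.sigma2_e)
        )
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise ValueError("implied heritability outside [0, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.sigma2_a)

    def total_sd(self, t: int) -> float:
        return float(
            np.sqrt(
                self.sigma2_a[t] + self.sigma2_pe[t] + self.sigma2_as[t] + self.sigma2_e[t]
            )
        )


def two_trait_config(**overrides) -> SimConfig:
    """Default bivariate conditions: grade and stenosis analogues, r_g = 0.6."""
    base = dict(
        sigma2_a=(0.45, 0.39),
        sigma2_pe=(0.16, 1e-12),
        sigma2_as=(0.30, 0.30),
        sigma2_e=(0.39, 0.61),
        category_probs=(TRAIT1_PROBS, TRAIT2_PROBS),
        g_corr=np.array([[1.0, 0.6], [0.6, 1.0]]),
        record_prob=(1.0, 0.9),
    )
    base.update(overrides)
    return SimConfig(**base)


def simulate_pedigree(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    return_merits: bool = False,
) -> Pedigree:
    """Non-overlapping-generation pedigree with founders, balanced sexes.

    Litters draw a random sire and dam from the previous generation; with
    ``mating="assortative-by-ebv"`` couples are instead rank-matched on a
    heritable merit score (midparent mean plus Mendelian noise), emulating
    selection-driven non-random mate choice. Litter sizes are 1 + Poisson.
    The result passes validation with an empty correction log.
    ``return_merits`` also returns the per-dog merit scores.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    colours = list(DEFAULT_COLOUR_MAP)
    records: list[PedigreeRecord] = []
    counter = 0

    def new_record(sire, dam, sex, year):
        nonlocal counter
        counter += 1
        is_nbs = rng.random() < cfg.nbs_fraction
        pool = colours[3:] if is_nbs else colours[:3]
        label = pool[rng.integers(0, len(pool))]
        return PedigreeRecord(
            id=f"D{counter:05d}",
            sire_id=sire,
            dam_id=dam,
            sex=sex,
            dob=date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365))),
            colour_label=label,
            colour_group=DEFAULT_COLOUR_MAP[label],
            has_sbn=bool(rng.random() < cfg.sbn_prob),
            registration="RKC",
        )

    # merits come from a derived stream so random-mating pedigrees are
    # unaffected by whether merit bookkeeping is on
    mrng = np.random.default_rng(cfg.seed + 104729)
    merit: dict[str, float] = {}
    gen: list[PedigreeRecord] = []
    for i in range(cfg.n_founders):
        rec = new_record(None, None, "male" if i % 2 == 0 else "female", 2000)
        records.append(rec)
        gen.append(rec)
        merit[rec.id] = float(mrng.standard_normal())

    for g in range(1, cfg.n_generations + 1):
        males = [r.id for r in gen if r.sex == "male"]
        females = [r.id for r in gen if r.sex == "female"]
        if not males or not females:
            raise ValueError("infeasible mating: a generation lost one sex entirely")
        if cfg.mating == "assortative-by-ebv":
            males = sorted(males, key=merit.get)
            females = sorted(females, key=merit.get)
        year = 2000 + 2 * g
        nxt: list[PedigreeRecord] = []
        while len(nxt) < cfg.generation_size:
            if cfg.mating == "assortative-by-ebv":
                # same quantile of each sex's merit ranking, with jitter
                q = rng.random()
                si = min(int(q * len(males) + rng.integers(-1, 2)), len(males) - 1)
                di = min(int(q * len(females) + rng.integers(-1, 2)), len(females) - 1)
                sire, dam = males[max(si, 0)], females[max(di, 0)]
            else:
                sire = males[rng.integers(0, len(males))]
                dam = females[rng.integers(0, len(females))]
            size = 1 + rng.poisson(max(cfg.litter_size_mean - 1.0, 0.0))
            for _ in range(size):
                sex = "male" if rng.random() < 0.5 else "female"
                rec = new_record(sire, dam, sex, year)
                records.append(rec)
                nxt.append(rec)
                merit[rec.id] = 0.5 * (merit[sire] + merit[dam]) + float(
                    mrng.standard_normal() * np.sqrt(0.5)
                )
        gen = nxt
    ped = Pedigree(records)
    return (ped, merit) if return_merits else ped


def _generation_of(ped: Pedigree) -> np.ndarray:
    sire, dam = ped._parent_positions()
    g = np.zeros(len(ped), dtype=int)
    for i in range(len(ped)):
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        g[i] = 1 + max((g[p] for p in parents), default=-1)
    return g


def simulate_phenotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Phenotype records for the youngest generations of ``ped``.

    Returns the long-format record table (dog_id, trait, value,
    assessor, test_date, age_days, sex) and a truth dictionary with the
    latent breeding values, permanent-environment effects and latent
    liabilities used to generate it.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    t = cfg.n_traits
    ped = compute_inbreeding(ped) if np.any(np.isnan(ped.inbreeding)) else ped
    L = cholesky_factor(ped)
    n = len(ped)

    sd_a = np.sqrt(np.asarray(cfg.sigma2_a))
    G_full = np.outer(sd_a, sd_a) * cfg.g_corr
    cG = np.linalg.cholesky(G_full + 1e-12 * np.eye(t))
    U = L @ rng.standard_normal((n, t)) @ cG.T  # cov = A (x) G_full

    gens = _generation_of(ped)
    youngest = gens.max()
    tested = np.where(gens > youngest - cfg.phenotyped_generations)[0]

    pe = rng.standard_normal((n, t)) * np.sqrt(np.asarray(cfg.sigma2_pe))
    assess_eff = rng.standard_normal((cfg.n_assessors, t)) * np.sqrt(np.asarray(cfg.sigma2_as))

    sizes = np.array(sorted(cfg.records_per_dog))
    probs = np.array([cfg.records_per_dog[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()

    # pre-draw ages to standardize the slope on the realized distribution
    dog_rows = []
    for pos in tested:
        n_rec = int(rng.choice(sizes, p=probs))
        age = int(rng.integers(365, 1096))
        for k in range(n_rec):
            if k > 0:
                age += int(rng.integers(300, 701))
            dog_rows.append((pos, k, age))
    ages = np.array([a for _, _, a in dog_rows], dtype=float)
    age_scaled = (ages - ages.mean()) / ages.std(ddof=1)

    rows = []
    liab_truth = []
    # centre the liability on the expected fixed-effect mean (balanced sexes)
    # so the threshold-implied category probabilities are marginal
    mu = -0.5 * cfg.sex_effect
    for (pos, k, age), z_age in zip(dog_rows, age_scaled):
        rec = ped.records[pos]
        assessor = int(rng.integers(0, cfg.n_assessors))
        blank = rng.random() < cfg.missing_rate
        sex_term = mu + (cfg.sex_effect if rec.sex == "female" else 0.0)
        for trait in range(t):
            if rng.random() > cfg.record_prob[trait]:
                continue
            liab = (
                sex_term
                + cfg.age_slope * z_age
                + U[pos, trait]
                + pe[pos, trait]
                + assess_eff[assessor, trait]
                + rng.standard_normal() * np.sqrt(cfg.sigma2_e[trait])
            )
            probs_t = cfg.category_probs[trait]
            if probs_t is None:
                value = liab
            else:
                cuts = _thresholds(probs_t, cfg.total_sd(trait))
                value = int(np.searchsorted(cuts, liab))
            rows.append(
                {
                    "dog_id": rec.id,
                    "trait": f"trait{trait + 1}",
                    "value": value,
                    "assessor": "" if blank else f"A{assessor:03d}",
                    "test_date": (rec.dob + timedelta(days=int(age))).isoformat(),
                    "age_days": age,
                    "sex": rec.sex,
                }
            )
            liab_truth.append(liab)

    records = pd.DataFrame(rows)
    truth = {
        "u": U,
        "pe": pe,
        "assessor_effects": assess_eff,
        "liability": np.array(liab_truth),
        "tested_positions": tested,
        "g_full": G_full,
    }
    return records, truth


def write_fixture_bundle(ped: Pedigree, records: pd.DataFrame, out_dir) -> dict:
    """Write pedigree.csv and phenotypes.csv in the dialects the parsers read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped_path = out / "pedigree.csv"
    pheno_path = out / "phenotypes.csv"
    df = ped.to_dataframe().drop(columns=["colour_group", "f"])
    df.to_csv(ped_path, index=False)
    records.to_csv(pheno_path, index=False)
    return {"pedigree": ped_path, "phenotypes": pheno_path}
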