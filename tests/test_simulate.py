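"""Synthetic pedigree/phenotype generator: determinism, distributional
properties, round-trips, and the liability-transform attenuation.

The attenuation check compares the ordinal-pipeline heritability with
the closed-form prediction: coarsening a latent Gaussian into ordered
categories and replacing each by its conditional mean shrinks
cross-relative covariances by c^2 and the variance to c (c = sum of
p_j y_j^2), so the transform-then-linear-model estimand is
c*sigma_a^2 / (sigma_tot^2 - c*sigma_as^2) rather than the latent
ratio — a known, documented downward bias of the transform pipeline.
"""

import numpy as np
import pandas as pd
import pytest

from kennelquant.liability import grade_to_liability
from kennelquant.pedigree import (
    compute_inbreeding,
    parse_pedigree,
    tabular_relationship,
    trim_to_phenotyped,
    validate_and_correct,
)
from kennelquant.simulate import (
    DEFAULT_COLOUR_MAP,
    TRAIT1_PROBS,
    SimConfig,
    simulate_pedigree,
    simulate_phenotypes,
    two_trait_config,
    write_fixture_bundle,
)


class TestPedigreeGeneration:
    def test_zero_generations_founders_only(self):
        ped = simulate_pedigree(SimConfig(n_founders=20, n_generations=0, seed=1))
        assert len(ped) == 20
        assert all(r.sire_id is None and r.dam_id is None for r in ped.records)

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_founders=30, n_generations=2, generation_size=40, seed=5)
        a = simulate_pedigree(cfg)
        b = simulate_pedigree(cfg)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_valid_under_correction_with_empty_log(self):
        ped = simulate_pedigree(SimConfig(n_founders=40, n_generations=3, seed=2))
        _, log = validate_and_correct(ped)
        assert log == []

    def test_assortative_mating_correlates_spouse_merits(self):
        common = dict(n_founders=60, n_generations=3, generation_size=120, seed=12)
        corr = {}
        for mode in ("random", "assortative-by-ebv"):
            cfg = SimConfig(mating=mode, **common)
            ped, merit = simulate_pedigree(cfg, return_merits=True)
            pairs = {(r.sire_id, r.dam_id) for r in ped.records if r.sire_id and r.dam_id}
            sm = np.array([[merit[s], merit[d]] for s, d in pairs])
            corr[mode] = np.corrcoef(sm[:, 0], sm[:, 1])[0, 1]
        assert corr["assortative-by-ebv"] > 0.5
        assert abs(corr["random"]) < 0.35

    def test_mean_inbreeding_rises_across_generations(self):
        # aggregated over seeds: later generations accumulate ancestry overlap
        from kennelquant.simulate import _generation_of

        early, late = [], []
        for seed in range(10):
            cfg = SimConfig(n_founders=24, n_generations=4, generation_size=24, seed=seed)
            ped = compute_inbreeding(simulate_pedigree(cfg))
            gens = _generation_of(ped)
            f = ped.inbreeding
            early.append(f[gens <= 1].mean())
            late.append(f[gens >= 3].mean())
        assert np.mean(late) > np.mean(early)


class TestPhenotypeGeneration:
    def test_breeding_value_variance_matches_relationship_scale(self):
        cfg = SimConfig(n_founders=150, n_generations=3, generation_size=400, seed=3)
        ped = compute_inbreeding(simulate_pedigree(cfg))
        _, truth = simulate_phenotypes(ped, cfg)
        A = tabular_relationship(ped)
        u = truth["u"][:, 0]
        expected = np.mean(np.diag(A)) * cfg.sigma2_a[0]
        assert np.var(u) == pytest.approx(expected, rel=0.10)

    def test_category_frequencies_match_threshold_probabilities(self):
        cfg = SimConfig(n_founders=2600, n_generations=1, generation_size=2600,
                        phenotyped_generations=2, seed=4,
                        records_per_dog={1: 1.0}, sigma2_as=(0.30,))
        ped = compute_inbreeding(simulate_pedigree(cfg))
        recs, _ = simulate_phenotypes(ped, cfg)
        n = len(recs)
        assert n >= 5000
        freq = recs["value"].value_counts(normalize=True).sort_index()
        for j, p in enumerate(TRAIT1_PROBS):
            se = np.sqrt(p * (1 - p) / n)
            # fixed effects fatten the tails slightly; allow a few SEs
            assert abs(freq.get(j, 0.0) - p) < max(6 * se, 0.02)

    def test_no_genetic_or_shared_variance_gives_uncorrelated_sibs(self):
        cfg = SimConfig(n_founders=60, n_generations=2, generation_size=400,
                        sigma2_a=(1e-10,), sigma2_pe=(1e-10,), sigma2_as=(1e-10,),
                        sigma2_e=(1.0,), seed=6, records_per_dog={1: 1.0},
                        category_probs=(None,), phenotyped_generations=1)
        ped = compute_inbreeding(simulate_pedigree(cfg))
        recs, _ = simulate_phenotypes(ped, cfg)
        merged = recs.merge(
            pd.DataFrame({"dog_id": [r.id for r in ped.records],
                          "sire": [r.sire_id for r in ped.records]}),
            on="dog_id")
        pairs = []
        for _, g in merged.dropna(subset=["sire"]).groupby("sire"):
            if len(g) >= 2:
                pairs.append((g["value"].iloc[0], g["value"].iloc[1]))
        pairs = np.array(pairs, dtype=float)
        assert len(pairs) >= 20
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(pairs)) + 0.05  # no family resemblance

    def test_missing_assessor_rate(self):
        cfg = SimConfig(n_founders=100, n_generations=2, generation_size=800,
                        missing_rate=0.1, seed=7, phenotyped_generations=1)
        ped = compute_inbreeding(simulate_pedigree(cfg))
        recs, _ = simulate_phenotypes(ped, cfg)
        blank = (recs["assessor"] == "").mean()
        n = len(recs)
        assert abs(blank - 0.1) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_multitrait_records_share_events(self):
        cfg = two_trait_config(n_founders=40, n_generations=2, generation_size=60, seed=8)
        ped = compute_inbreeding(simulate_pedigree(cfg))
        recs, _ = simulate_phenotypes(ped, cfg)
        ev = recs.groupby(["dog_id", "test_date"])["trait"].nunique()
        assert (ev >= 1).all() and (ev <= 2).all()
        assert (ev == 2).any()


class TestFixtureBundle:
    def test_round_trip_and_deterministic_bytes(self, tmp_path):
        cfg = SimConfig(n_founders=30, n_generations=2, generation_size=30, seed=9)
        ped = compute_inbreeding(simulate_pedigree(cfg))
        recs, _ = simulate_phenotypes(ped, cfg)
        paths1 = write_fixture_bundle(ped, recs, tmp_path / "a")
        paths2 = write_fixture_bundle(ped, recs, tmp_path / "b")
        assert paths1["pedigree"].read_bytes() == paths2["pedigree"].read_bytes()
        reread = parse_pedigree(paths1["pedigree"], DEFAULT_COLOUR_MAP)
        assert reread.ids == ped.ids
        for rid in ped.ids[:10]:
            assert reread[rid].sire_id == ped[rid].sire_id
            assert reread[rid].dob == ped[rid].dob
            assert reread[rid].colour_group == ped[rid].colour_group
        pheno = pd.read_csv(paths1["phenotypes"], dtype={"dog_id": str}, keep_default_na=False)
        assert len(pheno) == len(recs)
        assert pheno["value"].tolist() == recs["value"].tolist()


def test_liability_round_trip_attenuation_matches_prediction():
    """Ordinal thresholding + transform biases h2 down by the closed-form
    attenuation factor; the fitted value tracks that estimand, not the
    latent truth."""
    from kennelquant.animal_model import (
        ModelSpec,
        build_design,
        heritability_repeatability,
        reml_fit,
    )

    cfg = SimConfig(n_founders=120, n_generations=4, generation_size=260,
                    phenotyped_generations=2, seed=21)
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, _ = simulate_phenotypes(ped, cfg)
    lmap, y = grade_to_liability(recs["value"].to_numpy())
    recs = recs.assign(liab=y)
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    spec = ModelSpec(response="liab", spline_knots=6)
    fit = reml_fit(build_design(recs, trimmed, spec), trimmed, spec)
    hr = heritability_repeatability(fit)

    c = float(np.sum(lmap.p * lmap.y**2))
    s_tot = cfg.total_sd(0) ** 2
    predicted = c * cfg.sigma2_a[0] / (s_tot - c * cfg.sigma2_as[0])
    latent_h2 = cfg.sigma2_a[0] / (cfg.sigma2_a[0] + cfg.sigma2_pe[0] + cfg.sigma2_e[0])
    assert predicted < latent_h2  # the bias is downward by construction
    assert abs(hr["h2"] - predicted) <= max(2 * hr["h2_se"], 0.1)
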