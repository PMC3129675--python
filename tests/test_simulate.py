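"""Generator correctness: determinism, Mendelian consistency, allele
frequencies, and the arithmetic of the expression and treatment models."""

import numpy as np
import pytest

from imprintscan.config import RunConfig
from imprintscan.normalization import allelic_fold, compute_beta
from imprintscan.pipeline import ae_points_by_sample, treatment_records_for_loci
from imprintscan.simulate import (
    SimConfig,
    simulate_expression_signals,
    simulate_panel,
    simulate_pedigree_genotypes,
    simulate_treatment,
)
from imprintscan.treatment import classify_treatment_effect, mbd_signal_compare


def test_same_seed_gives_identical_panels():
    sim1, rec1 = simulate_panel(SimConfig(rng_seed=42))
    sim2, rec2 = simulate_panel(SimConfig(rng_seed=42))
    assert [s.snp_id for s in sim1.snps] == [s.snp_id for s in sim2.snps]
    assert rec1 == rec2
    for ind in sim1.haplotypes:
        assert np.array_equal(sim1.haplotypes[ind], sim2.haplotypes[ind])
    assert sim1.transmissions == sim2.transmissions


def test_different_seeds_differ():
    _, rec1 = simulate_panel(SimConfig(rng_seed=1))
    _, rec2 = simulate_panel(SimConfig(rng_seed=2))
    assert rec1 != rec2


def test_founder_het_frequency_matches_hardy_weinberg():
    config = SimConfig(
        rng_seed=5, n_trios=60, include_three_generation=False,
        maf_range=(0.3, 0.3),
        n_loci={"biallelic": 20}, snps_per_locus=(10, 10),
    )
    sim = simulate_pedigree_genotypes(config)
    founders = [m.individual_id for m in sim.pedigree.founders()]
    hets = total = 0
    for ind in founders:
        hap = sim.haplotypes[ind]
        hets += int((hap[0] != hap[1]).sum())
        total += hap.shape[1]
    # 2pq = 0.42 at MAF 0.3; ~24,000 draws
    assert hets / total == pytest.approx(0.42, abs=0.02)


def test_children_are_mendelian_consistent(default_panel):
    sim, _ = default_panel
    for father, mother, child in sim.pedigree.trios():
        ch = sim.haplotypes[child.individual_id]
        fa = sim.haplotypes[father.individual_id]
        mo = sim.haplotypes[mother.individual_id]
        for truth in sim.loci:
            idx = [sim.snp_index[s] for s in truth.snp_ids]
            tf, tm = sim.transmissions[(child.individual_id, truth.locus_id)]
            assert np.array_equal(ch[0, idx], fa[tf, idx])
            assert np.array_equal(ch[1, idx], mo[tm, idx])


def test_noise_free_imprinted_locus_gives_eightfold_ae():
    config = SimConfig(
        rng_seed=3, n_trios=3, include_three_generation=False,
        n_loci={"imprinted_paternal": 2}, bias_coefficients=(0.0, 0.0, 0.0),
        beta_noise_sd=0.0, snps_per_locus=(6, 6),
    )
    sim = simulate_pedigree_genotypes(config)
    records = simulate_expression_signals(sim)
    run = RunConfig()
    by_key = {(r.sample_id, r.snp_id, r.assay): r for r in records}
    checked = 0
    for (sample, snp, assay), r in by_key.items():
        if assay != "cDNA" or r.genotype != "AB":
            continue
        g = by_key[(sample, snp, "gDNA")]
        if g.total <= run.intensity_threshold or r.total <= run.intensity_threshold:
            continue
        beta, _ = compute_beta(r.x_raw, r.y_raw)
        _, magnitude, _ = allelic_fold(beta, run)
        assert magnitude == pytest.approx(8.0, rel=1e-6)
        checked += 1
    assert checked > 20


def test_gdna_hets_recentre_after_normalization(default_panel):
    """The generator's bias is exactly what the normalization removes."""
    from imprintscan.normalization import beta_observation, fit_bias_curve, normalize_beta

    sim, records = default_panel
    run = RunConfig()
    obs = [
        beta_observation(r)
        for r in records
        if r.assay == "gDNA" and r.genotype == "AB" and r.total > 0
    ]
    curve = fit_bias_curve(obs, run)
    raw_medians = curve.bin_medians
    assert np.max(np.abs(raw_medians - 0.5)) > 0.01  # bias is visible pre-correction
    norm = np.array([
        normalize_beta(o.beta_obs, o.log_total, curve)
        for o in obs
        if o.log_total > curve.x_min
    ])
    assert abs(np.median(norm) - 0.5) < 0.01


def test_biallelic_loci_rarely_reach_extreme_fold(default_panel):
    sim, records = default_panel
    run = RunConfig()
    from imprintscan.normalization import beta_observation, fit_bias_curve

    curve = fit_bias_curve(
        [beta_observation(r) for r in records
         if r.assay == "gDNA" and r.genotype == "AB" and r.total > 0],
        run,
    )
    ae = ae_points_by_sample(records, curve, run)
    biallelic_snps = {
        s for t in sim.loci if t.locus_class == "biallelic" for s in t.snp_ids
    }
    mags = [
        p.magnitude
        for pts in ae.values()
        for p in pts.values()
        if p.informative and p.snp_id in biallelic_snps
    ]
    assert len(mags) > 500
    assert np.mean(np.array(mags) > run.extreme_fold) < 0.01


class TestTreatmentModel:
    def test_rme_magnitude_decays_toward_balance(self):
        config = SimConfig(
            rng_seed=9, n_trios=2, include_three_generation=False,
            n_loci={"rme": 3}, bias_coefficients=(0.0, 0.0, 0.0),
            beta_noise_sd=0.0, snps_per_locus=(5, 5), treatment_response=0.5,
        )
        sim = simulate_pedigree_genotypes(config)
        treated, _ = simulate_treatment(sim, timepoints=("5d", "10d"))
        run = RunConfig()

        def het_magnitudes(recs):
            out = []
            for r in recs:
                if r.assay == "cDNA" and r.genotype == "AB":
                    beta, _ = compute_beta(r.x_raw, r.y_raw)
                    out.append(allelic_fold(beta, run)[1])
            return out

        m5 = np.mean(het_magnitudes(treated["5d"]))
        m10 = np.mean(het_magnitudes(treated["10d"]))
        # silenced share 1/9 -> 0.306 at 5d (fold 2.27) -> 0.403 at 10d (1.48)
        assert m5 == pytest.approx((1 - 0.30556) / 0.30556, rel=1e-3)
        assert m10 == pytest.approx((1 - 0.40278) / 0.40278, rel=1e-3)
        assert 1.0 < m10 < m5 < 8.0

    def test_rme_enriched_among_affected_calls(self, default_panel):
        """End to end: treatment calls pick out RME, not imprinted/heritable."""
        from imprintscan.normalization import beta_observation, fit_bias_curve

        sim, records = default_panel
        run = RunConfig()
        rng = np.random.default_rng(77)
        children = [m.individual_id for m in sim.pedigree.children()]
        treated, _ = simulate_treatment(sim, rng=rng, individuals=children)
        curve = fit_bias_curve(
            [beta_observation(r) for r in records
             if r.assay == "gDNA" and r.genotype == "AB" and r.total > 0],
            run,
        )
        untreated_ae = ae_points_by_sample(records, curve, run)
        gdna = [r for r in records if r.assay == "gDNA"]
        treated_ae = {
            tp: ae_points_by_sample(list(recs) + gdna, curve, run)
            for tp, recs in treated.items()
        }
        locus_snp_ids = {t.locus_id: list(t.snp_ids) for t in sim.loci}
        recs = treatment_records_for_loci(untreated_ae, treated_ae, locus_snp_ids, children)
        calls = {lid: classify_treatment_effect(r, config=run) for lid, r in recs.items()}
        truth = sim.truth_by_id()
        affected_rme = sum(
            1 for lid, c in calls.items() if c.affected and truth[lid].locus_class == "rme"
        )
        affected_other = sum(
            1 for lid, c in calls.items() if c.affected and truth[lid].locus_class != "rme"
        )
        n_rme = sum(t.locus_class == "rme" for t in sim.loci)
        assert affected_rme >= 0.8 * n_rme
        # odds ratio of (affected | rme) vs (affected | other) clearly > 1
        unaffected_rme = n_rme - affected_rme
        unaffected_other = len(sim.loci) - n_rme - affected_other
        odds = (affected_rme * unaffected_other) / max(1, affected_other * unaffected_rme)
        assert odds > 1

    def test_mbd_truth_recovered(self, default_panel):
        sim, _ = default_panel
        rng = np.random.default_rng(123)
        _, mbd = simulate_treatment(sim, rng=rng, individuals=[])
        cmp = mbd_signal_compare(mbd.treated, mbd.untreated, RunConfig())
        assert cmp.fraction_decreased_among_changed > 0.95
        # changed sites are overwhelmingly the truly demethylated ones
        changed_dec = np.array([d == "decreased" for d in cmp.directions])
        assert (changed_dec & mbd.affected).sum() >= 0.9 * changed_dec.sum()
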