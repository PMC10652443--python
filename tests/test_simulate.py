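"""Tests for the synthetic-cohort generator: validation, determinism,
frequency recovery and the generative guarantees the analyses rely on."""

import numpy as np
import pytest
from scipy import stats as sps

from panelprofiler import (
    SimulationConfig,
    ValidationError,
    default_baseline_panel,
    simulate_cohort,
    simulate_locus_profiles,
    simulate_pileups,
)
from panelprofiler.simulate import TrueVariant

SITES_UNIFORM = {"duodenum": 0.4, "jejunum": 0.3, "ileum": 0.3}


def small_config(**kw):
    defaults = dict(
        n_patients=20, n_msi_loci=5, msi_locus_depth=50,
        n_ref_sites_per_patient=5, seed=123,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_zero_patients_rejected(self):
        with pytest.raises(ValidationError, match="n_patients"):
            SimulationConfig(n_patients=0)

    def test_site_probs_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="site_probs"):
            SimulationConfig(site_probs={"duodenum": 0.5, "jejunum": 0.4})

    def test_error_rate_range(self):
        with pytest.raises(ValidationError, match="error_rate"):
            SimulationConfig(error_rate=0.7)

    def test_af_range_within_unit_interval(self):
        with pytest.raises(ValidationError, match="true_af_range"):
            SimulationConfig(true_af_range=(0.0, 0.5))


class TestDeterminism:
    def test_same_config_and_seed_identical_outputs(self, tmp_path):
        from panelprofiler.io import write_maf_like, write_patients
        from panelprofiler.variants import VariantCall

        files = []
        for run in ("a", "b"):
            patients, pileups, profiles, truth = simulate_cohort(small_config())
            path = tmp_path / f"patients_{run}.tsv"
            write_patients(patients, path)
            maf = {
                pid: [
                    VariantCall(
                        gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref,
                        alt=v.alt, variant_type=v.variant_type,
                        functional_class=v.functional_class, af=v.true_af,
                        depth=0, alt_reads=0, popfreq=v.popfreq,
                        is_driver=v.is_driver,
                    )
                    for v in truth.variants[pid]
                ]
                for pid in truth.variants
            }
            mpath = tmp_path / f"maf_{run}.tsv"
            write_maf_like(maf, mpath)
            files.append((path.read_bytes(), mpath.read_bytes()))
        assert files[0] == files[1]

    def test_earlier_patients_stable_under_cohort_growth(self):
        """Counter-based sub-seeding: growing the cohort must not reshuffle
        already-generated patients."""
        small, *_ = simulate_cohort(small_config(n_patients=5))
        large, *_ = simulate_cohort(small_config(n_patients=15))
        assert [p.patient_id for p in small] == [p.patient_id for p in large[:5]]
        assert small == large[:5]

    def test_same_seed_identical_pileups(self):
        v = TrueVariant(
            gene="G", chrom="1", pos=100, ref="A", alt="T",
            variant_type="SNV", functional_class="missense", true_af=0.3,
        )
        a = simulate_pileups([v], 200, 0.01, seed=9, n_ref_sites=10)
        b = simulate_pileups([v], 200, 0.01, seed=9, n_ref_sites=10)
        assert a == b


class TestFrequencyRecovery:
    def test_gene_frequency_within_99pct_binomial_interval(self):
        """n=2000 patients with P(TP53 mutated)=0.53 everywhere: the empirical
        frequency must land inside the central 99% binomial interval."""
        cfg = SimulationConfig(
            n_patients=2000,
            gene_mut_probs={("TP53", s): 0.53 for s in SITES_UNIFORM},
            site_probs=SITES_UNIFORM,
            n_msi_loci=1, msi_locus_depth=2, n_ref_sites_per_patient=0,
            tmb_rate_by_msi={"MSI-H": 0.0, "MSS": 0.0},
            seed=42,
        )
        patients, *_ = simulate_cohort(cfg)
        hits = sum("TP53" in p.mutated_genes for p in patients)
        lo = sps.binom.ppf(0.005, 2000, 0.53)
        hi = sps.binom.ppf(0.995, 2000, 0.53)
        assert lo <= hits <= hi

    def test_patients_carry_metadata(self):
        patients, *_ = simulate_cohort(small_config())
        for p in patients:
            assert p.site in SITES_UNIFORM or p.site == "duodenum"
            assert p.sex in ("male", "female")
            assert 40.0 <= p.age <= 80.0
            assert p.pdl1_tps is None or 0.0 <= p.pdl1_tps <= 100.0


class TestLocusProfiles:
    PANEL = default_baseline_panel(100)

    def test_mss_tail_fraction_converges_to_baseline(self):
        """Law of large numbers: at depth 200k the observed fraction of reads
        beyond each cut-point approaches the baseline p_i."""
        profs = simulate_locus_profiles("MSS", 20, 200_000, self.PANEL, seed=2)
        for prof, base in zip(profs, self.PANEL[:20]):
            frac = prof.unstable_reads(base.cut_point) / prof.total_reads
            # 5-sigma band around p_i for a binomial proportion
            sigma = np.sqrt(base.p_i * (1 - base.p_i) / prof.total_reads)
            assert abs(frac - base.p_i) < 5 * sigma + 1e-9

    def test_unstable_fraction_one_shifts_all_loci(self):
        profs = simulate_locus_profiles(
            "MSI-H", 30, 500, self.PANEL, seed=3, unstable_fraction=1.0
        )
        for prof, base in zip(profs, self.PANEL[:30]):
            frac = prof.unstable_reads(base.cut_point) / prof.total_reads
            assert frac > base.p_i * 3  # well beyond the MSS expectation

    def test_zero_depth_rejected(self):
        with pytest.raises(ValidationError):
            simulate_locus_profiles("MSS", 10, 0, self.PANEL, seed=1)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValidationError):
            simulate_locus_profiles("MSS", 10, 100, self.PANEL[:3], seed=1)


class TestPileups:
    def test_error_rate_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_pileups([], 100, 0.6, seed=1)

    def test_no_variants_tiny_error_rate_no_alt_reads(self):
        piles = simulate_pileups([], 100, 1e-12, seed=1, n_ref_sites=50)
        assert all(r.alt_reads == 0 for r in piles)

    def test_observed_af_tracks_truth_at_high_depth(self):
        v = TrueVariant(
            gene="G", chrom="1", pos=100, ref="A", alt="T",
            variant_type="SNV", functional_class="missense", true_af=0.5,
        )
        piles = simulate_pileups([v], 10_000, 0.01, seed=4)
        assert 0.45 <= piles[0].af <= 0.55

    def test_strand_counts_recorded(self):
        v = TrueVariant(
            gene="G", chrom="1", pos=100, ref="A", alt="T",
            variant_type="SNV", functional_class="missense", true_af=0.4,
        )
        rec = simulate_pileups([v], 500, 0.01, seed=5)[0]
        assert rec.alt_fwd + rec.alt_rev == rec.alt_reads


class TestTruthConsistency:
    def test_every_truth_record_matches_one_patient(self):
        patients, pileups, profiles, truth = simulate_cohort(small_config())
        ids = {p.patient_id for p in patients}
        assert set(truth.msi_status) == ids
        assert set(truth.mutated_genes) == ids
        assert set(truth.variants) == ids
        assert set(pileups) == ids and set(profiles) == ids

    def test_msi_groups_differ_in_tmb(self):
        cfg = small_config(n_patients=60, seed=7)
        patients, *_ = simulate_cohort(cfg)
        msih = [p.tmb_per_mb for p in patients if p.msi_class == "MSI-H"]
        mss = [p.tmb_per_mb for p in patients if p.msi_class == "MSS"]
        if msih and mss:  # site mix is duodenum-heavy so MSI-H may be absent
            assert np.mean(msih) > np.mean(mss)
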