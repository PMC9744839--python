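"""Generator contracts: determinism, planted structure, referential integrity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, ks_2samp, kstest

from embryosplice.simulate import SimConfig, Simulator, generate_development, transcript_tpm
from tests.conftest import small_config


class TestConfig:
    def test_default_prenatal_count(self):
        sim = Simulator(SimConfig())
        n_pre = sum(1 for v in sim.pathway_labels.values() if v == "prenatal")
        assert n_pre == 30  # 60 pathways, frac 0.5

    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_ep": 0.6, "frac_en": 0.6},
            {"n_csf": 50, "n_sf": 40},
            {"n_timepoints_pre": 3, "n_timepoints_post": 4},
            {"n_genes": 0},
            {"frac_prenatal_pathways": 1.0},
            {"noise_sd": -1.0},
            {"n_genes": 10, "n_pathways": 5, "genes_per_pathway": 10},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_yaml_roundtrip_and_unknown_key(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_events: 100\nseed: 5\n")
        cfg = SimConfig.from_yaml(path)
        assert cfg.n_events == 100 and cfg.seed == 5
        path.write_text("not_a_knob: 1\n")
        with pytest.raises(ValueError, match="not_a_knob"):
            SimConfig.from_yaml(path)


class TestDeterminism:
    def test_development_bit_identical(self, sim_config):
        a = Simulator(sim_config).development()
        b = Simulator(sim_config).development()
        pd.testing.assert_frame_equal(a.expr, b.expr, check_exact=True)
        pd.testing.assert_frame_equal(a.psi, b.psi, check_exact=True)
        assert a.truth.exon_labels == b.truth.exon_labels

    def test_full_world_identical(self, sim_config):
        def build():
            sim = Simulator(sim_config)
            dev = sim.development()
            can = sim.cancer(dev.truth)
            reg = sim.regulatory(dev.truth)
            return dev, can, reg

        (d1, c1, r1), (d2, c2, r2) = build(), build()
        pd.testing.assert_frame_equal(c1.psi, c2.psi, check_exact=True)
        pd.testing.assert_frame_equal(c1.mutations, c2.mutations, check_exact=True)
        pd.testing.assert_frame_equal(r1.tf_expr, r2.tf_expr, check_exact=True)
        assert r1.binding == r2.binding

    def test_seed_changes_output(self, sim_config):
        a = Simulator(sim_config).development()
        b = Simulator(dataclasses.replace(sim_config, seed=99)).development()
        assert not a.expr.equals(b.expr)


class TestDevelopment:
    def test_value_ranges(self, dev_data):
        assert (dev_data.expr.to_numpy() >= 0).all()
        psi = dev_data.psi.to_numpy()
        assert ((psi >= 0) & (psi <= 1)).all()

    def test_noiseless_prenatal_activity_separation(self):
        cfg = small_config(noise_sd=0.0, psi_noise_sd=0.0, pathway_noise_sd=0.0)
        dev = generate_development(cfg)
        logx = np.log2(dev.expr + 1.0)
        pre = dev.meta.index[dev.meta["stage"] == "prenatal"]
        post = dev.meta.index[dev.meta["stage"] == "postnatal"]
        for pw, genes in dev.pathways.items():
            act = logx.loc[sorted(genes)].median(axis=0)
            if dev.truth.pathway_labels[pw] == "prenatal":
                assert act[pre].min() > act[post].max()
            else:
                assert act[post].min() > act[pre].max()

    def test_exon_label_partition(self, dev_data):
        labels = dev_data.truth.exon_labels
        assert set(labels) == set(dev_data.psi.index)
        n_ep = sum(1 for v in labels.values() if v == "EP")
        assert n_ep == round(0.15 * len(labels))


class TestCancer:
    def test_mutation_referential_integrity(self, world):
        dev, can, ann, reg = world
        tumor_ids = set(can.meta.index[can.meta["cohort"] == "tumor"])
        assert set(can.mutations["sample_id"]) <= tumor_ids
        for factor, samples in dev.truth.mutated_samples.items():
            assert samples <= tumor_ids
            assert factor in set(dev.truth.sf_ids)

    def test_cnv_values(self, world):
        _, can, _, _ = world
        assert set(np.unique(can.cnv.to_numpy())) <= {-1, 0, 1}

    def test_stage_tracks_reactivation(self, world):
        dev, can, _, _ = world
        r = dev.truth.sample_reactivation
        stages = can.meta.loc[r.index, "stage"]
        assert r[stages == "stage3"].mean() > r[stages == "stage1"].mean()

    def test_zero_reactivation_matches_normal_distribution(self):
        # pooled EP PSIs of tumors vs normals should be exchangeable when no
        # reactivation or mutations are planted.  Events within a sample
        # share latent expression noise, so the nominal KS p-value is
        # anti-conservative on pooled values; calibrate the KS statistic by
        # permuting cohort labels over samples instead.
        rng = np.random.default_rng(2024)
        fails = 0
        n_seeds = 30
        n_perm = 49
        for seed in range(n_seeds):
            cfg = small_config(
                seed=seed, reactivation_strength=0.0, n_mut_csf=0, n_mut_neg=0
            )
            sim = Simulator(cfg)
            truth = sim.development().truth
            can = sim.cancer(truth)
            ep = sorted(truth.events_with_label("EP"))
            tum = can.meta.index[can.meta["cohort"] == "tumor"].tolist()
            nor = can.meta.index[can.meta["cohort"] == "normal"].tolist()
            mat = can.psi.loc[ep, tum + nor].to_numpy()
            n_t = len(tum)

            def ks_stat(cols):
                return ks_2samp(
                    mat[:, cols[:n_t]].ravel(), mat[:, cols[n_t:]].ravel()
                ).statistic

            obs = ks_stat(np.arange(mat.shape[1]))
            null = [
                ks_stat(rng.permutation(mat.shape[1])) for _ in range(n_perm)
            ]
            p = (1 + sum(s >= obs for s in null)) / (1 + n_perm)
            fails += p < 0.02  # finest level resolvable with 49 permutations
        assert fails / n_seeds <= 0.05

    def test_all_drivers_mutated_noiseless_equals_normal(self):
        cfg = small_config(
            noise_sd=0.0, psi_noise_sd=0.0, pathway_noise_sd=0.0,
            mut_frac=1.0, n_mut_neg=0,
        )
        sim = Simulator(cfg)
        truth = sim.development().truth
        can = sim.cancer(truth)
        ep = sorted(truth.events_with_label("EP"))
        tum = can.meta.index[can.meta["cohort"] == "tumor"]
        nor = can.meta.index[can.meta["cohort"] == "normal"]
        med_t = can.psi.loc[ep, tum].median(axis=0)
        med_n = can.psi.loc[ep, nor].median(axis=0)
        np.testing.assert_allclose(med_t.to_numpy(), med_n.to_numpy()[0], atol=1e-12)

    def test_reactivation_monotone_in_strength(self):
        means = []
        for strength in (0.2, 0.5, 0.8):
            cfg = small_config(
                noise_sd=0.0, psi_noise_sd=0.0, pathway_noise_sd=0.0,
                reactivation_strength=strength, reactivation_cv=0.0,
                n_mut_csf=0, n_mut_neg=0,
            )
            sim = Simulator(cfg)
            truth = sim.development().truth
            can = sim.cancer(truth)
            ep = sorted(truth.events_with_label("EP"))
            tum = can.meta.index[can.meta["cohort"] == "tumor"]
            means.append(float(can.psi.loc[ep, tum].median(axis=0).mean()))
        assert means[0] < means[1] < means[2]


class TestAnnotation:
    def test_exon_within_host_gene(self, world):
        dev, can, ann, reg = world
        gene_start = {row["gene"]: row["tss"] for _, row in ann.tss.iterrows()}
        for ev in ann.events:
            start = gene_start[ev.gene_id]
            assert start <= ev.start < ev.end <= start + 8000

    def test_no_duplicate_domain_rows(self, world):
        _, _, ann, _ = world
        dup = ann.domain_bed.duplicated(subset=["name", "chrom", "start", "end"])
        assert not dup.any()

    def test_transcript_tpm_roundtrip(self, world):
        dev, _, ann, _ = world
        from embryosplice.psi import compute_psi

        tpm = transcript_tpm(ann, dev.psi, dev.expr)
        psi = compute_psi(tpm, ann.events, min_total_tpm=0)
        np.testing.assert_allclose(
            psi.to_numpy(), dev.psi.loc[psi.index, psi.columns].to_numpy(), atol=1e-9
        )


class TestRegulatory:
    def test_planted_tf_coverage(self, world):
        dev, _, _, reg = world
        truth = dev.truth
        targets = reg.binding[truth.planted_tf]
        cov_csf = len(targets & truth.csf_set) / len(truth.csf_set)
        cov_ncsf = len(targets & truth.ncsf_set) / len(truth.ncsf_set)
        assert cov_csf >= 0.8
        assert cov_ncsf <= 0.15

    def test_requires_cancer_first(self, sim_config):
        sim = Simulator(sim_config)
        truth = sim.development().truth
        with pytest.raises(ValueError, match="cancer"):
            sim.regulatory(truth)

    def test_decoy_targets_exchangeable_with_random_draws(self):
        # randomized-PIT of the decoy CSF-overlap count against the
        # hypergeometric null must be uniform across seeds
        rng = np.random.default_rng(123)
        pits = []
        for seed in range(200):
            cfg = small_config(
                seed=seed, n_genes=100, n_pathways=10, genes_per_pathway=5,
                n_events=50, n_sf=60, n_csf=15, n_driver_csf=2, n_mut_csf=2,
                n_mut_neg=1, n_neg_reg=2, n_kd_csf=2, n_kd_ncsf=3,
            )
            sim = Simulator(cfg)
            truth = sim.development().truth
            truth.sample_reactivation = pd.Series(
                0.5, index=[f"tumor_{i:03d}" for i in range(cfg.n_tumor)]
            )
            reg = sim.regulatory(truth)
            decoy = next(t for t in reg.binding if t != truth.planted_tf)
            targets = reg.binding[decoy]
            k = len(targets & truth.csf_set)
            m, big_k, n = cfg.n_sf, cfg.n_csf, len(targets)
            u = hypergeom.cdf(k - 1, m, big_k, n) + rng.random() * hypergeom.pmf(
                k, m, big_k, n
            )
            pits.append(u)
        assert kstest(pits, "uniform").pvalue > 0.01

    def test_noiseless_noncsf_knockdown_zero_delta(self):
        cfg = small_config(noise_sd=0.0, psi_noise_sd=0.0, pathway_noise_sd=0.0)
        sim = Simulator(cfg)
        truth = sim.development().truth
        truth.sample_reactivation = pd.Series(
            0.5, index=[f"tumor_{i:03d}" for i in range(cfg.n_tumor)]
        )
        reg = sim.regulatory(truth)
        ctrl_mean = reg.assay.control_psi.mean(axis=1)
        for factor, reps in reg.assay.kd_psi.items():
            if factor not in truth.csf_set:
                np.testing.assert_allclose(
                    reps.sub(ctrl_mean, axis=0).to_numpy(), 0.0, atol=1e-12
                )

    def test_kd_expression_meets_efficiency(self, world):
        dev, _, _, reg = world
        kd = reg.assay.kd_expr
        drop = 1 - kd[["kd_rep1", "kd_rep2"]].div(kd["control_mean"], axis=0)
        assert (drop >= 0.5).all().all()
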