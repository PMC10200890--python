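"""Synthetic-data generators: determinism, truth records, and the
statistical structure each downstream stage relies on."""

import io

import numpy as np
import pytest

import karyoploid as kp
from karyoploid.dstat import QuartetSpec, jackknife
from karyoploid.karyotype import KaryotypeError, canonical_form
from karyoploid.simulate import (
    SimConfig,
    expected_quartet_d,
    make_cluster_genotypes,
    random_scenario,
    simulate_allele_counts,
    simulate_quartet_snps,
    write_site_counts_tsv,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ploidy": 5},
            {"mean_depth": 0},
            {"base_error": 0.7},
            {"gamma": 1.5},
            {"k_events": -1},
            {"ploidy": 4, "dosage_probs": {1: 0.5, 2: 0.2}},
            {"ploidy": 2, "dosage_probs": {3: 1.0}},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestAlleleCounts:
    def test_seed_determinism_byte_identical(self):
        out = []
        for _ in range(2):
            df, _ = simulate_allele_counts(SimConfig(seed=42, n_sites=500))
            buf = io.StringIO()
            write_site_counts_tsv(df, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]
        df2, _ = simulate_allele_counts(SimConfig(seed=43, n_sites=500))
        buf = io.StringIO()
        write_site_counts_tsv(df2, buf)
        assert buf.getvalue() != out[0]

    def test_diploid_no_error_centred(self):
        cfg = SimConfig(seed=1, ploidy=2, base_error=0.0, n_sites=3000)
        df, truth = simulate_allele_counts(cfg)
        f = df["alt_reads"] / (df["ref_reads"] + df["alt_reads"])
        assert abs(f.mean() - 0.5) < 0.01
        assert truth["ploidy"] == 2
        assert set(truth["dosages"]) == {1}

    def test_tetraploid_modes(self):
        cfg = SimConfig(seed=2, ploidy=4, n_sites=6000)
        df, truth = simulate_allele_counts(cfg)
        f = (df["alt_reads"] / (df["ref_reads"] + df["alt_reads"])).to_numpy()
        d = np.array(truth["dosages"])
        for dosage, centre in ((1, 0.25), (2, 0.5), (3, 0.75)):
            assert abs(f[d == dosage].mean() - centre) < 0.02

    def test_coverage_always_positive(self):
        df, _ = simulate_allele_counts(
            SimConfig(seed=3, mean_depth=3, overdispersion=0.5, n_sites=2000)
        )
        assert (df["ref_reads"] + df["alt_reads"]).min() >= 1


class TestQuartets:
    def test_closed_form(self):
        assert expected_quartet_d(SimConfig(gamma=0.0)) == 0.0
        assert expected_quartet_d(SimConfig(gamma=0.2, b=0.1)) == pytest.approx(0.5)

    def test_null_d_near_zero(self):
        m, truth = simulate_quartet_snps(SimConfig(seed=7, n_sites=20_000))
        r = jackknife(m, QuartetSpec("P1", "P2", "P3", "O"), block_size=500)
        se = abs(r.d / r.z) if r.z else 0.01
        assert abs(r.d) < 3 * se + 1e-9

    def test_mean_d_matches_closed_form(self):
        # E[D] = 0.5 when gamma = 2b; average over 10 seeds, so a single
        # tail draw cannot fail the check
        devs, ses = [], []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_sites=20_000, gamma=0.2, b=0.1)
            m, truth = simulate_quartet_snps(cfg)
            r = jackknife(m, QuartetSpec("P1", "P2", "P3", "O"),
                          block_size=500)
            devs.append(r.d - truth["expected_D"])
            ses.append(r.d / r.z)
        mean_se = float(np.mean(ses)) / np.sqrt(len(devs))
        assert abs(float(np.mean(devs))) < 3 * mean_se

    def test_jackknife_se_scales_with_n(self):
        ses = {}
        for n in (10_000, 40_000):
            cfg = SimConfig(seed=11, n_sites=n, gamma=0.2, b=0.1)
            m, _ = simulate_quartet_snps(cfg)
            r = jackknife(m, QuartetSpec("P1", "P2", "P3", "O"),
                          block_size=500)
            ses[n] = r.d / r.z
        ratio = ses[10_000] / ses[40_000]
        assert 1.4 < ratio < 2.9  # quadrupling sites should halve the SE

    def test_outgroup_always_ancestral(self):
        m, _ = simulate_quartet_snps(SimConfig(seed=8, n_sites=1000))
        assert (m["O"] == 0).all()


class TestRandomScenario:
    def test_zero_events_identity(self, ack):
        scn, end = random_scenario(SimConfig(seed=1, k_events=0), ack)
        assert scn.events == ()
        assert end.same_as(ack, copy_blind=False)

    def test_single_inversion_changes_one_chromosome(self, ack):
        cfg = SimConfig(seed=5, k_events=1, allowed_operators=("PERI_INV",))
        scn, end = random_scenario(cfg, ack)
        before = {canonical_form(c) for c in ack.chromosomes}
        after = {canonical_form(c) for c in end.chromosomes}
        assert len(before - after) == 1 and len(after - before) == 1

    def test_scenario_replays_to_end(self, ack):
        scn, end = random_scenario(SimConfig(seed=6, k_events=3), ack)
        replayed, _ = kp.replay(scn, start=ack)
        assert replayed.same_as(end, copy_blind=False)

    def test_impossible_event_reported(self):
        single = kp.Karyotype((kp.build_ack().chromosomes[0],))
        cfg = SimConfig(seed=1, k_events=1, allowed_operators=("EET",))
        with pytest.raises(KaryotypeError, match="1000 rejections"):
            random_scenario(cfg, single)


class TestClusterGenotypes:
    def test_requested_structure(self):
        table, extra = make_cluster_genotypes(
            shared=50, unique={"I": 10, "II": 5}, singletons=3, seed=0
        )
        assert table.shape == (12, 68)
        truth = extra["truth"]
        assert truth["shared"] == 50 and truth["singletons"] == 3
        carriers = table.sum(axis=0)
        members = truth["membership"]
        assert sum(1 for v in members.values() if v == "singleton") == 3
        for snp, kind in members.items():
            if kind == "singleton":
                assert carriers[snp] == 1
            else:
                assert carriers[snp] >= 2

    def test_all_shared_request(self):
        table, extra = make_cluster_genotypes(
            shared=20, unique={"I": 0, "II": 0}, singletons=0, seed=1
        )
        members = set(extra["truth"]["membership"].values())
        assert members == {"shared"}

    def test_seeds_change_placement_not_counts(self):
        t1, e1 = make_cluster_genotypes(30, {"I": 4, "II": 2}, 2, seed=1)
        t2, e2 = make_cluster_genotypes(30, {"I": 4, "II": 2}, 2, seed=2)
        assert not t1.equals(t2)
        assert e1["truth"]["shared"] == e2["truth"]["shared"]

    def test_inconsistent_request_rejected(self):
        with pytest.raises(ValueError):
            make_cluster_genotypes(5, {"I": 1, "II": 0}, 0, n_per_cluster=1)
        with pytest.raises(ValueError):
            make_cluster_genotypes(-1, {"I": 0, "II": 0}, 0)
        with pytest.raises(ValueError):
            make_cluster_genotypes(5, {"I": 1}, 0)
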