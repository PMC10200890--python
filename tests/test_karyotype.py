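"""Karyotype model: ACK construction, rearrangement operators,
canonicalization, replay and serialization."""

import pytest

import karyoploid as kp
from karyoploid.karyotype import (
    Breakpoint,
    Chromosome,
    ConfigError,
    KaryotypeError,
    Segment,
    canonical_form,
    cp13_private_inversion_scenario,
    normalize_chromosome,
    reverse_chromosome,
)


def labels_or_reverse(k, name, expected):
    """Block-label reading of a chromosome in either direction."""
    got = list(k.labels(k.get(name)))
    return got == expected or got[::-1] == expected


class TestACK:
    def test_eight_chromosomes(self, ack):
        assert ack.n == 8
        assert ack.two_n == 16

    def test_all_blocks_single_copy(self, ack):
        cov = ack.block_coverage()
        assert len(cov) == 22
        assert all(copy == 1 for (_b, copy) in cov)
        assert all(abs(v - 1.0) < 1e-12 for v in cov.values())

    def test_ak5_arms(self, ack):
        ak5 = ack.get("AK5")
        assert [s.block for s in ak5.segments] == ["K-L", "M-N"]
        assert ak5.cen == 1

    def test_malformed_table_rejected(self, tmp_path):
        bad = tmp_path / "ack.tsv"
        bad.write_text("AK1\tA,B\tC\n")  # misses 19 blocks
        with pytest.raises(ConfigError):
            kp.build_ack(bad)


class TestWGD:
    def test_doubles_complement(self, ack, post_wgd):
        assert post_wgd.n == 16
        assert post_wgd.two_n == 32

    def test_every_block_two_copies(self, post_wgd):
        per_block = kp.summarize(post_wgd)["block_copy_numbers"]
        assert set(per_block.values()) == {2}

    def test_rejects_polyploid_input(self, post_wgd):
        with pytest.raises(KaryotypeError):
            kp.apply_wgd(post_wgd)

    def test_single_chromosome_toy(self):
        toy = kp.Karyotype(
            (
                Chromosome(
                    "t",
                    (Segment("D", 1, 0.0, 1.0, 1), Segment("E", 1, 0.0, 1.0, 1)),
                    1,
                ),
            )
        )
        doubled = kp.apply_wgd(toy)
        assert doubled.n == 2
        a, b = doubled.chromosomes
        assert canonical_form(a) == canonical_form(b)
        assert canonical_form(a, copy_blind=False) != canonical_form(
            b, copy_blind=False
        )


class TestEET:
    def test_fusion_composition(self, post_wgd):
        k = kp.apply_eet(post_wgd, "AK7b", "head", "AK5b", "head", "AK5b",
                         name="fusion")
        assert k.n == 15
        assert k.two_n == 30
        assert labels_or_reverse(k, "fusion", ["U", "T", "S", "K-L", "M-N"])
        fusion = k.get("fusion")
        # the AK5 centromere sits between (K-L) and (M-N)
        reading = list(k.labels(fusion, with_cen=True))
        if reading[0] != "U":
            reading = reading[::-1]
        assert reading == ["U", "T", "S", "K-L", "CEN", "M-N"]
        assert any("AK7b" in h for h in fusion.history)

    def test_operand_symmetry(self, post_wgd):
        k1 = kp.apply_eet(post_wgd, "AK7b", "head", "AK5b", "head", "AK5b")
        k2 = kp.apply_eet(post_wgd, "AK5b", "head", "AK7b", "head", "AK5b")
        assert k1.same_as(k2, copy_blind=False)

    def test_keep_centromere_validation(self, post_wgd):
        with pytest.raises(KaryotypeError):
            kp.apply_eet(post_wgd, "AK7b", "head", "AK5b", "head", "AK1a")

    def test_block_content_conserved(self, post_wgd):
        k = kp.apply_eet(post_wgd, "AK7b", "head", "AK5b", "head", "AK5b")
        assert k.content_multiset() == post_wgd.content_multiset()


@pytest.fixture(scope="module")
def with_fusion(post_wgd):
    return kp.apply_eet(
        post_wgd, "AK7b", "head", "AK5b", "head", "AK5b", name="fusion"
    )


class TestReciprocalTranslocation:
    def test_cp15_products(self, with_fusion):
        k = kp.apply_reciprocal_translocation(
            with_fusion,
            Breakpoint("AK3b", "F", 0.5),
            Breakpoint("fusion", "T", 1.0),
            names=("U+Fb+G+H", "Cp15"),
        )
        assert labels_or_reverse(k, "Cp15", ["Fa", "T", "S", "K-L", "M-N"])
        assert labels_or_reverse(k, "U+Fb+G+H", ["U", "Fb", "G", "H"])
        assert k.composition(k.get("Cp15")) in (
            "Fa+T+S+(K-L)+(M-N)", "(M-N)+(K-L)+S+T+Fa"
        )

    def test_argument_order_symmetry(self, with_fusion):
        k1 = kp.apply_reciprocal_translocation(
            with_fusion, Breakpoint("AK3b", "F", 0.5),
            Breakpoint("fusion", "T", 1.0),
        )
        k2 = kp.apply_reciprocal_translocation(
            with_fusion, Breakpoint("fusion", "T", 1.0),
            Breakpoint("AK3b", "F", 0.5),
        )
        assert k1.same_as(k2, copy_blind=False)

    def test_empty_fragments_identity(self, post_wgd):
        k = kp.apply_reciprocal_translocation(
            post_wgd, Breakpoint("AK1a", end="tail"),
            Breakpoint("AK2a", end="tail"),
        )
        assert k.same_as(post_wgd, copy_blind=False)

    def test_content_conserved(self, with_fusion):
        k = kp.apply_reciprocal_translocation(
            with_fusion, Breakpoint("AK3b", "F", 0.5),
            Breakpoint("fusion", "T", 1.0),
        )
        assert (
            sorted(k.block_coverage().items())
            == sorted(with_fusion.block_coverage().items())
        )


class TestUnequalTranslocation:
    def test_cp12_cp13(self, post_wgd):
        k = kp.apply_unequal_translocation(
            post_wgd, Breakpoint("AK1b", "A", 0.5), "AK6b", "head",
            names=("Cp12", "Cp13"),
        )
        assert labels_or_reverse(k, "Cp12", ["Ab", "B", "C"])
        assert labels_or_reverse(k, "Cp13", ["Aa", "O", "P", "Q", "R"])

    def test_empty_donation_is_identity(self, post_wgd):
        k = kp.apply_unequal_translocation(
            post_wgd, Breakpoint("AK1a", end="head"), "AK2a", "head"
        )
        assert k.same_as(post_wgd, copy_blind=False)

    def test_palindromic_target_head_tail_equivalent(self):
        # copy-blind palindrome: D@1+ | cen | D@2- reads the same reversed
        palin = Chromosome(
            "p", (Segment("D", 1, 0.0, 1.0, 1), Segment("D", 2, 0.0, 1.0, -1)), 1
        )
        donor = Chromosome(
            "d", (Segment("E", 1, 0.0, 1.0, 1), Segment("F", 1, 0.0, 1.0, 1)), 1
        )
        k = kp.Karyotype((palin, donor))
        heads = kp.apply_unequal_translocation(
            k, Breakpoint("d", "F", 0.5), "p", "head"
        )
        tails = kp.apply_unequal_translocation(
            k, Breakpoint("d", "F", 0.5), "p", "tail"
        )
        assert heads.same_as(tails)


class TestPericentricInversion:
    def test_cp14(self, with_fusion):
        k = kp.apply_reciprocal_translocation(
            with_fusion, Breakpoint("AK3b", "F", 0.5),
            Breakpoint("fusion", "T", 1.0), names=("pre14", "Cp15"),
        )
        k = kp.apply_pericentric_inversion(
            k, "pre14", Breakpoint("pre14", "F", 0.75),
            Breakpoint("pre14", "H", 0.5), name="Cp14",
        )
        assert labels_or_reverse(k, "Cp14", ["U", "Fb", "Ha", "G", "Fc", "Hb"])

    def test_cp11(self, post_wgd):
        k = kp.apply_pericentric_inversion(
            post_wgd, "AK1a", Breakpoint("AK1a", "A", 0.5),
            Breakpoint("AK1a", "C", 0.5), name="Cp11",
        )
        assert labels_or_reverse(k, "Cp11", ["Aa", "Ca", "B", "Ab", "Cb"])

    def test_involution(self, post_wgd):
        k1 = kp.apply_pericentric_inversion(
            post_wgd, "AK1a", Breakpoint("AK1a", "A", 0.5),
            Breakpoint("AK1a", "C", 0.5), name="inv",
        )
        k2 = kp.apply_pericentric_inversion(
            k1, "inv",
            Breakpoint("inv", "A", 0.5, occurrence=0),
            Breakpoint("inv", "C", 0.5, occurrence=1),
        )
        assert k2.same_as(post_wgd)

    def test_not_pericentric_rejected(self, post_wgd):
        with pytest.raises(KaryotypeError, match="not pericentric"):
            kp.apply_pericentric_inversion(
                post_wgd, "AK6a", Breakpoint("AK6a", "Q", 0.5),
                Breakpoint("AK6a", "R", 0.5),
            )

    def test_centromere_breakpoint_rejected(self, post_wgd):
        with pytest.raises(KaryotypeError):
            kp.apply_reciprocal_translocation(
                post_wgd,
                Breakpoint("AK5a", "K-L", 1.0),  # the centromere gap
                Breakpoint("AK1a", "A", 0.5),
            )


class TestCanonicalForm:
    def test_reversal_invariance(self, catolobus):
        for c in catolobus.chromosomes:
            assert canonical_form(c) == canonical_form(reverse_chromosome(c))

    def test_orientation_patterns_differ(self):
        # a 3-segment toy: not all orientation patterns are one chromosome
        base = [Segment(b, 1, 0.0, 1.0, 1) for b in ("D", "E", "F")]
        forms = set()
        for o1 in (1, -1):
            for o2 in (1, -1):
                for o3 in (1, -1):
                    segs = (
                        base[0]._replace(orient=o1),
                        base[1]._replace(orient=o2),
                        base[2]._replace(orient=o3),
                    )
                    forms.add(canonical_form(Chromosome("t", segs, 1)))
        # block order D,E,F is asymmetric, so no two orientation patterns
        # are reversals of each other: all 8 canonical forms are distinct
        assert len(forms) == 8

    def test_trivial_cut_merged(self):
        whole = Chromosome(
            "w", (Segment("D", 1, 0.0, 1.0, 1), Segment("E", 1, 0.0, 1.0, 1)), 1
        )
        cut = Chromosome(
            "c",
            (
                Segment("D", 1, 0.0, 1.0, 1),
                Segment("E", 1, 0.0, 0.5, 1),
                Segment("E", 1, 0.5, 1.0, 1),
            ),
            1,
        )
        assert canonical_form(whole) == canonical_form(cut)
        assert normalize_chromosome(cut).segments == whole.segments


class TestReplayAndScenario:
    def test_final_karyotype(self, catolobus_snapshots):
        final, snaps = catolobus_snapshots
        assert final.n == 15
        assert snaps[0].two_n == 32
        assert snaps[1].n == 15

    def test_event_kind_multiset(self):
        from collections import Counter

        kinds = Counter(e.kind for e in kp.catolobus_scenario().events)
        assert kinds == Counter(
            {"WGD": 1, "EET": 1, "RECIP_TRANSLOC": 1, "PERI_INV": 2,
             "UNEQ_TRANSLOC": 1}
        )

    def test_ten_of_fifteen_mirror_ancestral(self, ack, catolobus):
        from collections import Counter

        ref = Counter(canonical_form(c) for c in ack.chromosomes)
        mirrored = sum(
            1 for c in catolobus.chromosomes if canonical_form(c) in ref
        )
        assert mirrored == 10

    def test_truncated_scenario_contains_fusion(self):
        scen = kp.catolobus_scenario()
        truncated = kp.Scenario(scen.events[:2], start="ACK")
        k, _ = kp.replay(truncated)
        assert k.n == 15
        fusion = k.get("AK5/7b")
        assert labels_or_reverse(k, "AK5/7b", ["U", "T", "S", "K-L", "M-N"])

    def test_empty_scenario_identity(self, ack):
        k, snaps = kp.replay(kp.Scenario((), start="ACK"))
        assert k.same_as(ack, copy_blind=False)
        assert snaps == []

    def test_replay_deterministic_byte_identical(self):
        a, _ = kp.replay(kp.catolobus_scenario())
        b, _ = kp.replay(kp.catolobus_scenario())
        assert kp.karyotype_to_json(a) == kp.karyotype_to_json(b)

    def test_error_carries_step_index(self, ack):
        bad = kp.Scenario(
            (kp.RearrangementEvent("EET", {
                "chr_a": "nope", "end_a": "head", "chr_b": "AK1",
                "end_b": "head", "keep_centromere_of": "AK1"}),),
            start="ACK",
        )
        with pytest.raises(KaryotypeError, match="step 0"):
            kp.replay(bad)

    def test_cp13_private_inversion(self, catolobus):
        k, _ = kp.replay(cp13_private_inversion_scenario(), start=catolobus)
        assert k.n == 15
        assert not k.same_as(catolobus)

    def test_conservation_across_random_scenarios(self, ack):
        from karyoploid.simulate import SimConfig, random_scenario

        for seed in range(6):
            _scn, end = random_scenario(
                SimConfig(seed=seed, k_events=3), ack
            )
            assert (
                sorted(end.block_coverage().items())
                == sorted(ack.block_coverage().items())
            )
            for c in end.chromosomes:
                c.validate()


class TestSummarize:
    def test_affected_six(self, post_wgd, catolobus):
        s = kp.summarize(catolobus, post_wgd)
        assert s["affected"] == 6
        assert s["total_block_copies"] == 44
        assert s["n"] == 15 and s["2n"] == 30

    def test_self_reference_zero(self, catolobus):
        assert kp.summarize(catolobus, catolobus)["affected"] == 0


class TestSerialization:
    def test_karyotype_round_trip_bit_exact(self, catolobus):
        text = kp.karyotype_to_json(catolobus)
        again = kp.karyotype_to_json(kp.karyotype_from_json(text))
        assert text == again

    def test_scenario_round_trip_bit_exact(self):
        text = kp.scenario_to_json(kp.catolobus_scenario())
        again = kp.scenario_to_json(kp.scenario_from_json(text))
        assert text == again

    def test_packaged_fixture_matches_replay(self, catolobus):
        from importlib import resources

        text = (
            resources.files("karyoploid.data")
            .joinpath("cp_karyotype.json")
            .read_text()
        )
        fixture = kp.karyotype_from_json(text)
        assert fixture.same_as(catolobus, copy_blind=False)

    def test_rejects_two_centromeres(self):
        text = kp.karyotype_to_json(kp.build_ack()).replace(
            '"CEN",', '"CEN",\n   "CEN",', 1
        )
        with pytest.raises(ConfigError):
            kp.karyotype_from_json(text)

    def test_rejects_wrong_format(self):
        with pytest.raises(ConfigError):
            kp.karyotype_from_json('{"format": "something-else"}')
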