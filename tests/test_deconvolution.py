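import numpy as np
import pytest

from lumipanel.deconvolution import (
    InferenceError,
    PriorTable,
    call_sample,
    concordance,
    consistent,
    infer_bead,
    infer_hla,
    oracle_infer,
)
from lumipanel.panel_model import (
    ANTI_HLA,
    Bead,
    Donor,
    DonorPanel,
    HpaGenotype,
    Specificity,
)
from lumipanel.reactivity import call_reactivity


def random_instance(rng, n_systems=3, n_donors=4):
    """Random genotyped panel + random reactivity partition for one bead."""
    systems = tuple(f"HPA-{i + 1}" for i in range(n_systems))
    donors = tuple(
        Donor(
            f"D{j}",
            {
                s: HpaGenotype(s, ("aa", "ab", "bb")[rng.integers(3)])
                for s in systems
            },
        )
        for j in range(n_donors)
    )
    panel = DonorPanel(donors)
    bead = Bead("B", "LC-TEST", "GP-TEST", systems=systems, role="hpa_capture")
    mask = rng.integers(0, 2, size=n_donors).astype(bool)
    reactive = frozenset(d.donor_id for d, m in zip(donors, mask) if m)
    nonreactive = frozenset(d.donor_id for d in donors) - reactive
    return panel, bead, reactive, nonreactive


class TestConsistent:
    def test_sole_noncarrier_pattern(self, donor_panel, gp2b3a):
        # G3 is the only donor not carrying HPA-3a; anti-HPA-3a explains
        # reactivity of everyone else with G3 silent
        spec = {Specificity.hpa("HPA-3", "a")}
        assert consistent(
            spec, gp2b3a, {"G1", "G2", "G4"}, {"G3"}, donor_panel
        )

    def test_violated_by_nonreactive_carrier(self, donor_panel, gp2b3a):
        # every donor carries HPA-1a, so a non-reactive G3 refutes anti-HPA-1a
        spec = {Specificity.hpa("HPA-1", "a")}
        assert not consistent(
            spec, gp2b3a, {"G1", "G2", "G4"}, {"G3"}, donor_panel
        )

    def test_empty_pattern_empty_explanation(self, donor_panel, gp2b3a):
        assert consistent(set(), gp2b3a, set(), {"G1", "G2", "G3", "G4"}, donor_panel)


class TestInferBead:
    def test_sole_carrier_resolves_uniquely(self, donor_panel, bead_panel, priors):
        # G4 is the only HPA-5b carrier
        bead = bead_panel.bead("GPIaIIa")
        ranked = infer_bead(
            bead, frozenset({"G4"}), frozenset({"G1", "G2", "G3"}),
            donor_panel, priors,
        )
        assert [r.labels for r in ranked] == [("anti-HPA-5b",)]

    def test_all_reactive_ambiguity_resolved_by_prior(
        self, donor_panel, gp2b3a, priors
    ):
        # all donors are HPA-1aa and HPA-4aa: both singletons consistent,
        # anti-HPA-1a must outrank anti-HPA-4a
        ranked = infer_bead(
            gp2b3a, frozenset({"G1", "G2", "G3", "G4"}), frozenset(),
            donor_panel, priors,
        )
        singles = [r.labels for r in ranked if r.cardinality == 1]
        assert ("anti-HPA-1a",) in singles and ("anti-HPA-4a",) in singles
        assert ranked[0].labels == ("anti-HPA-1a",)

    def test_inexplicable_pattern_yields_empty(self, donor_panel, gp2b3a, priors):
        # a lone reactive G3 cannot be explained: every allele G3 carries is
        # also carried by a non-reactive donor
        ranked = infer_bead(
            gp2b3a, frozenset({"G3"}), frozenset({"G1", "G2", "G4"}),
            donor_panel, priors,
        )
        assert ranked == []

    def test_no_reactivity_yields_empty(self, donor_panel, gp2b3a):
        assert infer_bead(
            gp2b3a, frozenset(), frozenset({"G1", "G2", "G3", "G4"}), donor_panel
        ) == []

    def test_reported_sets_are_minimal_and_sound(self, donor_panel, gp2b3a, priors):
        ranked = infer_bead(
            gp2b3a, frozenset({"G1", "G3", "G4"}), frozenset({"G2"}),
            donor_panel, priors, max_set_size=6,
        )
        for r in ranked:
            assert consistent(
                r.specificities, gp2b3a, {"G1", "G3", "G4"}, {"G2"}, donor_panel
            )
            for other in ranked:
                assert not other.specificities < r.specificities

    def test_bad_max_set_size(self, donor_panel, gp2b3a):
        with pytest.raises(InferenceError):
            infer_bead(gp2b3a, frozenset({"G1"}), frozenset(), donor_panel,
                       max_set_size=0)

    def test_hla_bead_rejected(self, donor_panel, bead_panel):
        with pytest.raises(InferenceError):
            infer_bead(bead_panel.bead("HLA"), frozenset({"G1"}), frozenset(),
                       donor_panel)


class TestOracle:
    def test_oracle_matches_on_clinical_patterns(
        self, donor_panel, bead_panel, clinical_mfi, clinical_cutoffs, priors
    ):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        for bead in bead_panel.active_hpa:
            for sample_id in clinical_mfi.sample_ids:
                cell = pattern.get(sample_id, bead.bead_id)
                fast = infer_bead(
                    bead, cell.reactive, cell.nonreactive, donor_panel,
                    priors, max_set_size=6,
                )
                slow = oracle_infer(
                    bead, cell.reactive, cell.nonreactive, donor_panel, priors
                )
                assert [r.specificities for r in fast] == [
                    r.specificities for r in slow
                ]

    def test_oracle_equivalence_random_instances(self, priors):
        rng = np.random.default_rng(20240917)
        for _ in range(300):
            panel, bead, reactive, nonreactive = random_instance(
                rng, n_systems=int(rng.integers(1, 4)),
                n_donors=int(rng.integers(4, 7)),
            )
            fast = infer_bead(
                bead, reactive, nonreactive, panel, priors,
                max_set_size=2 * len(bead.systems),
            )
            slow = oracle_infer(bead, reactive, nonreactive, panel, priors)
            assert [r.specificities for r in fast] == [r.specificities for r in slow]

    def test_oracle_bound_enforced(self, donor_panel):
        wide = Bead(
            "W", "LC-W", "GP-W",
            systems=tuple(f"HPA-{i}" for i in range(1, 8)),  # 14 candidates
            role="hpa_capture",
        )
        with pytest.raises(InferenceError, match="bound"):
            oracle_infer(wide, frozenset({"G1"}), frozenset(), donor_panel)

    def test_monotone_ambiguity_when_removing_donors(self):
        # dropping a donor (and its evidence) can only enlarge the family of
        # consistent candidate sets
        rng = np.random.default_rng(7)
        for _ in range(100):
            panel, bead, reactive, nonreactive = random_instance(rng)
            full = {
                r.specificities
                for r in oracle_infer(bead, reactive, nonreactive, panel)
            }
            victim = panel.donor_ids[int(rng.integers(len(panel)))]
            reduced_panel = panel.without(victim)
            reduced_reactive = reactive - {victim}
            reduced_nonreactive = nonreactive - {victim}
            # every consistent set stays consistent with one donor's
            # evidence removed — constraints only ever disappear
            for specs in full:
                assert consistent(
                    specs, bead, reduced_reactive, reduced_nonreactive,
                    reduced_panel,
                )
            if reduced_reactive:
                reduced = {
                    r.specificities
                    for r in oracle_infer(
                        bead, reduced_reactive, reduced_nonreactive, reduced_panel
                    )
                }
                # and each formerly-minimal set now has a (possibly smaller)
                # minimal representative
                for specs in full:
                    assert any(s <= specs for s in reduced)


class TestInferHla:
    def test_partial_reactivity_is_positive(
        self, clinical_mfi, clinical_cutoffs, donor_panel, bead_panel
    ):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        hla = bead_panel.hla_bead
        assert infer_hla(pattern, "T8", hla)  # 3 of 4 donors reactive
        assert not infer_hla(pattern, "T5", hla)  # all below cutoff

    def test_all_zero_negative(self, donor_panel, bead_panel, clinical_cutoffs):
        from lumipanel.reactivity import MfiMatrix

        mfi = MfiMatrix.from_records(
            [("Z", d, "HLA", 0.0) for d in donor_panel.donor_ids]
        )
        pattern = call_reactivity(mfi, clinical_cutoffs, donor_panel)
        assert not infer_hla(pattern, "Z", bead_panel.hla_bead)


@pytest.fixture(scope="module")
def calls(clinical_mfi, clinical_cutoffs, donor_panel, bead_panel, priors):
    pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
    return {
        s: call_sample(s, pattern, donor_panel, bead_panel, priors)
        for s in clinical_mfi.sample_ids
    }


class TestCallSample:
    def test_two_specificity_call(self, calls):
        assert calls["S9"].final_call == frozenset(
            {ANTI_HLA, Specificity.hpa("HPA-3", "b")}
        )

    def test_multi_hpa_without_hla(self, calls):
        assert calls["S7"].final_call == frozenset(
            {Specificity.hpa("HPA-5", "a"), Specificity.hpa("HPA-1", "a")}
        )
        assert not calls["S7"].hla_positive

    def test_borderline_reading_flagged_not_called(self, calls):
        call = calls["S2"]
        assert call.final_call == frozenset(
            {ANTI_HLA, Specificity.hpa("HPA-2", "b")}
        )
        kinds = {(f.kind, f.bead_id) for f in call.flags}
        assert ("borderline_only", "GPIIbIIIa") in kinds
        assert ("unexplained_reactivity", "GPIIbIIIa") in kinds

    def test_all_zero_sample_is_negative(self, donor_panel, bead_panel,
                                         clinical_cutoffs, priors):
        from lumipanel.reactivity import MfiMatrix

        mfi = MfiMatrix.from_records(
            [
                ("Z", d, b.bead_id, 0.0)
                for d in donor_panel.donor_ids
                for b in bead_panel.active
                if b.role != "positive_control"
            ]
        )
        pattern = call_reactivity(mfi, clinical_cutoffs, donor_panel)
        call = call_sample("Z", pattern, donor_panel, bead_panel, priors)
        assert call.negative
        assert call.final_call == frozenset()
        assert call.flags == ()

    def test_soundness_of_all_outputs(self, calls, donor_panel, bead_panel):
        for call in calls.values():
            for bead_id, inference in call.beads.items():
                bead = bead_panel.bead(bead_id)
                if bead.role != "hpa_capture":
                    continue
                for ranked in inference.candidate_sets:
                    assert consistent(
                        ranked.specificities, bead,
                        inference.reactive, inference.nonreactive, donor_panel,
                    )


class TestConcordance:
    def test_full_agreement(self, clinical_mfi, clinical_cutoffs, donor_panel,
                            bead_panel, priors, expected_calls):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        calls = [
            call_sample(s, pattern, donor_panel, bead_panel, priors)
            for s in clinical_mfi.sample_ids
        ]
        report = concordance(calls, expected_calls)
        assert report.n_compared == 9
        assert report.percent_agreement == 100.0
        assert report.discordant == ()

    def test_flipped_reference_detected(self, clinical_mfi, clinical_cutoffs,
                                        donor_panel, bead_panel, priors,
                                        expected_calls):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        calls = [
            call_sample(s, pattern, donor_panel, bead_panel, priors)
            for s in clinical_mfi.sample_ids
        ]
        perturbed = dict(expected_calls)
        perturbed["T5"] = frozenset({ANTI_HLA})
        report = concordance(calls, perturbed)
        assert report.n_agree == 8
        assert report.n_compared == 9
        assert report.discordant[0][0] == "T5"

    def test_missing_reference_excluded(self, clinical_mfi, clinical_cutoffs,
                                        donor_panel, bead_panel, priors,
                                        expected_calls):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        calls = [
            call_sample(s, pattern, donor_panel, bead_panel, priors)
            for s in clinical_mfi.sample_ids
        ]
        partial = {k: v for k, v in expected_calls.items() if k != "S12"}
        report = concordance(calls, partial)
        assert report.n_compared == 8
        assert report.missing_reference == ("S12",)

    def test_empty_overlap_errors(self, clinical_mfi, clinical_cutoffs,
                                  donor_panel, bead_panel, priors):
        pattern = call_reactivity(clinical_mfi, clinical_cutoffs, donor_panel)
        calls = [
            call_sample("T5", pattern, donor_panel, bead_panel, priors)
        ]
        report = concordance(calls, {"OTHER": frozenset()})
        with pytest.raises(InferenceError, match="no overlapping"):
            _ = report.percent_agreement


class TestPriorTable:
    def test_weight_bounds_enforced(self):
        with pytest.raises(InferenceError):
            PriorTable({"anti-HPA-1a": 1.5})

    def test_missing_weight_errors(self):
        table = PriorTable({"anti-HLA": 0.9})
        with pytest.raises(InferenceError, match="anti-HPA-1a"):
            table.weight(Specificity.hpa("HPA-1", "a"))

    def test_default_covers_default_beads(self, bead_panel):
        PriorTable.default().validate_coverage(bead_panel)

    def test_set_score_is_product(self, priors):
        a = Specificity.hpa("HPA-3", "a")
        b = Specificity.hpa("HPA-5", "b")
        assert priors.score({a, b}) == pytest.approx(
            priors.weight(a) * priors.weight(b)
        )
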