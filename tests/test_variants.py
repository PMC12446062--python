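"""Variant parsing, candidate enumeration, delta scoring and concordance."""

import pytest

from ptmvar.ensemble import EnsemblePredictor
from ptmvar.seqcore import ProteinRecord
from ptmvar.variants import (
    VariantSpec,
    apply_variant,
    classify_effects,
    concordance_tally,
    enumerate_candidate_sites,
    parse_hgvs_p,
    score_variant,
    score_variant_effect,
)
from conftest import StubModel, sequon_rule


class TestHGVS:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("p.R1441C", (1441, "R", "C")),
            ("p.Ile1048Thr", (1048, "I", "T")),
            ("p.(Ser22Ala)", (22, "S", "A")),
        ],
    )
    def test_parses(self, text, expected):
        assert parse_hgvs_p(text) == expected

    @pytest.mark.parametrize("bad", ["p.R1441R", "R1441C", "p.Xyz5Ala", "p.12A"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_hgvs_p(bad)


class TestApplyVariant:
    def test_substitution(self):
        p = ProteinRecord("p", "GGGRGG")
        out = apply_variant(p, VariantSpec("p", 4, "R", "C"))
        assert out.sequence == "GGGCGG"
        assert len(out) == len(p)

    def test_reference_mismatch(self):
        with pytest.raises(ValueError, match="expected 'K', found 'R'"):
            apply_variant(ProteinRecord("p", "GGGRGG"), VariantSpec("p", 4, "K", "C"))

    def test_round_trip_involution(self):
        p = ProteinRecord("p", "GGGRGG")
        v = VariantSpec("p", 4, "R", "C")
        back = apply_variant(apply_variant(p, v), VariantSpec("p", 4, "C", "R"))
        assert back.sequence == p.sequence


class TestEnumerate:
    def test_gain_and_retained_site(self):
        ref = ProteinRecord("p", "GGGKGGGAGGGTGGG")
        sites = enumerate_candidate_sites(ref, VariantSpec("p", 8, "A", "S"), "phosphorylation")
        assert {(s.position, s.provenance) for s in sites} == {
            (8, "var_only"),
            (12, "ref_and_var"),
        }

    def test_acetylation_same_variant(self):
        ref = ProteinRecord("p", "GGGKGGGAGGGTGGG")
        sites = enumerate_candidate_sites(ref, VariantSpec("p", 8, "A", "S"), "acetylation")
        assert {(s.position, s.provenance) for s in sites} == {(4, "ref_and_var")}

    def test_direct_loss_single_site(self):
        ref = ProteinRecord("p", "GGGGGGGSGGGGGGG")
        sites = enumerate_candidate_sites(ref, VariantSpec("p", 8, "S", "A"), "phosphorylation")
        assert [(s.position, s.provenance) for s in sites] == [(8, "ref_only")]

    def test_range_limited_to_seven(self):
        ref = ProteinRecord("p", "S" + "G" * 7 + "A" + "G" * 7 + "S")
        sites = enumerate_candidate_sites(ref, VariantSpec("p", 9, "A", "V"), "phosphorylation")
        positions = {s.position for s in sites}
        assert positions == {2, 16} or all(abs(p - 9) <= 7 for p in positions)
        assert all(abs(s.position - 9) <= 7 for s in sites)


class TestScoreEffect:
    @pytest.fixture
    def motif_ensemble(self):
        return EnsemblePredictor(
            models=[StubModel(window_len=11, rule=sequon_rule) for _ in range(3)]
        )

    def test_direct_gain_zeroing(self, motif_ensemble):
        # A -> N completing a sequon: p_reference forced to exactly 0
        ref = ProteinRecord("p", "GGGGGGGAGSGGGGG")
        [site] = enumerate_candidate_sites(ref, VariantSpec("p", 8, "A", "N"), "n_glycosylation")
        eff = score_variant_effect(
            motif_ensemble, ref, VariantSpec("p", 8, "A", "N"), site, "n_glycosylation"
        )
        assert eff.p_reference == 0.0
        assert eff.delta_signed == eff.p_variant
        assert eff.category == "direct" and eff.direction == "increase"
        assert eff.altered  # stub scores the sequon at 0.95

    def test_direct_loss_zeroing(self, motif_ensemble):
        ref = ProteinRecord("p", "GGGGGGGNGSGGGGG")
        [site] = enumerate_candidate_sites(ref, VariantSpec("p", 8, "N", "A"), "n_glycosylation")
        eff = score_variant_effect(
            motif_ensemble, ref, VariantSpec("p", 8, "N", "A"), site, "n_glycosylation"
        )
        assert eff.p_variant == 0.0
        assert eff.delta_signed == -eff.p_reference
        assert eff.direction == "decrease"

    def test_proximal_effect_and_antisymmetry(self, motif_ensemble):
        # variant at +2 of the N creates the sequon S: proximal increase
        ref = ProteinRecord("p", "GGGGGGGNGAGGGGG")
        variant = VariantSpec("p", 10, "A", "S")
        effects = score_variant(motif_ensemble, ref, variant, "n_glycosylation")
        eff = next(e for e in effects if e.site_position == 8)
        assert eff.category == "proximal" and eff.direction == "increase"
        assert eff.delta_signed == pytest.approx(0.9)
        # reverse variant on the mutated sequence negates the delta exactly
        mutated = apply_variant(ref, variant)
        back = VariantSpec("p", 10, "S", "A")
        rev = next(
            e
            for e in score_variant(motif_ensemble, mutated, back, "n_glycosylation")
            if e.site_position == 8
        )
        assert rev.delta_signed == -eff.delta_signed

    def test_boundary_delta_half_is_altered(self):
        ens = EnsemblePredictor(models=[StubModel(0.5)])
        ref = ProteinRecord("p", "GGGGGGGNGSGGGGG")
        [site] = enumerate_candidate_sites(ref, VariantSpec("p", 8, "N", "A"), "n_glycosylation")
        eff = score_variant_effect(
            ens, ref, VariantSpec("p", 8, "N", "A"), site, "n_glycosylation"
        )
        assert eff.delta_signed == pytest.approx(-0.5)
        assert eff.altered  # |delta| >= 0.5 is inclusive at the boundary

    def test_non_candidate_site_rejected(self, motif_ensemble):
        from ptmvar.variants import CandidateSite

        ref = ProteinRecord("p", "GGGGGGGAGGGGGGG")
        with pytest.raises(ValueError, match="either allele"):
            score_variant_effect(
                motif_ensemble, ref, VariantSpec("p", 8, "A", "V"),
                CandidateSite(4, "ref_and_var"), "n_glycosylation",
            )


class TestClassify:
    def _effect(self, delta, category, pid="p", pos=5):
        from ptmvar.variants import VariantEffect

        p_ref = max(0.0, -delta)
        p_var = max(0.0, delta)
        return VariantEffect(
            variant=VariantSpec(pid, 1, "A", "V"),
            site_position=pos,
            ptm="phosphorylation",
            p_reference=p_ref,
            p_variant=p_var,
            category=category,
        )

    def test_four_way_tally(self):
        effects = [
            self._effect(0.98, "proximal"),
            self._effect(-0.53, "proximal"),
            self._effect(1.0, "direct"),
            self._effect(0.30, "direct"),  # below cutoff, excluded
        ]
        tally = classify_effects(effects)
        assert tally[("proximal", "increase")] == 1
        assert tally[("proximal", "decrease")] == 1
        assert tally[("direct", "increase")] == 1
        assert tally[("direct", "decrease")] == 0
        assert sum(tally.values()) == 3

    def test_concordance_rules(self):
        effects = [
            self._effect(0.9, "direct", pos=1),   # increase, MT_only -> supported
            self._effect(-0.9, "direct", pos=2),  # decrease, MT_only -> conflicting
            self._effect(0.9, "direct", pos=3),   # Both -> unevaluable
            self._effect(0.9, "direct", pos=4),   # no evidence -> unevaluable
        ]
        evidence = {
            ("p", 1): "MT_only",
            ("p", 2): "MT_only",
            ("p", 3): "Both",
        }
        counts = concordance_tally(effects, evidence)
        assert counts == {"supported": 1, "conflicting": 1, "unevaluable": 2}
        assert sum(counts.values()) == len(effects)
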