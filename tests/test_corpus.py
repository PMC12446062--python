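"""Positive/negative sampling, 81/9/10 splits, identity filtering."""

import pytest
from hypothesis import given, settings, strategies as st

from ptmvar.corpus import (
    CorpusConfig,
    build_positives,
    sample_negatives,
    similarity_filter,
    split_samples,
    window_identity,
)
from ptmvar.seqcore import ProteinRecord, SiteRef, window_from_peptide
from ptmvar.corpus import LabeledSample
from ptmvar.seqcore import PTMType


def _sample(peptide, label=1, pid="p"):
    return LabeledSample(
        window=window_from_peptide(peptide, protein_id=pid),
        label=label,
        ptm=PTMType("phosphorylation"),
    )


@pytest.fixture
def phospho_proteins():
    # prot0 carries 12 serines at even positions for clean counting
    return [
        ProteinRecord("prot0", "ASASASASASASASASASASASASA"),
        ProteinRecord("prot1", "ASASAAAAAAAAAAAAAAAAAAAAA"),
    ]


class TestBuildPositives:
    def test_counts_and_rejections(self, phospho_proteins):
        sites = [
            SiteRef("prot0", 2, "S"),
            SiteRef("prot0", 4, "S"),
            SiteRef("prot0", 1, "A"),  # not a phospho residue
        ]
        samples, rejected = build_positives(sites, phospho_proteins, "phosphorylation", 5)
        assert len(samples) == 2 and len(rejected) == 1
        assert rejected[0].residue == "A"

    def test_terminal_site_is_padded(self, phospho_proteins):
        samples, _ = build_positives(
            [SiteRef("prot0", 2, "S")], phospho_proteins, "phosphorylation", 7
        )
        assert samples[0].window.peptide.startswith("XX")

    def test_unknown_protein_raises(self, phospho_proteins):
        with pytest.raises(KeyError, match="ghost"):
            build_positives([SiteRef("ghost", 1, "S")], phospho_proteins, "phosphorylation", 5)


class TestSampleNegatives:
    def test_eligibility_threshold_and_exclusions(self, phospho_proteins):
        # prot0 has 12 serines; mark 10 as positive -> eligible, 2 left in pool
        positives = [SiteRef("prot0", 2 * i + 2, "S") for i in range(10)]
        negatives = sample_negatives(
            phospho_proteins, positives, [], "phosphorylation", 5, seed=0,
            neg_pos_ratio=1.0,
        )
        keys = {(s.window.site.protein_id, s.window.site.position) for s in negatives}
        # prot1 has only 2 positives-worth of serines and zero positives -> ineligible
        assert all(pid == "prot0" for pid, _ in keys)
        assert keys <= {("prot0", 22), ("prot0", 24)}

    def test_known_sites_removed_from_pool(self, phospho_proteins):
        positives = [SiteRef("prot0", 2 * i + 2, "S") for i in range(10)]
        negatives = sample_negatives(
            phospho_proteins, positives, [SiteRef("prot0", 22, "S")],
            "phosphorylation", 5, seed=0,
        )
        keys = {(s.window.site.protein_id, s.window.site.position) for s in negatives}
        assert keys == {("prot0", 24)}

    def test_protein_below_threshold_contributes_nothing(self, phospho_proteins):
        positives = [SiteRef("prot0", 2 * i + 2, "S") for i in range(9)]
        with pytest.raises(ValueError, match="lower"):
            sample_negatives(
                phospho_proteins, positives, [], "phosphorylation", 5, seed=0
            )

    def test_deterministic_given_seed(self, phospho_proteins):
        positives = [SiteRef("prot0", 2 * i + 2, "S") for i in range(10)]
        a = sample_negatives(
            phospho_proteins, positives, [], "phosphorylation", 5, seed=3
        )
        b = sample_negatives(
            phospho_proteins, positives, [], "phosphorylation", 5, seed=3
        )
        assert [s.window.peptide for s in a] == [s.window.peptide for s in b]

    def test_disjoint_from_positives(self, phospho_proteins):
        positives = [SiteRef("prot0", 2 * i + 2, "S") for i in range(10)]
        negatives = sample_negatives(
            phospho_proteins, positives, [], "phosphorylation", 5, seed=0
        )
        pos_keys = {(s.protein_id, s.position) for s in positives}
        neg_keys = {(s.window.site.protein_id, s.window.site.position) for s in negatives}
        assert pos_keys.isdisjoint(neg_keys)


class TestSplitSamples:
    def test_exact_site_counts(self):
        samples = [_sample("AASAA", pid=f"p{i}") for i in range(1000)]
        out = split_samples(samples, CorpusConfig(seed=1))
        counts = {s: 0 for s in ("train", "validation", "test")}
        for smp in out:
            counts[smp.split] += 1
        assert counts == {"train": 810, "validation": 90, "test": 100}

    def test_by_protein_no_leakage(self):
        samples = [
            _sample("AASAA", pid=f"p{i % 7}") for i in range(70)
        ]
        out = split_samples(samples, CorpusConfig(split_mode="by_protein", seed=2))
        per_protein = {}
        for smp in out:
            per_protein.setdefault(smp.window.site.protein_id, set()).add(smp.split)
        assert all(len(v) == 1 for v in per_protein.values())

    def test_same_seed_identical_partition(self):
        samples = [_sample("AASAA", pid=f"p{i}") for i in range(50)]
        a = split_samples(samples, CorpusConfig(seed=9))
        b = split_samples(samples, CorpusConfig(seed=9))
        assert [s.split for s in a] == [s.split for s in b]

    def test_every_sample_assigned(self):
        samples = [_sample("AASAA", pid=f"p{i}") for i in range(13)]
        out = split_samples(samples, CorpusConfig(seed=0))
        assert all(s.split in ("train", "validation", "test") for s in out)


class TestWindowIdentity:
    def test_identical_windows(self):
        a = _sample("ACDSF").window
        assert window_identity(a, a) == 1.0

    def test_hand_counted_fraction(self):
        # 31-mers differing at 3 of 31 positions -> 28/31
        base = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLM"
        other = "QCDEFGHIKLMNPQRSTVWYACDEFGHIKQQ"
        ident = window_identity(
            window_from_peptide(base), window_from_peptide(other)
        )
        assert ident == pytest.approx(28 / 31)

    def test_pad_positions_excluded(self):
        a = window_from_peptide("XXASA")
        b = window_from_peptide("GGASA")
        assert window_identity(a, b) == 1.0

    def test_all_pad_overlap_returns_zero(self):
        a = window_from_peptide("XXSXX")
        b = window_from_peptide("GGSGG")
        assert window_identity(a, b) == 1.0  # only center overlaps and matches
        c = window_from_peptide("XXAXX")
        d = window_from_peptide("AAXAA")  # no position where both non-pad
        assert window_identity(c, d) == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            window_identity(_sample("ASA").window, _sample("AASAA").window)


class TestSimilarityFilter:
    def test_duplicate_removed_at_090(self):
        train = [_sample("ACDSFGHIKLM")]
        test = [_sample("ACDSFGHIKLM"), _sample("WWWSWWWWWWW")]
        retained, removed = similarity_filter(test, train, 0.9)
        assert len(retained) == 1 and len(removed) == 1
        assert removed[0][2] == 1.0

    def test_threshold_one_keeps_near_duplicates(self):
        train = [_sample("ACDSFGHIKLM")]
        test = [_sample("ACDSFGHIKLW")]  # identity 10/11 < 1.0
        retained, removed = similarity_filter(test, train, 1.0)
        assert len(retained) == 1 and not removed

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_random_windows_survive_07(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        make = lambda: "".join(rng.choice(aa, size=31))  # noqa: E731
        train = [_sample(make()) for _ in range(5)]
        test = [_sample(make()) for _ in range(5)]
        retained, _ = similarity_filter(test, train, 0.7)
        assert len(retained) == 5
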