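"""Seeded generators for planted-motif corpora, variant benchmarks and site tables.

These generators stand in for MS-derived training corpora: positive
windows carry a short position-constrained motif around the central
modifiable residue (with configurable penetrance), negatives are drawn
from background residue frequencies with rejection sampling so they never
match the motif, gain/loss variant benchmarks plant or break the motif at
known positions, and site-table generators emit recurrent high-scoring
true sites plus decoy/noise records with a lower-shifted score
distribution so that target-decoy FDR behavior is known by design.

All outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregate import SiteEvidence
from .corpus import Corpus, CorpusConfig, LabeledSample, split_samples
from .seqcore import ProteinRecord, as_ptm, window_from_peptide
from .variants import VariantSpec

#: 20 standard residues; U/O are excluded from backgrounds
BACKGROUND_AA = "ACDEFGHIKLMNPQRSTVWY"

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class MotifSpec:
    """Position-constrained residue sets relative to the window center.

    ``pattern`` maps a signed offset to either an allowed residue set
    (``{"S", "T"}``) or a forbidden set written as ("not", {"P"}).  Offset 0
    (the center) must be consistent with the PTM's target residues.
    """

    name: str
    ptm: str
    pattern: dict
    penetrance: float = 1.0
    center_residues: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        targets = as_ptm(self.ptm).target_residues
        centers = tuple(self.center_residues) or tuple(sorted(targets))
        if not set(centers) <= targets:
            raise ValueError("center residues must be target residues of the PTM")
        object.__setattr__(self, "center_residues", centers)

    def matches(self, peptide: str) -> bool:
        """True iff every positional constraint holds within the peptide."""
        center = (len(peptide) - 1) // 2
        for offset, constraint in self.pattern.items():
            pos = center + offset
            if not 0 <= pos < len(peptide):
                return False
            aa = peptide[pos]
            if isinstance(constraint, tuple) and constraint[0] == "not":
                if aa in constraint[1]:
                    return False
            elif aa not in constraint:
                return False
        return True


def sequon_motif(penetrance: float = 1.0) -> MotifSpec:
    """N-glycosylation sequon N-!P-[ST]."""
    return MotifSpec(
        name="sequon",
        ptm="n_glycosylation",
        pattern={0: {"N"}, 1: ("not", {"P"}), 2: {"S", "T"}},
        penetrance=penetrance,
    )


def pka_motif(penetrance: float = 1.0) -> MotifSpec:
    """Basophilic R-R-x-[ST] motif recognized by PKA-family kinases."""
    return MotifSpec(
        name="rrxst",
        ptm="phosphorylation",
        pattern={-3: {"R"}, -2: {"R"}, 0: {"S", "T"}},
        penetrance=penetrance,
        center_residues=("S", "T"),
    )


def proline_directed_motif(penetrance: float = 1.0) -> MotifSpec:
    """[ST]-P motif recognized by proline-directed kinases (CDKs, MAPKs)."""
    return MotifSpec(
        name="stp",
        ptm="phosphorylation",
        pattern={0: {"S", "T"}, 1: {"P"}},
        penetrance=penetrance,
        center_residues=("S", "T"),
    )


MOTIFS = {
    "sequon": sequon_motif,
    "rrxst": pka_motif,
    "stp": proline_directed_motif,
}


def _random_background(rng, length: int, frequencies=None) -> list[str]:
    aa = list(BACKGROUND_AA)
    return list(rng.choice(aa, size=length, p=frequencies))


def _plant_motif(chars: list[str], motif: MotifSpec, rng) -> None:
    center = (len(chars) - 1) // 2
    for offset, constraint in motif.pattern.items():
        pos = center + offset
        if not 0 <= pos < len(chars):
            raise ValueError(
                f"motif {motif.name!r} does not fit in a window of "
                f"length {len(chars)}"
            )
        if isinstance(constraint, tuple) and constraint[0] == "not":
            while chars[pos] in constraint[1]:
                chars[pos] = str(rng.choice(list(BACKGROUND_AA)))
        else:
            chars[pos] = str(rng.choice(sorted(constraint)))


def generate_motif_corpus(
    motif: MotifSpec,
    n_pos: int,
    n_neg: int,
    window_len: int,
    seed: int,
    *,
    background_frequencies=None,
    split: bool = True,
) -> Corpus:
    """Planted-motif positives vs rejection-sampled background negatives.

    Positives carry the motif with probability ``penetrance`` (background
    with the correct center residue otherwise); negatives are resampled
    until they do not match the motif (capped attempts, then an error).
    Returns a :class:`Corpus` already split 81/9/10 by site when ``split``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    ptm = as_ptm(motif.ptm)
    center = (window_len - 1) // 2
    samples: list[LabeledSample] = []

    def background_window() -> list[str]:
        chars = _random_background(rng, window_len, background_frequencies)
        chars[center] = str(rng.choice(motif.center_residues))
        return chars

    for i in range(n_pos):
        chars = background_window()
        if rng.random() < motif.penetrance:
            _plant_motif(chars, motif, rng)
        samples.append(
            LabeledSample(
                window=window_from_peptide("".join(chars), protein_id=f"pos{i}"),
                label=1,
                ptm=ptm,
            )
        )
    for i in range(n_neg):
        for _ in range(_REJECTION_CAP):
            chars = background_window()
            if not motif.matches("".join(chars)):
                break
        else:
            raise RuntimeError(
                f"could not sample a non-motif negative in {_REJECTION_CAP} tries"
            )
        samples.append(
            LabeledSample(
                window=window_from_peptide("".join(chars), protein_id=f"neg{i}"),
                label=0,
                ptm=ptm,
            )
        )
    config = CorpusConfig(seed=seed)
    if split:
        samples = split_samples(samples, config)
    return Corpus(samples=samples, ptm=ptm, config=config)


@dataclass(frozen=True)
class VariantCase:
    """One benchmark case: reference protein, variant, and expected outcome."""

    reference: ProteinRecord
    variant: VariantSpec
    site_position: int
    truth_direction: str  # increase | decrease
    truth_category: str  # direct | proximal


def generate_variant_benchmark(
    motif: MotifSpec, n_cases: int, seed: int, *, flank: int = 20
) -> list[VariantCase]:
    """Gain/loss variant pairs with known ground truth, four types in rotation.

    direct gain:    background residue -> modifiable residue completing the motif
    direct loss:    modifiable motif center -> alanine
    proximal gain:  a motif-breaking flank residue -> the motif-completing one
    proximal loss:  a motif flank residue -> one that breaks the motif
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = sorted(o for o in motif.pattern if o != 0)
    if not offsets:
        raise ValueError("proximal cases need at least one non-center constraint")
    cases: list[VariantCase] = []
    kinds = ["direct_gain", "direct_loss", "proximal_gain", "proximal_loss"]
    length = 2 * flank + 1
    center = flank + 1  # 1-based center position
    for i in range(n_cases):
        kind = kinds[i % 4]
        chars = _random_background(rng, length)
        _plant_motif(chars, motif, rng)
        chars[center - 1] = str(rng.choice(motif.center_residues))
        if kind == "direct_gain":
            ref_center = "A" if "A" not in motif.center_residues else "G"
            mutant_center = chars[center - 1]
            chars[center - 1] = ref_center
            ref_seq = "".join(chars)
            variant = VariantSpec(f"case{i}", center, ref_center, mutant_center)
            truth, site = "increase", center
        elif kind == "direct_loss":
            ref_seq = "".join(chars)
            variant = VariantSpec(f"case{i}", center, chars[center - 1], "A")
            truth, site = "decrease", center
        else:
            offset = int(rng.choice(offsets))
            constraint = motif.pattern[offset]
            pos = center + offset
            if isinstance(constraint, tuple):  # 'not' constraint: breaker = member
                good = chars[pos - 1]
                bad = str(rng.choice(sorted(constraint[1])))
            else:
                good = chars[pos - 1]
                breakers = [
                    aa for aa in BACKGROUND_AA if aa not in constraint
                ]
                bad = str(rng.choice(breakers))
            if kind == "proximal_gain":
                chars[pos - 1] = bad
                ref_seq = "".join(chars)
                variant = VariantSpec(f"case{i}", pos, bad, good)
                truth, site = "increase", center
            else:
                ref_seq = "".join(chars)
                variant = VariantSpec(f"case{i}", pos, good, bad)
                truth, site = "decrease", center
        cases.append(
            VariantCase(
                reference=ProteinRecord(id=f"case{i}", sequence=ref_seq),
                variant=variant,
                site_position=site,
                truth_direction=truth,
                truth_category="direct" if kind.startswith("direct") else "proximal",
            )
        )
    return cases


def generate_site_tables(
    n_true_sites: int,
    n_noise_sites: int,
    n_datasets: int,
    seed: int,
    *,
    true_score_mean: float = 3.0,
    noise_score_mean: float = 0.0,
    score_sd: float = 1.0,
    residue: str = "S",
    min_recurrence: int = 2,
) -> list[SiteEvidence]:
    """Decoy-bearing site tables with known FDR structure.

    True sites recur in at least ``min_recurrence`` datasets with scores
    from a high distribution; each noise target is paired with one decoy
    record, both drawn from a lower-shifted distribution, so decoy counts
    estimate the noise contamination.
    """
    if n_true_sites < 1 or n_datasets < 1:
        raise ValueError("need at least one true site and one dataset")
    rng = np.random.default_rng(seed)
    evidences: list[SiteEvidence] = []
    for i in range(n_true_sites):
        protein = f"prot{i // 10}"
        position = 10 * (i % 10) + 5
        k = int(rng.integers(min(min_recurrence, n_datasets), n_datasets + 1))
        for d in sorted(rng.choice(n_datasets, size=k, replace=False)):
            evidences.append(
                SiteEvidence(
                    dataset_id=f"ds{d}",
                    protein_id=protein,
                    position=position,
                    residue=residue,
                    score=float(rng.normal(true_score_mean, score_sd)),
                    localization_prob=float(rng.uniform(0.75, 1.0)),
                    psm_count=int(rng.integers(1, 20)),
                )
            )
    for i in range(n_noise_sites):
        d = int(rng.integers(n_datasets))
        common = dict(
            dataset_id=f"ds{d}",
            residue=residue,
            localization_prob=float(rng.uniform(0.5, 1.0)),
            psm_count=1,
        )
        evidences.append(
            SiteEvidence(
                protein_id=f"noise{i}",
                position=int(rng.integers(1, 500)),
                score=float(rng.normal(noise_score_mean, score_sd)),
                **common,
            )
        )
        evidences.append(
            SiteEvidence(
                protein_id=f"decoy{i}",
                position=int(rng.integers(1, 500)),
                score=float(rng.normal(noise_score_mean, score_sd)),
                is_decoy=True,
                **common,
            )
        )
    return evidences


def generate_proteins(
    n_proteins: int,
    length: int,
    seed: int,
    *,
    frequencies=None,
) -> list[ProteinRecord]:
    """Random background proteins for corpus and aggregation fixtures."""
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(
            id=f"prot{i}",
            sequence="".join(_random_background(rng, length, frequencies)),
        )
        for i in range(n_proteins)
    ]
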