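"""Labeled corpus construction: positive/negative sampling, splits, leakage control.

Positives are sites with MS/MS evidence; negatives are unmodified residues
of the same type drawn only from proteins that carry at least a minimum
number of positive sites (so that a residue without evidence on a
well-covered protein is plausibly a true negative), with anything listed as
positive or known in external databases removed from the pool.

Samples are split 81/9/10 into train/validation/test, either per site or
per protein (the latter prevents peptide leakage between splits), and a
positional-identity filter can remove test windows too similar to any
training/validation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqcore import (
    PAD,
    PTMType,
    ProteinRecord,
    SiteRef,
    SiteWindow,
    as_ptm,
    extract_window,
)

SPLITS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.81, 0.09, 0.10)


@dataclass(frozen=True)
class LabeledSample:
    window: SiteWindow
    label: int  # 1 positive, 0 negative
    ptm: PTMType
    split: str = "unassigned"

    @property
    def key(self) -> tuple[str, int]:
        return (self.window.site.protein_id, self.window.site.position)


@dataclass
class CorpusConfig:
    split_fractions: tuple = DEFAULT_FRACTIONS
    min_positive_sites_per_protein_for_negatives: int = 10
    split_mode: str = "by_site"
    identity_threshold: float | None = None
    neg_pos_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.split_mode not in ("by_site", "by_protein"):
            raise ValueError("split_mode must be 'by_site' or 'by_protein'")


def build_positives(
    sites, proteins, ptm: str | PTMType, n: int
) -> tuple[list[LabeledSample], list[SiteRef]]:
    """One positive sample per valid site; invalid sites go in the report.

    A site is rejected when its residue is not a target residue of the PTM
    type or does not match the protein sequence.  Unknown proteins raise.
    """
    ptm = as_ptm(ptm)
    index = {p.id: p for p in proteins}
    samples: list[LabeledSample] = []
    rejected: list[SiteRef] = []
    for site in sites:
        protein = index.get(site.protein_id)
        if protein is None:
            raise KeyError(f"site references unknown protein {site.protein_id!r}")
        if (
            site.residue not in ptm.target_residues
            or protein.residue(site.position) != site.residue
        ):
            rejected.append(site)
            continue
        window = extract_window(protein, site.position, n)
        samples.append(LabeledSample(window=window, label=1, ptm=ptm))
    return samples, rejected


def sample_negatives(
    proteins,
    positives,
    known_sites,
    ptm: str | PTMType,
    n: int,
    seed: int,
    *,
    min_positives: int = 10,
    neg_pos_ratio: float = 1.0,
) -> list[LabeledSample]:
    """Sample negative windows from proteins with >= ``min_positives`` positives.

    The eligible pool is every target residue on an eligible protein whose
    (protein, position) is in neither the positive set nor ``known_sites``.
    The pool is downsampled to ``neg_pos_ratio`` times the positive count
    (or kept whole if smaller) with a seeded shuffle, so the draw is
    deterministic given the seed.
    """
    ptm = as_ptm(ptm)
    pos_keys = {(s.protein_id, s.position) for s in _as_siterefs(positives)}
    known_keys = {(s.protein_id, s.position) for s in _as_siterefs(known_sites)}
    per_protein_pos: dict[str, int] = {}
    for pid, _ in pos_keys:
        per_protein_pos[pid] = per_protein_pos.get(pid, 0) + 1

    pool: list[tuple[ProteinRecord, int]] = []
    for protein in proteins:
        if per_protein_pos.get(protein.id, 0) < min_positives:
            continue
        for pos0, aa in enumerate(protein.sequence):
            key = (protein.id, pos0 + 1)
            if aa in ptm.target_residues and key not in pos_keys and key not in known_keys:
                pool.append((protein, pos0 + 1))
    if not pool:
        raise ValueError(
            "no protein is eligible to contribute negatives; lower "
            "min_positives for small fixtures"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    target = int(round(neg_pos_ratio * len(pos_keys))) if pos_keys else len(pool)
    chosen = sorted(order[: max(1, min(target, len(pool)))])
    return [
        LabeledSample(
            window=extract_window(pool[i][0], pool[i][1], n), label=0, ptm=ptm
        )
        for i in chosen
    ]


def _as_siterefs(items):
    for item in items:
        if isinstance(item, LabeledSample):
            yield item.window.site
        else:
            yield item


def _exact_counts(total: int, fractions) -> list[int]:
    """Largest-remainder apportionment of `total` into len(fractions) parts."""
    raw = [f * total for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest frac part first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def split_samples(samples, config: CorpusConfig) -> list[LabeledSample]:
    """Assign train/validation/test splits with exact-count partitioning.

    ``by_site`` shuffles samples and cuts exact 81/9/10 blocks; ``by_protein``
    partitions proteins the same way and lets samples inherit their
    protein's split, so no protein straddles two splits.
    """
    samples = list(samples)
    rng = np.random.default_rng(config.seed)
    if config.split_mode == "by_site":
        order = rng.permutation(len(samples))
        counts = _exact_counts(len(samples), config.split_fractions)
        assigned = [None] * len(samples)
        offset = 0
        for split, count in zip(SPLITS, counts):
            for idx in order[offset : offset + count]:
                assigned[idx] = split
            offset += count
        return [replace(s, split=a) for s, a in zip(samples, assigned)]
    proteins = sorted({s.window.site.protein_id for s in samples})
    order = rng.permutation(len(proteins))
    counts = _exact_counts(len(proteins), config.split_fractions)
    protein_split: dict[str, str] = {}
    offset = 0
    for split, count in zip(SPLITS, counts):
        for idx in order[offset : offset + count]:
            protein_split[proteins[idx]] = split
        offset += count
    return [replace(s, split=protein_split[s.window.site.protein_id]) for s in samples]


def window_identity(a: SiteWindow, b: SiteWindow) -> float:
    """Positional identity over positions where both windows are non-pad."""
    if a.n != b.n:
        raise ValueError(f"window lengths differ: {a.n} vs {b.n}")
    both = matches = 0
    for x, y in zip(a.peptide, b.peptide):
        if x != PAD and y != PAD:
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


def similarity_filter(
    test_samples, reference_samples, threshold: float
) -> tuple[list[LabeledSample], list[tuple[LabeledSample, LabeledSample, float]]]:
    """Drop test samples whose max identity to any reference exceeds threshold.

    Returns (retained, removal report); each report row is the removed test
    sample, the offending reference and their identity.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    retained: list[LabeledSample] = []
    removed: list[tuple[LabeledSample, LabeledSample, float]] = []
    refs = list(reference_samples)
    for sample in test_samples:
        worst = None
        worst_ident = -1.0
        for ref in refs:
            ident = window_identity(sample.window, ref.window)
            if ident > worst_ident:
                worst_ident, worst = ident, ref
        if worst is not None and worst_ident > threshold:
            removed.append((sample, worst, worst_ident))
        else:
            retained.append(sample)
    return retained, removed


@dataclass
class Corpus:
    """A split corpus plus convenience accessors used by the model layer."""

    samples: list
    ptm: PTMType
    config: CorpusConfig = field(default_factory=CorpusConfig)

    def subset(self, split: str) -> list[LabeledSample]:
        return [s for s in self.samples if s.split == split]

    def peptides_labels(self, split: str) -> tuple[list[str], np.ndarray]:
        part = self.subset(split)
        return [s.window.peptide for s in part], np.array(
            [s.label for s in part], dtype=np.float32
        )
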