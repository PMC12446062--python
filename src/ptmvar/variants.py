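"""Missense-variant effects on PTM sites: delta scores and concordance.

For a missense variant, every position within seven residues whose
reference and/or variant residue is modifiable for the PTM type is a
candidate site.  The ensemble scores the site on both allele sequences;
the allele in which the site residue is not modifiable contributes a
probability of exactly zero (a lost site cannot be modified in the variant;
a gained site has no reference probability).  The signed delta is
P(variant) - P(reference); |delta| >= 0.5 calls the variant PTM-altering,
and the sign gives the direction.  A site at the variant position is a
direct effect, otherwise proximal.

Concordance with modified-peptide MS evidence follows the detection rule:
variant-peptide-only detection supports an increase call, wild-type-only
detection supports a decrease call, the opposite detections conflict, and
sites seen on both peptides (or not at all) are unevaluable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqcore import ProteinRecord, as_ptm, extract_window

#: maximum distance (residues) between variant and candidate PTM site
PROXIMAL_RANGE = 7
#: |delta| at or above this calls a variant PTM-altering
DELTA_CUTOFF = 0.5
#: flanking residues of true sequence context used for prediction input
VARIANT_FLANK = 15

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Sec": "U", "Pyl": "O",
}
_HGVS_RE = re.compile(
    r"^p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])\)?$"
)


@dataclass(frozen=True)
class VariantSpec:
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"variant {self.protein_id}:{self.position} has identical "
                f"reference and alternate residues ({self.ref_aa})"
            )

    @property
    def label(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class CandidateSite:
    position: int
    provenance: str  # ref_and_var | ref_only | var_only


@dataclass
class VariantEffect:
    variant: VariantSpec
    site_position: int
    ptm: str
    p_reference: float
    p_variant: float
    category: str  # direct | proximal

    @property
    def delta_signed(self) -> float:
        return self.p_variant - self.p_reference

    @property
    def delta_abs(self) -> float:
        return abs(self.delta_signed)

    @property
    def direction(self) -> str:
        if self.delta_signed > 0:
            return "increase"
        if self.delta_signed < 0:
            return "decrease"
        return "none"

    @property
    def altered(self) -> bool:
        return self.delta_abs >= DELTA_CUTOFF


def parse_hgvs_p(text: str) -> tuple[int, str, str]:
    """Parse a protein-level HGVS string like ``p.R1441C`` or ``p.Ile1048Thr``."""
    match = _HGVS_RE.match(text.strip())
    if not match:
        raise ValueError(f"malformed HGVS p. string: {text!r}")
    ref_raw, pos, alt_raw = match.groups()
    try:
        ref = _AA3[ref_raw] if len(ref_raw) == 3 else ref_raw
        alt = _AA3[alt_raw] if len(alt_raw) == 3 else alt_raw
    except KeyError as exc:
        raise ValueError(
            f"unknown amino-acid code {exc.args[0]!r} in HGVS string {text!r}"
        ) from exc
    if ref == alt:
        raise ValueError(f"HGVS string {text!r} describes no residue change")
    return int(pos), ref, alt


def apply_variant(protein: ProteinRecord, variant: VariantSpec) -> ProteinRecord:
    """Substitute the variant residue; length and coordinates are preserved."""
    found = protein.residue(variant.position)
    if found != variant.ref_aa:
        raise ValueError(
            f"reference mismatch at {protein.id}:{variant.position}: "
            f"expected {variant.ref_aa!r}, found {found!r}"
        )
    seq = protein.sequence
    mutated = seq[: variant.position - 1] + variant.alt_aa + seq[variant.position :]
    return ProteinRecord(id=protein.id, sequence=mutated)


def enumerate_candidate_sites(
    reference: ProteinRecord, variant: VariantSpec, ptm
) -> list[CandidateSite]:
    """Candidate PTM sites within +/-7 residues of the variant.

    A position qualifies if the residue there is modifiable in the
    reference, the variant sequence, or both; provenance records which.
    """
    ptm = as_ptm(ptm)
    mutated = apply_variant(reference, variant)
    sites: list[CandidateSite] = []
    lo = max(1, variant.position - PROXIMAL_RANGE)
    hi = min(len(reference), variant.position + PROXIMAL_RANGE)
    for pos in range(lo, hi + 1):
        in_ref = reference.residue(pos) in ptm.target_residues
        in_var = mutated.residue(pos) in ptm.target_residues
        if not in_ref and not in_var:
            continue
        if in_ref and in_var:
            provenance = "ref_and_var"
        elif in_ref:
            provenance = "ref_only"
        else:
            provenance = "var_only"
        sites.append(CandidateSite(position=pos, provenance=provenance))
    return sites


def _score_context(ensemble, protein: ProteinRecord, center: int) -> float:
    """Ensemble score at ``center`` from 15 true flanking residues per side.

    The 31-residue context (X-padded past the protein ends) is re-padded or
    center-cropped to each member's own window length, so every model sees
    at most 15 residues of real sequence on each side.
    """
    from .ensemble import iqr_trimmed_mean

    context = extract_window(protein, center, 2 * VARIANT_FLANK + 1).peptide
    return iqr_trimmed_mean(
        [m.score_peptides([context])[0] for m in ensemble.models]
    )


def score_variant_effect(
    ensemble,
    reference: ProteinRecord,
    variant: VariantSpec,
    site: CandidateSite,
    ptm,
) -> VariantEffect:
    """Delta score for one (variant, candidate site) pair.

    The allele whose residue at the site is not modifiable gets probability
    exactly 0 (direct losses and gains therefore have delta equal to minus
    or plus the probability of the modifiable allele, bit-exactly).
    """
    ptm = as_ptm(ptm)
    mutated = apply_variant(reference, variant)
    in_ref = reference.residue(site.position) in ptm.target_residues
    in_var = mutated.residue(site.position) in ptm.target_residues
    if not in_ref and not in_var:
        raise ValueError(
            f"position {site.position} is not a {ptm.name} site in either allele"
        )
    p_ref = _score_context(ensemble, reference, site.position) if in_ref else 0.0
    p_var = _score_context(ensemble, mutated, site.position) if in_var else 0.0
    return VariantEffect(
        variant=variant,
        site_position=site.position,
        ptm=ptm.name,
        p_reference=float(p_ref),
        p_variant=float(p_var),
        category="direct" if site.position == variant.position else "proximal",
    )


def score_variant(ensemble, reference, variant, ptm) -> list[VariantEffect]:
    """All candidate-site effects for one variant."""
    return [
        score_variant_effect(ensemble, reference, variant, site, ptm)
        for site in enumerate_candidate_sites(reference, variant, ptm)
    ]


def classify_effects(effects) -> dict:
    """2x2 tally of altered effects: {direct, proximal} x {increase, decrease}."""
    tally = {
        ("direct", "increase"): 0,
        ("direct", "decrease"): 0,
        ("proximal", "increase"): 0,
        ("proximal", "decrease"): 0,
    }
    for e in effects:
        if e.altered and e.direction != "none":
            tally[(e.category, e.direction)] += 1
    return tally


def concordance_tally(effects, ms_evidence: dict) -> dict:
    """Tally altered predictions against WT-only/MT-only/Both MS detection.

    ``ms_evidence`` maps (protein_id, site_position) -> status.  Counts are
    conserved: supported + conflicting + unevaluable == len(effects).
    """
    counts = {"supported": 0, "conflicting": 0, "unevaluable": 0}
    for e in effects:
        status = ms_evidence.get((e.variant.protein_id, e.site_position))
        if status not in ("WT_only", "MT_only") or e.direction == "none":
            counts["unevaluable"] += 1
        elif (e.direction == "increase") == (status == "MT_only"):
            counts["supported"] += 1
        else:
            counts["conflicting"] += 1
    return counts
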