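"""Plain-text table I/O: site tables, variant tables, effect tables, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .aggregate import SiteEvidence
from .seqcore import SiteRef
from .variants import VariantSpec, parse_hgvs_p


def read_sites_tsv(path) -> list[SiteRef]:
    """Columns: protein_id, position (1-based), residue[, source]."""
    df = pd.read_csv(path, sep="\t")
    return [
        SiteRef(str(r.protein_id), int(r.position), str(r.residue))
        for r in df.itertuples()
    ]


def write_sites_tsv(sites, path) -> None:
    pd.DataFrame(
        [
            {"protein_id": s.protein_id, "position": s.position, "residue": s.residue}
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantSpec]:
    """Either (protein_id, position, ref_aa, alt_aa) or (protein_id, hgvs_p)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    if "hgvs_p" in df.columns:
        for r in df.itertuples():
            pos, ref, alt = parse_hgvs_p(str(r.hgvs_p))
            out.append(VariantSpec(str(r.protein_id), pos, ref, alt))
    else:
        for r in df.itertuples():
            out.append(
                VariantSpec(
                    str(r.protein_id), int(r.position), str(r.ref_aa), str(r.alt_aa)
                )
            )
    return out


def read_evidence_tsv(path) -> list[SiteEvidence]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteEvidence(
            dataset_id=str(r.dataset_id),
            protein_id=str(r.protein_id),
            position=int(r.position),
            residue=str(r.residue),
            score=float(r.score),
            localization_prob=float(r.localization_prob),
            is_decoy=bool(r.is_decoy),
            psm_count=int(r.psm_count),
        )
        for r in df.itertuples()
    ]


def write_evidence_tsv(evidences, path) -> None:
    from .aggregate import evidences_to_frame

    evidences_to_frame(evidences).to_csv(path, sep="\t", index=False)


def read_ms_status_tsv(path) -> dict:
    """(protein_id, site_position) -> WT_only | MT_only | Both."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.protein_id), int(r.site_position)): str(r.status)
        for r in df.itertuples()
    }


def effects_to_frame(effects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": e.variant.protein_id,
                "variant": e.variant.label,
                "ptm": e.ptm,
                "site_position": e.site_position,
                "p_reference": e.p_reference,
                "p_variant": e.p_variant,
                "delta_signed": e.delta_signed,
                "category": e.category,
                "direction": e.direction,
                "altered": e.altered,
            }
            for e in effects
        ]
    )


def write_corpus_tsv(corpus, path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": s.window.site.protein_id,
                "position": s.window.site.position,
                "peptide": s.window.peptide,
                "label": s.label,
                "split": s.split,
            }
            for s in corpus.samples
        ]
    ).to_csv(path, sep="\t", index=False)


def write_manifest(path, **payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
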