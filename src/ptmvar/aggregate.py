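"""Cross-dataset modification-site aggregation with target-decoy FDR control.

Per-dataset site tables are merged on (protein, position, residue, decoy
flag): the best (maximum) score, the maximum localization probability, the
PSM sum and the number of contributing datasets are kept.  A global
site-level FDR is estimated by target-decoy counting — at a score
threshold t, FDR(t) = #decoys >= t / #targets >= t — and monotonized from
the bottom of the ranking into q-values.  Retention requires q <= 1%,
localization probability strictly greater than 0.5 and, for
N-glycosylation, an N-!P-[ST] sequon around the site.

Rarefaction curves (mean unique sites after k datasets, over random dataset
orderings) quantify how far site discovery is from saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqcore import as_ptm, sequon_check

EVIDENCE_COLUMNS = [
    "dataset_id",
    "protein_id",
    "position",
    "residue",
    "score",
    "localization_prob",
    "is_decoy",
    "psm_count",
]


@dataclass(frozen=True)
class SiteEvidence:
    dataset_id: str
    protein_id: str
    position: int
    residue: str
    score: float
    localization_prob: float
    is_decoy: bool = False
    psm_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization_prob must be in [0, 1]")
        if self.psm_count < 0:
            raise ValueError("psm_count must be non-negative")


def evidences_to_frame(evidences) -> pd.DataFrame:
    return pd.DataFrame([vars(e) | {} for e in evidences], columns=EVIDENCE_COLUMNS)


def merge_site_tables(evidences) -> pd.DataFrame:
    """Aggregate evidences per unique (protein, position, residue, is_decoy).

    Raises if the same (protein, position, decoy-class) carries conflicting
    residue letters in different datasets.
    """
    df = (
        evidences
        if isinstance(evidences, pd.DataFrame)
        else evidences_to_frame(evidences)
    )
    if df.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "position", "residue", "is_decoy",
                "best_score", "max_localization_prob", "n_datasets", "total_psms",
            ]
        )
    conflicts = (
        df.groupby(["protein_id", "position", "is_decoy"])["residue"]
        .nunique()
        .pipe(lambda s: s[s > 1])
    )
    if len(conflicts):
        rows = ", ".join(f"{p}:{pos}" for p, pos, _ in conflicts.index)
        raise ValueError(f"conflicting residue letters at sites: {rows}")
    agg = (
        df.groupby(["protein_id", "position", "residue", "is_decoy"], as_index=False)
        .agg(
            best_score=("score", "max"),
            max_localization_prob=("localization_prob", "max"),
            n_datasets=("dataset_id", "nunique"),
            total_psms=("psm_count", "sum"),
        )
        .sort_values("best_score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return agg


def compute_site_qvalues(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Target-decoy q-values over the pooled target+decoy score ranking.

    FDR at threshold t counts all records with best_score >= t (score ties
    are kept together); the q-value is the running minimum of FDR taken
    from the weakest score upward, so it is monotone non-increasing in
    best_score.
    """
    df = aggregates.copy()
    if (~df["is_decoy"]).sum() == 0:
        raise ValueError("q-value computation requires at least one target")
    df = df.sort_values(
        "best_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    is_decoy = df["is_decoy"].to_numpy()
    decoys_above = np.cumsum(is_decoy)
    targets_above = np.cumsum(~is_decoy)
    # extend counts over score ties: every row of a tied block gets the
    # block-final counts, so acceptance at a threshold is all-or-none
    scores = df["best_score"].to_numpy()
    block_last = np.zeros(len(df), dtype=int)
    last = len(df) - 1
    for i in range(len(df) - 1, -1, -1):
        if i < len(df) - 1 and scores[i] != scores[i + 1]:
            last = i
        block_last[i] = last
    fdr = decoys_above[block_last] / np.maximum(targets_above[block_last], 1)
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    df["q_value"] = np.clip(qvals, 0.0, 1.0)
    return df


def apply_site_filters(
    aggregates: pd.DataFrame,
    ptm,
    proteins=None,
    q_cut: float = 0.01,
    loc_cut: float = 0.5,
) -> pd.DataFrame:
    """Retain targets with q <= q_cut and localization probability > loc_cut.

    For N-glycosylation the site must additionally pass the N-!P-[ST]
    sequon check against the parent protein sequence (``proteins`` is then
    required: an iterable of ProteinRecords).
    """
    ptm = as_ptm(ptm)
    df = aggregates
    if "q_value" not in df.columns:
        raise ValueError("q-values must be computed before filtering")
    keep = (
        (~df["is_decoy"])
        & (df["q_value"] <= q_cut)
        & (df["max_localization_prob"] > loc_cut)
    )
    out = df[keep].copy()
    if ptm.name == "n_glycosylation":
        if proteins is None:
            raise ValueError("sequon filtering requires protein sequences")
        seqs = {p.id: p.sequence for p in proteins}
        mask = [
            row.protein_id in seqs
            and seqs[row.protein_id][row.position - 1] == "N"
            and sequon_check(seqs[row.protein_id], row.position)
            for row in out.itertuples()
        ]
        out = out[mask]
    return out.reset_index(drop=True)


def rarefaction_curve(
    evidences, n_permutations: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Mean cumulative unique-site count after k of D datasets.

    Averaged over ``n_permutations`` random dataset orderings; the curve is
    non-decreasing in k by construction.  Returns columns (k, mean, sd).
    """
    df = (
        evidences
        if isinstance(evidences, pd.DataFrame)
        else evidences_to_frame(evidences)
    )
    df = df[~df["is_decoy"]]
    datasets = sorted(df["dataset_id"].unique())
    if not datasets:
        raise ValueError("rarefaction requires at least one dataset")
    site_sets = {
        d: set(
            map(
                tuple,
                df[df["dataset_id"] == d][
                    ["protein_id", "position", "residue"]
                ].itertuples(index=False),
            )
        )
        for d in datasets
    }
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, len(datasets)))
    for rep in range(n_permutations):
        order = rng.permutation(len(datasets))
        seen: set = set()
        for k, idx in enumerate(order):
            seen |= site_sets[datasets[idx]]
            curves[rep, k] = len(seen)
    return pd.DataFrame(
        {
            "k": np.arange(1, len(datasets) + 1),
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1) if n_permutations > 1 else 0.0,
        }
    )
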