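"""Model/Results facade over the architecture search and ensemble pipeline.

:class:`SitePredictionModel` holds a labeled corpus for one PTM type; its
``fit`` runs the genetic architecture search on the train/validation
splits, retrains the top genomes from scratch and returns a
:class:`SitePredictionResults` carrying the ensemble, per-member validation
accuracies, held-out test metrics, the calibrated 1%-FPR threshold and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .ensemble import (
    EnsemblePredictor,
    build_ensemble,
    compute_auroc,
)
from .nas import GAConfig, evolve, top_k as _top_k


class SitePredictionModel:
    """An ensemble PTM-site classifier to be fitted to a labeled corpus."""

    def __init__(self, corpus: Corpus, ga_config: GAConfig | None = None):
        if not corpus.subset("train") or not corpus.subset("validation"):
            raise ValueError("corpus must carry train and validation splits")
        self.corpus = corpus
        self.ga_config = ga_config or GAConfig()

    @classmethod
    def from_samples(cls, samples, ptm, ga_config=None, config=None) -> "SitePredictionModel":
        from .corpus import CorpusConfig, split_samples

        config = config or CorpusConfig()
        if any(s.split == "unassigned" for s in samples):
            samples = split_samples(samples, config)
        return cls(Corpus(samples=list(samples), ptm=ptm, config=config), ga_config)

    def fit(
        self,
        *,
        n_members: int = 10,
        final_epochs: int = 100,
        fpr: float = 0.01,
        seed: int | None = None,
        verbose: bool = False,
    ) -> "SitePredictionResults":
        """Search architectures, train the top ``n_members``, calibrate, evaluate."""
        if seed is not None:
            self.ga_config.seed = seed
        records = evolve(self.corpus, self.ga_config, verbose=verbose)
        genomes = _top_k(records, n_members)
        ensemble = build_ensemble(
            genomes,
            self.corpus,
            seed=self.ga_config.seed,
            max_epochs=final_epochs,
            fpr=fpr,
        )
        test_p, test_y = self.corpus.peptides_labels("test")
        auroc = accuracy = None
        if test_p and test_y.min() < 0.5 < test_y.max():
            scores = ensemble.score_peptides(test_p)
            auroc = compute_auroc(scores[test_y == 1], scores[test_y == 0])
            accuracy = float(np.mean((scores >= 0.5) == (test_y >= 0.5)))
        return SitePredictionResults(
            model=self,
            ensemble=ensemble,
            search_records=records,
            test_auroc=auroc,
            test_accuracy=accuracy,
        )


@dataclass
class SitePredictionResults:
    """Fitted ensemble plus search history and held-out diagnostics."""

    model: SitePredictionModel
    ensemble: EnsemblePredictor
    search_records: list
    test_auroc: float | None
    test_accuracy: float | None

    @property
    def member_table(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.ensemble.models):
            rows.append(
                {
                    "member": i,
                    "window_len": m.genome.window_len,
                    "conv_layers": len(m.genome.conv_layers),
                    "dense_layers": len(m.genome.dense_layers),
                    "optimizer": m.genome.optimizer,
                    "val_accuracy": m.val_accuracy,
                }
            )
        return pd.DataFrame(rows)

    def predict_site(self, protein, position, ptm=None) -> float:
        return self.ensemble.predict_site(
            protein, position, ptm or self.model.corpus.ptm
        )

    def scan(self, proteins, ptm=None) -> pd.DataFrame:
        from .ensemble import scan_proteome

        return pd.DataFrame(
            scan_proteome(self.ensemble, proteins, ptm or self.model.corpus.ptm)
        )

    def score_variants(self, reference, variant, ptm=None) -> list:
        from .variants import score_variant

        return score_variant(
            self.ensemble, reference, variant, ptm or self.model.corpus.ptm
        )

    def summary(self) -> str:
        ptm = self.model.corpus.ptm.name
        counts = {
            split: len(self.model.corpus.subset(split))
            for split in ("train", "validation", "test")
        }
        lines = [
            "PTM Site Prediction Ensemble Results",
            "=" * 52,
            f"PTM type:             {ptm}",
            f"samples (train/val/test): {counts['train']}/"
            f"{counts['validation']}/{counts['test']}",
            f"architectures evaluated:  {len(self.search_records)}",
            f"ensemble members:         {len(self.ensemble.models)}",
            f"positive threshold:       {self.ensemble.positive_threshold:.2f}",
        ]
        if self.ensemble.high_conf_threshold is not None:
            lines.append(
                f"1%-FPR threshold:         {self.ensemble.high_conf_threshold:.4f}"
            )
        if self.test_auroc is not None:
            lines.append(f"held-out test AUROC:      {self.test_auroc:.4f}")
        if self.test_accuracy is not None:
            lines.append(f"held-out test accuracy:   {self.test_accuracy:.4f}")
        lines.append("-" * 52)
        lines.append(self.member_table.to_string(index=False))
        return "\n".join(lines)
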