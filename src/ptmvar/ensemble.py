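"""Final model training, IQR-trimmed ensembling, calibration and attribution.

The top genomes from the architecture search are each retrained from
scratch (up to 100 epochs, batch 64, early stopping on validation
accuracy).  At prediction time every member cuts its own window length
around the queried site and the member probabilities are combined by an
outlier-excluded average: values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are
dropped and the rest averaged.  A site is called positive at probability
>= 0.5; a stricter high-confidence threshold is calibrated so that at most
1% of held-out negative test scores exceed it.

Positional attribution is a Monte-Carlo Shapley estimate with the all-pad
(all-zero) window as baseline: residues are revealed in random permutation
order and each position is credited with the average change in model output
caused by revealing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .corpus import Corpus
from .nas import ArchitectureGenome, repad_peptide
from .network import SequenceClassifier, train_classifier
from .seqcore import ProteinRecord, as_ptm, encode_batch, extract_window


@dataclass
class TrainedModel:
    genome: ArchitectureGenome
    classifier: SequenceClassifier
    val_accuracy: float

    def score_peptides(self, peptides) -> np.ndarray:
        """Scores after re-padding/cropping each peptide to this model's n."""
        return self.classifier.predict_proba(
            [repad_peptide(p, self.genome.window_len) for p in peptides]
        )


def train_final(
    genome: ArchitectureGenome,
    corpus: Corpus,
    seed: int = 0,
    *,
    max_epochs: int = 100,
    batch_size: int = 64,
    patience: int = 5,
) -> TrainedModel:
    """Train one ensemble member from scratch on the corpus' train split."""
    train_p, train_y = corpus.peptides_labels("train")
    val_p, val_y = corpus.peptides_labels("validation")
    if not train_p or not val_p:
        raise ValueError("corpus must have non-empty train and validation splits")
    tx = encode_batch([repad_peptide(p, genome.window_len) for p in train_p])
    vx = encode_batch([repad_peptide(p, genome.window_len) for p in val_p])
    model = SequenceClassifier(genome, seed=seed)
    hist = train_classifier(
        model, tx, train_y, vx, val_y,
        max_epochs=max_epochs, batch_size=batch_size, patience=patience, seed=seed,
    )
    return TrainedModel(genome, model, float(hist["best_val_accuracy"]))


def iqr_trimmed_mean(scores) -> float:
    """Mean after removing values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles are computed by linear interpolation.  With a single score or
    all-equal scores the bounds collapse and that value is returned.
    """
    arr = np.asarray(list(scores), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("iqr_trimmed_mean requires at least one score")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = arr[(arr >= lo) & (arr <= hi)]
    return float(kept.mean())


@dataclass
class EnsemblePredictor:
    """Up to ten trained models combined by IQR-trimmed averaging."""

    models: list
    positive_threshold: float = 0.5
    high_conf_threshold: float | None = None

    def member_scores(self, peptide: str) -> np.ndarray:
        """One probability per member for a centered peptide."""
        return np.array([m.score_peptides([peptide])[0] for m in self.models])

    def score_peptides(self, peptides) -> np.ndarray:
        """IQR-trimmed ensemble score for each centered peptide (batched)."""
        peptides = list(peptides)
        per_model = np.stack([m.score_peptides(peptides) for m in self.models])
        return np.array(
            [iqr_trimmed_mean(per_model[:, j]) for j in range(len(peptides))]
        )

    def predict_site(
        self, protein: ProteinRecord, position: int, ptm
    ) -> float:
        """Ensemble probability that the residue at ``position`` is modified."""
        ptm = as_ptm(ptm)
        residue = protein.residue(position)
        if residue not in ptm.target_residues:
            raise ValueError(
                f"residue {residue!r} at {protein.id}:{position} is not a "
                f"{ptm.name} target residue"
            )
        scores = [
            m.score_peptides(
                [extract_window(protein, position, m.genome.window_len).peptide]
            )[0]
            for m in self.models
        ]
        return iqr_trimmed_mean(scores)


def predict_site(ensemble: EnsemblePredictor, protein, position, ptm) -> float:
    return ensemble.predict_site(protein, position, ptm)


def scan_proteome(ensemble: EnsemblePredictor, proteins, ptm) -> list[dict]:
    """Score every target residue; classify at 0.5 and the 1%-FPR threshold."""
    ptm = as_ptm(ptm)
    rows: list[dict] = []
    for protein in proteins:
        positions = [
            i + 1
            for i, aa in enumerate(protein.sequence)
            if aa in ptm.target_residues
        ]
        if not positions:
            continue
        max_n = max(m.genome.window_len for m in ensemble.models)
        peptides = [extract_window(protein, p, max_n).peptide for p in positions]
        probs = ensemble.score_peptides(peptides)
        for pos, prob in zip(positions, probs):
            if prob < ensemble.positive_threshold:
                label = "negative"
            elif (
                ensemble.high_conf_threshold is not None
                and prob > ensemble.high_conf_threshold
            ):
                label = "high_confidence"
            else:
                label = "positive"
            rows.append(
                {
                    "protein_id": protein.id,
                    "position": pos,
                    "residue": protein.sequence[pos - 1],
                    "ptm": ptm.name,
                    "probability": float(prob),
                    "class": label,
                }
            )
    return rows


def calibrate_fpr_threshold(negative_scores, fpr: float = 0.01) -> float:
    """Smallest negative score t with fraction(negatives > t) <= fpr."""
    arr = np.sort(np.asarray(list(negative_scores), dtype=np.float64))
    if arr.size == 0:
        raise ValueError("calibration requires negative scores")
    n = arr.size
    for i, t in enumerate(arr):
        if (n - np.searchsorted(arr, t, side="right")) / n <= fpr:
            return float(t)
    return float(arr[-1])


def compute_auroc(scores_pos, scores_neg) -> float:
    """P(random positive outscores random negative), ties counted half."""
    pos = np.asarray(list(scores_pos), dtype=np.float64)
    neg = np.asarray(list(scores_neg), dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def positional_attribution(
    predict_fn, window, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Monte-Carlo Shapley contributions of each window position.

    ``predict_fn`` maps a batch of encoded windows (B, n, 22) to scores;
    ``window`` is an encoded (n, 22) array or a peptide string.  Positions
    are revealed one by one in ``n_samples`` random permutations starting
    from the all-zero baseline; the marginal change on revealing position i
    accumulates into its contribution.  Returns (contributions, efficiency
    residual |sum(contrib) - (f(x) - f(baseline))|), which is 0 up to
    Monte-Carlo noise by the Shapley efficiency axiom.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    encoded = (
        window if isinstance(window, np.ndarray) else encode_batch([window])[0]
    )
    n = encoded.shape[0]
    rng = np.random.default_rng(seed)
    contrib = np.zeros(n, dtype=np.float64)
    baseline = np.zeros_like(encoded)
    for _ in range(n_samples):
        order = rng.permutation(n)
        # batch the n+1 prefix states of this permutation in one forward pass
        states = np.empty((n + 1,) + encoded.shape, dtype=encoded.dtype)
        states[0] = baseline
        current = baseline.copy()
        for step, pos in enumerate(order):
            current[pos] = encoded[pos]
            states[step + 1] = current.copy()
        values = np.asarray(predict_fn(states), dtype=np.float64).reshape(-1)
        contrib[order] += np.diff(values)
    contrib /= n_samples
    full = float(np.asarray(predict_fn(np.stack([baseline, encoded]))).reshape(-1)[1])
    base = float(np.asarray(predict_fn(np.stack([baseline, encoded]))).reshape(-1)[0])
    residual = abs(contrib.sum() - (full - base))
    return contrib, residual


def exact_shapley(predict_fn, window) -> np.ndarray:
    """Exact Shapley values by subset enumeration; only for tiny windows."""
    from itertools import combinations
    from math import factorial

    encoded = (
        window if isinstance(window, np.ndarray) else encode_batch([window])[0]
    )
    n = encoded.shape[0]
    if n > 12:
        raise ValueError("exact enumeration is limited to n <= 12 positions")

    cache: dict[frozenset, float] = {}

    def value(subset: frozenset) -> float:
        if subset not in cache:
            x = np.zeros_like(encoded)
            for i in subset:
                x[i] = encoded[i]
            cache[subset] = float(np.asarray(predict_fn(x[None])).reshape(-1)[0])
        return cache[subset]

    contrib = np.zeros(n)
    players = list(range(n))
    for i in players:
        others = [j for j in players if j != i]
        for size in range(n):
            weight = factorial(size) * factorial(n - size - 1) / factorial(n)
            for subset in combinations(others, size):
                s = frozenset(subset)
                contrib[i] += weight * (value(s | {i}) - value(s))
    return contrib


def save_ensemble(ensemble: EnsemblePredictor, directory) -> None:
    """Write a model bundle: manifest JSON plus one weight file per member."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "positive_threshold": ensemble.positive_threshold,
        "high_conf_threshold": ensemble.high_conf_threshold,
        "members": [
            {"genome": m.genome.to_dict(), "val_accuracy": m.val_accuracy}
            for m in ensemble.models
        ],
    }
    (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for i, m in enumerate(ensemble.models):
        np.savez(
            directory / f"member_{i}.npz",
            **{f"w{j}": w for j, w in enumerate(m.classifier.get_weights())},
        )


def load_ensemble(directory) -> EnsemblePredictor:
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.json").read_text())
    models = []
    for i, member in enumerate(manifest["members"]):
        genome = ArchitectureGenome.from_dict(member["genome"])
        clf = SequenceClassifier(genome, seed=0)
        with np.load(directory / f"member_{i}.npz") as data:
            clf.set_weights([data[f"w{j}"] for j in range(len(data.files))])
        models.append(TrainedModel(genome, clf, member["val_accuracy"]))
    return EnsemblePredictor(
        models=models,
        positive_threshold=manifest["positive_threshold"],
        high_conf_threshold=manifest["high_conf_threshold"],
    )


def build_ensemble(
    genomes,
    corpus: Corpus,
    seed: int = 0,
    *,
    max_epochs: int = 100,
    fpr: float = 0.01,
) -> EnsemblePredictor:
    """Train all members, then calibrate the 1%-FPR threshold on test negatives."""
    models = [
        train_final(g, corpus, seed=seed + 1000 * i, max_epochs=max_epochs)
        for i, g in enumerate(genomes)
    ]
    ensemble = EnsemblePredictor(models=models)
    test_p, test_y = corpus.peptides_labels("test")
    neg = [p for p, y in zip(test_p, test_y) if y < 0.5]
    if neg:
        ensemble.high_conf_threshold = calibrate_fpr_threshold(
            ensemble.score_peptides(neg), fpr=fpr
        )
    return ensemble
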