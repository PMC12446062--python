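"""Genetic-algorithm search over CNN/BiGRU architectures and window length.

Each individual is an :class:`ArchitectureGenome`: 1-4 convolutional genes,
1-3 dense genes, an optimizer choice and the window length ``n`` (odd, 31-61
in production; smaller search spaces may be supplied for fast runs).  The
bidirectional GRU layer is fixed at 50 units and is not searched.  Fitness
is validation accuracy of a model trained from scratch for a bounded number
of epochs with early stopping.  Selection is a size-3 tournament with
elitism; crossover inherits each top-level field intact from one parent;
mutation independently resamples genes.  Fitness values are cached by
genome so duplicates are never retrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SequenceClassifier, train_classifier
from .seqcore import encode_batch

GRU_UNITS = 50


@dataclass(frozen=True)
class ConvGene:
    feature_maps: int
    kernel_size: int
    activation: str
    dropout: float
    batch_norm: bool
    max_pool: bool

    def __post_init__(self) -> None:
        if self.feature_maps < 1:
            raise ValueError("feature_maps must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if not 0.0 <= self.dropout <= 0.5:
            raise ValueError("dropout must be in [0, 0.5]")


@dataclass(frozen=True)
class DenseGene:
    units: int
    activation: str
    dropout: float
    batch_norm: bool

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if not 0.0 <= self.dropout <= 0.5:
            raise ValueError("dropout must be in [0, 0.5]")


@dataclass(frozen=True)
class ArchitectureGenome:
    conv_layers: tuple
    dense_layers: tuple
    optimizer: str
    window_len: int
    gru_units: int = GRU_UNITS

    def __post_init__(self) -> None:
        if not 1 <= len(self.conv_layers) <= 4:
            raise ValueError("1-4 conv layers required")
        if not 1 <= len(self.dense_layers) <= 3:
            raise ValueError("1-3 dense layers required")
        if self.gru_units != GRU_UNITS:
            raise ValueError(f"gru_units is fixed at {GRU_UNITS}")
        if self.window_len % 2 == 0:
            raise ValueError("window_len must be odd")

    def to_dict(self) -> dict:
        return {
            "conv_layers": [vars(g) | {} for g in self.conv_layers],
            "dense_layers": [vars(g) | {} for g in self.dense_layers],
            "optimizer": self.optimizer,
            "window_len": self.window_len,
            "gru_units": self.gru_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureGenome":
        return cls(
            conv_layers=tuple(ConvGene(**g) for g in d["conv_layers"]),
            dense_layers=tuple(DenseGene(**g) for g in d["dense_layers"]),
            optimizer=d["optimizer"],
            window_len=d["window_len"],
        )


@dataclass(frozen=True)
class SearchSpace:
    """Discrete option sets the GA samples from; one object, swappable whole."""

    feature_maps: tuple = (16, 32, 64, 128)
    kernel_sizes: tuple = (3, 5, 7, 9)
    dense_units: tuple = (32, 64, 128, 256)
    dropouts: tuple = (0.0, 0.1, 0.25, 0.5)
    activations: tuple = ("relu", "tanh", "elu", "sigmoid")
    optimizers: tuple = ("adam", "rmsprop", "sgd")
    conv_layer_counts: tuple = (1, 2, 3, 4)
    dense_layer_counts: tuple = (1, 2, 3)
    window_lens: tuple = tuple(range(31, 62, 2))


#: small space for fast fixtures and reduced searches
def reduced_space(window_lens=(31,)) -> SearchSpace:
    return SearchSpace(
        feature_maps=(16, 32),
        kernel_sizes=(3, 5),
        dense_units=(32, 64),
        dropouts=(0.0, 0.1),
        conv_layer_counts=(1, 2),
        dense_layer_counts=(1,),
        window_lens=tuple(window_lens),
    )


@dataclass
class GAConfig:
    generations: int = 20
    population: int = 50
    search_epochs: int = 20
    mutation_rate: float = 0.2
    crossover_rate: float = 0.7
    elitism_count: int = 2
    seed: int = 0
    space: SearchSpace = field(default_factory=SearchSpace)

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")


def _sample_conv_gene(space: SearchSpace, rng) -> ConvGene:
    return ConvGene(
        feature_maps=int(rng.choice(space.feature_maps)),
        kernel_size=int(rng.choice(space.kernel_sizes)),
        activation=str(rng.choice(space.activations)),
        dropout=float(rng.choice(space.dropouts)),
        batch_norm=bool(rng.random() < 0.5),
        max_pool=bool(rng.random() < 0.5),
    )


def _sample_dense_gene(space: SearchSpace, rng) -> DenseGene:
    return DenseGene(
        units=int(rng.choice(space.dense_units)),
        activation=str(rng.choice(space.activations)),
        dropout=float(rng.choice(space.dropouts)),
        batch_norm=bool(rng.random() < 0.5),
    )


def sample_genome(space: SearchSpace, rng) -> ArchitectureGenome:
    return ArchitectureGenome(
        conv_layers=tuple(
            _sample_conv_gene(space, rng)
            for _ in range(int(rng.choice(space.conv_layer_counts)))
        ),
        dense_layers=tuple(
            _sample_dense_gene(space, rng)
            for _ in range(int(rng.choice(space.dense_layer_counts)))
        ),
        optimizer=str(rng.choice(space.optimizers)),
        window_len=int(rng.choice(space.window_lens)),
    )


def init_population(config: GAConfig, rng=None) -> list[ArchitectureGenome]:
    """Uniformly sample ``config.population`` genomes from the search space."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return [sample_genome(config.space, rng) for _ in range(config.population)]


def mutate(
    genome: ArchitectureGenome, rng, rate: float, space: SearchSpace | None = None
) -> ArchitectureGenome:
    """Independently resample genes with probability ``rate``.

    Layer counts can also change by one (within bounds) with the same
    probability; a mutated genome always satisfies every invariant.
    """
    space = space or SearchSpace()
    conv = list(genome.conv_layers)
    dense = list(genome.dense_layers)
    def resize(layers, counts, sampler):
        can_add = len(layers) < max(counts)
        can_remove = len(layers) > min(counts)
        if can_add and (not can_remove or rng.random() < 0.5):
            layers.insert(int(rng.integers(len(layers) + 1)), sampler(space, rng))
        elif can_remove:
            layers.pop(int(rng.integers(len(layers))))

    if rng.random() < rate:  # change one layer count, staying within bounds
        resize(conv, space.conv_layer_counts, _sample_conv_gene)
    if rng.random() < rate:
        resize(dense, space.dense_layer_counts, _sample_dense_gene)
    conv = [
        _sample_conv_gene(space, rng) if rng.random() < rate else g for g in conv
    ]
    dense = [
        _sample_dense_gene(space, rng) if rng.random() < rate else g for g in dense
    ]
    optimizer = (
        str(rng.choice(space.optimizers)) if rng.random() < rate else genome.optimizer
    )
    window_len = (
        int(rng.choice(space.window_lens)) if rng.random() < rate else genome.window_len
    )
    return ArchitectureGenome(
        conv_layers=tuple(conv),
        dense_layers=tuple(dense),
        optimizer=optimizer,
        window_len=window_len,
    )


def crossover(
    a: ArchitectureGenome, b: ArchitectureGenome, rng
) -> ArchitectureGenome:
    """Uniform crossover over top-level fields, each inherited intact."""
    pick = lambda x, y: x if rng.random() < 0.5 else y  # noqa: E731
    return ArchitectureGenome(
        conv_layers=pick(a.conv_layers, b.conv_layers),
        dense_layers=pick(a.dense_layers, b.dense_layers),
        optimizer=pick(a.optimizer, b.optimizer),
        window_len=pick(a.window_len, b.window_len),
    )


def repad_peptide(peptide: str, n: int) -> str:
    """Center-crop or X-pad an odd-length peptide to odd length ``n``."""
    if n % 2 == 0 or len(peptide) % 2 == 0:
        raise ValueError("peptide and target length must be odd")
    half = (n - len(peptide)) // 2
    if half >= 0:
        return "X" * half + peptide + "X" * half
    return peptide[-half : len(peptide) + half]


@dataclass
class FitnessRecord:
    genome: ArchitectureGenome
    fitness: float
    generation: int


def evaluate_fitness(
    genome: ArchitectureGenome,
    train_peptides,
    train_y,
    val_peptides,
    val_y,
    config: GAConfig,
    seed: int = 0,
) -> float:
    """Validation accuracy of a model trained from scratch for this genome."""
    if len(train_peptides) == 0 or len(val_peptides) == 0:
        raise ValueError("empty train or validation split")
    tx = encode_batch([repad_peptide(p, genome.window_len) for p in train_peptides])
    vx = encode_batch([repad_peptide(p, genome.window_len) for p in val_peptides])
    model = SequenceClassifier(genome, seed=seed)
    hist = train_classifier(
        model,
        tx,
        np.asarray(train_y, dtype=np.float32),
        vx,
        np.asarray(val_y, dtype=np.float32),
        max_epochs=config.search_epochs,
        patience=3,
        seed=seed,
    )
    return float(hist["best_val_accuracy"])


def evolve(corpus, config: GAConfig, *, verbose: bool = False) -> list[FitnessRecord]:
    """Run the GA and return all evaluated genomes sorted by fitness.

    ``corpus`` is a :class:`ptmvar.corpus.Corpus` (train + validation splits
    are used; test is untouched).  The returned list is deduplicated by
    genome, descending in fitness; ``top_k`` slices the ensemble candidates.
    """
    rng = np.random.default_rng(config.seed)
    train_p, train_y = corpus.peptides_labels("train")
    val_p, val_y = corpus.peptides_labels("validation")
    cache: dict[ArchitectureGenome, float] = {}
    records: list[FitnessRecord] = []

    def fitness(genome: ArchitectureGenome, generation: int) -> float:
        if genome not in cache:
            cache[genome] = evaluate_fitness(
                genome, train_p, train_y, val_p, val_y, config,
                seed=int(rng.integers(2**31 - 1)),
            )
            records.append(FitnessRecord(genome, cache[genome], generation))
        return cache[genome]

    population = init_population(config, rng)
    for generation in range(config.generations):
        scored = sorted(
            ((fitness(g, generation), i, g) for i, g in enumerate(population)),
            key=lambda t: (-t[0], t[1]),
        )
        if verbose:
            print(f"generation {generation}: best fitness {scored[0][0]:.4f}")
        if generation == config.generations - 1:
            break
        elite = [g for _, _, g in scored[: config.elitism_count]]
        children = list(elite)
        while len(children) < config.population:
            pa = _tournament(scored, rng)
            pb = _tournament(scored, rng)
            child = (
                crossover(pa, pb, rng) if rng.random() < config.crossover_rate else pa
            )
            child = mutate(child, rng, config.mutation_rate, config.space)
            children.append(child)
        population = children
    return sorted(records, key=lambda r: -r.fitness)


def _tournament(scored, rng, k: int = 3) -> ArchitectureGenome:
    # `scored` is fitness-sorted, so the lowest sampled index wins
    picks = rng.integers(len(scored), size=k)
    return scored[min(picks)][2]


def top_k(records, k: int = 10) -> list[ArchitectureGenome]:
    """Best ``k`` distinct genomes by descending fitness."""
    out, seen = [], set()
    for rec in sorted(records, key=lambda r: -r.fitness):
        if rec.genome not in seen:
            seen.add(rec.genome)
            out.append(rec.genome)
        if len(out) == k:
            break
    return out
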