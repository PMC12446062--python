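"""Shared fixtures: tiny proteins, stub ensemble members, small corpora."""

import numpy as np
import pytest
from hypothesis import settings

from ptmvar.ensemble import EnsemblePredictor

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from ptmvar.nas import repad_peptide
from ptmvar.seqcore import ProteinRecord


class StubModel:
    """Ensemble member with a fixed or rule-based score; no training."""

    class _Genome:
        def __init__(self, window_len):
            self.window_len = window_len

    def __init__(self, score=0.7, window_len=11, rule=None):
        self.genome = self._Genome(window_len)
        self._score = score
        self._rule = rule  # optional callable peptide -> score

    def score_peptides(self, peptides):
        peptides = [repad_peptide(p, self.genome.window_len) for p in peptides]
        if self._rule is not None:
            return np.array([self._rule(p) for p in peptides], dtype=float)
        return np.full(len(peptides), self._score, dtype=float)


@pytest.fixture
def stub_ensemble():
    """Ten constant-score members at 0.7."""
    return EnsemblePredictor(models=[StubModel(0.7) for _ in range(10)])


def sequon_rule(peptide: str) -> float:
    """Score 0.95 when the window center carries an N-!P-[ST] sequon, else 0.05."""
    center = (len(peptide) - 1) // 2
    ok = (
        peptide[center] == "N"
        and center + 2 < len(peptide)
        and peptide[center + 1] != "P"
        and peptide[center + 2] in "ST"
    )
    return 0.95 if ok else 0.05


@pytest.fixture
def rule_ensemble():
    """Three members that deterministically recognize the sequon motif."""
    return EnsemblePredictor(
        models=[StubModel(window_len=11, rule=sequon_rule) for _ in range(3)]
    )


@pytest.fixture
def toy_protein():
    return ProteinRecord(id="P1", sequence="MKVSNGSTRRASPLYKNDTA")
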