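"""End-to-end P300 speller pipelines.

``SpellerPipeline`` chains the full detection stack — class balancing,
STLFL projection, DRBM scoring, repetition-aggregated decoding — behind a
fit/score interface that the hyperparameter search can drive.  ``FldPipeline``
is the vectorized Fisher-discriminant baseline using the identical decoding
path, so accuracy differences isolate the feature-learning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import discriminant, drbm
from .decoding import DecodeResult, decode_session
from .epochs import EpochSet
from .preprocessing import balance_classes
from .synthetic import ParadigmSpec


@dataclass
class SpellerPipeline:
    paradigm: ParadigmSpec
    truth: list[str]
    seed: int
    alpha: float = 1.0
    beta: float = 0.0
    h: int = 4
    n_hidden: int = 5
    drbm_epochs: int = 100
    generative_weight: float = 0.01
    model: discriminant.StlflModel | None = field(default=None, repr=False)
    classifier: drbm.DrbmModel | None = field(default=None, repr=False)

    def fit(self, train_epochs: EpochSet) -> "SpellerPipeline":
        balanced = balance_classes(train_epochs, seed=self.seed)
        self.model = discriminant.fit_stlfl(balanced, alpha=self.alpha,
                                            beta=self.beta, h=self.h)
        feats = discriminant.transform(self.model, balanced)
        cfg = drbm.DrbmTrainConfig(seed=self.seed,
                                   n_epochs=self.drbm_epochs,
                                   generative_weight=self.generative_weight)
        self.classifier = drbm.fit_drbm(feats.features, feats.labels, cfg,
                                        n_hidden=self.n_hidden)
        return self

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        if self.model is None or self.classifier is None:
            raise RuntimeError("pipeline is not fitted")
        feats = discriminant.transform(self.model, epochs)
        return drbm.score_p300(self.classifier, feats.features)

    def decode(self, epochs: EpochSet, budgets=None) -> DecodeResult:
        return decode_session(epochs, self.score_epochs(epochs),
                              self.paradigm, self.truth, budgets=budgets)

    def score(self, epochs: EpochSet) -> float:
        """Character-selection accuracy at the full repetition budget."""
        m = int(epochs.repetition_index.max()) + 1
        return self.decode(epochs, budgets=[m]).accuracy_by_repetition[m]


@dataclass
class FldPipeline:
    """Vectorized Fisher-discriminant baseline over the same decoder."""

    paradigm: ParadigmSpec
    truth: list[str]
    seed: int
    direction: np.ndarray | None = field(default=None, repr=False)

    def fit(self, train_epochs: EpochSet) -> "FldPipeline":
        balanced = balance_classes(train_epochs, seed=self.seed)
        self.direction = discriminant.fit_fld_baseline(balanced)
        return self

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        if self.direction is None:
            raise RuntimeError("pipeline is not fitted")
        return discriminant.fld_scores(self.direction, epochs)

    def decode(self, epochs: EpochSet, budgets=None) -> DecodeResult:
        return decode_session(epochs, self.score_epochs(epochs),
                              self.paradigm, self.truth, budgets=budgets)

    def score(self, epochs: EpochSet) -> float:
        m = int(epochs.repetition_index.max()) + 1
        return self.decode(epochs, budgets=[m]).accuracy_by_repetition[m]
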