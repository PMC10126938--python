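"""Speller metrics and hyperparameter search.

Information transfer rate (Wolpaw-style) in bits per minute:

    bits = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))
    ITR  = bits * 60 / T_char

with N the number of selectable characters, P the character accuracy and
T_char the selection time.  For the matrix speller at 12 flashes of 175 ms
per repetition plus a 2.5 s inter-character pause,

    T_char(rep) = 2.5 + 2.1 * rep   (seconds, 1 <= rep <= 15).

Feature separability is summarized by the pointwise biserial correlation

    r = sqrt(N1 N2) / (N1 + N2) * (mean_1 - mean_2) / std_all,

whose square is reported (with the population SD, r is exactly the Pearson
correlation between feature and binary label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet, TARGET_LABEL

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(1.0, 5.0 + 1e-9, 0.2), 10))
DEFAULT_BETA_GRID = (0.0, 0.01, 0.001, 0.0001, 0.1, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0)


def selection_time(rep: int) -> float:
    """Seconds to select one matrix-speller character at ``rep`` repetitions."""
    if not 1 <= rep <= 15:
        raise ValueError("rep must be in 1..15")
    return 2.5 + 2.1 * rep


def itr_bpm(p: float, n: int, t_char: float) -> float:
    """Information transfer rate in bits per minute.

    Continuous in P on [0, 1] (x log2 x -> 0 at the endpoints); zero at
    chance P = 1/N and increasing above it.
    """
    if not 0 <= p <= 1:
        raise ValueError("accuracy P must be in [0, 1]")
    if n < 2:
        raise ValueError("alphabet size N must be >= 2")
    if t_char <= 0:
        raise ValueError("T_char must be positive")
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(bits * 60.0 / t_char)


def biserial_r2(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """Squared pointwise biserial correlation of one feature with the labels."""
    x = np.asarray(feature_column, dtype=np.float64)
    labels = np.asarray(labels)
    mask1 = labels == TARGET_LABEL
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    sd = x.std()
    if sd == 0:
        raise ValueError("pooled standard deviation is zero")
    r = np.sqrt(n1 * n2) / (n1 + n2) * (x[mask1].mean() - x[~mask1].mean()) / sd
    return float(r ** 2)


def accuracy_table(decode_results, budgets: list[int]) -> pd.DataFrame:
    """Mean and sample SD of accuracy per repetition budget across sessions."""
    if not decode_results:
        raise ValueError("need at least one decode result")
    rows = []
    for m in budgets:
        accs = np.array([res.accuracy_by_repetition[m] for res in decode_results])
        sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
        rows.append((m, float(accs.mean()), sd))
    return pd.DataFrame(rows, columns=["budget", "mean_accuracy", "sd_accuracy"])


@dataclass(frozen=True)
class SearchSpec:
    """Grid and validation scheme for the (alpha, beta) search.

    ``k_folds`` >= 2 requests character-stratified k-fold cross-validation;
    a float in (0, 1) requests a single seeded holdout of that fraction of
    character trials.
    """

    seed: int
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    beta_grid: tuple = DEFAULT_BETA_GRID
    k_folds: float = 5

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0 or len(self.beta_grid) == 0:
            raise ValueError("grids must be non-empty")
        kf = self.k_folds
        if not ((isinstance(kf, (int, np.integer)) and kf >= 2)
                or (0 < kf < 1)):
            raise ValueError("k_folds must be an int >= 2 or a fraction in (0, 1)")


@dataclass
class TuneResult:
    alpha: float
    beta: float
    cv_table: pd.DataFrame
    final_pipeline: object = field(default=None, repr=False)


def _char_folds(char_ids: np.ndarray, spec: SearchSpec) -> list[np.ndarray]:
    """Split character-trial ids into validation folds (seeded)."""
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(char_ids)
    if isinstance(spec.k_folds, (int, np.integer)):
        if len(char_ids) < spec.k_folds:
            raise ValueError("fewer character trials than folds")
        return [perm[i::spec.k_folds] for i in range(int(spec.k_folds))]
    n_val = max(1, int(round(spec.k_folds * len(char_ids))))
    return [perm[:n_val]]


def tune_hyperparameters(epochs: EpochSet, spec: SearchSpec,
                         pipeline_factory) -> TuneResult:
    """Select (alpha, beta) by validation character accuracy.

    Folds are stratified at the character-trial level so flashes of one
    character never straddle train and validation.  ``pipeline_factory(alpha,
    beta)`` must return an object with ``fit(epochs)`` and ``score(epochs) ->
    accuracy``.  Ties go to the smaller beta, then the smaller alpha; the
    winning pipeline is refit on all epochs.
    """
    char_ids = np.unique(epochs.char_index)
    folds = _char_folds(char_ids, spec)
    rows = []
    for alpha in spec.alpha_grid:
        for beta in spec.beta_grid:
            for fi, val_chars in enumerate(folds):
                val_mask = np.isin(epochs.char_index, val_chars)
                pipe = pipeline_factory(alpha, beta)
                pipe.fit(epochs.subset(~val_mask))
                acc = pipe.score(epochs.subset(val_mask))
                rows.append((float(alpha), float(beta), fi, float(acc)))
    cv_table = pd.DataFrame(rows, columns=["alpha", "beta", "fold", "accuracy"])
    means = (cv_table.groupby(["alpha", "beta"])["accuracy"].mean()
             .reset_index()
             .sort_values(["accuracy", "beta", "alpha"],
                          ascending=[False, True, True],
                          kind="stable"))
    best = means.iloc[0]
    final = pipeline_factory(best["alpha"], best["beta"])
    final.fit(epochs)
    return TuneResult(alpha=float(best["alpha"]), beta=float(best["beta"]),
                      cv_table=cv_table, final_pipeline=final)
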