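"""Repetition-aggregated character decoding.

Per-epoch P300 scores are summed per stimulus code over the first m
repetitions, C(j) = sum_k S_j(k); the selected candidate is argmax_j C(j)
(ties broken by lowest code).  For the matrix speller the attended character
is the intersection of the winning row and column; for RSVP the winner is a
symbol group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .synthetic import ParadigmSpec, RCP, RSVP


@dataclass
class DecodeResult:
    """Predictions and accuracy per repetition budget for one session."""

    predictions: pd.DataFrame  # columns: char_index, budget, predicted, truth, correct
    accuracy_by_repetition: dict[int, float]
    scores_table: pd.DataFrame  # columns: char_index, budget, code, score

    def accuracy_curve(self) -> pd.Series:
        return pd.Series(self.accuracy_by_repetition).sort_index()


def aggregate_scores(scores: np.ndarray, codes: np.ndarray,
                     repetition_index: np.ndarray, m: int,
                     candidates: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sum scores per candidate code over the first ``m`` repetitions.

    Returns ``(candidates, totals)``.  A candidate with no flash in the
    first m repetitions indicates a malformed schedule and raises.
    """
    scores = np.asarray(scores, dtype=np.float64)
    codes = np.asarray(codes)
    repetition_index = np.asarray(repetition_index)
    if not (len(scores) == len(codes) == len(repetition_index)):
        raise ValueError("scores, codes and repetition_index must align")
    if m < 1:
        raise ValueError("m must be >= 1")
    if candidates is None:
        candidates = np.unique(codes)
    keep = repetition_index < m
    totals = np.empty(len(candidates))
    for i, cand in enumerate(candidates):
        mask = keep & (codes == cand)
        if not mask.any():
            raise ValueError(
                f"candidate code {cand} has no flashes in the first {m} repetitions"
            )
        totals[i] = scores[mask].sum()
    return np.asarray(candidates), totals


def _argmax_low_tie(values: np.ndarray) -> int:
    return int(np.argmax(values))  # np.argmax returns the first (lowest) maximum


def select_character_rcp(c_rows: np.ndarray, c_cols: np.ndarray,
                         alphabet) -> str:
    """Intersect the winning row and column in the 6x6 row-major layout."""
    if len(c_rows) != 6 or len(c_cols) != 6:
        raise ValueError("expected 6 row and 6 column candidates")
    if len(alphabet) != 36:
        raise ValueError("RCP alphabet must have 36 symbols")
    r = _argmax_low_tie(np.asarray(c_rows))
    c = _argmax_low_tie(np.asarray(c_cols))
    return alphabet[r * 6 + c]


def select_group_rsvp(c_groups: np.ndarray) -> int:
    """Pick the winning RSVP group (1-based, lowest-index tie break)."""
    if len(c_groups) != 9:
        raise ValueError("expected 9 group candidates")
    return _argmax_low_tie(np.asarray(c_groups)) + 1


def decode_session(epochs: EpochSet, scores: np.ndarray,
                   paradigm: ParadigmSpec, truth: list[str],
                   budgets: list[int] | None = None) -> DecodeResult:
    """Decode every character trial at each repetition budget.

    ``truth`` gives the attended symbol per character trial (indexed by
    ``epochs.char_index``).  For RSVP, predictions and truth are compared at
    the group level (the within-group symbol is resolved by a separate
    modality and is outside this decoder).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != epochs.n_epochs:
        raise ValueError("scores must align with epochs")
    if budgets is None:
        budgets = list(range(1, paradigm.n_repetitions + 1))
    if max(budgets) > paradigm.n_repetitions:
        raise ValueError("budget exceeds available repetitions")

    chars = np.unique(epochs.char_index)
    pred_rows, score_rows = [], []
    accuracy: dict[int, float] = {}
    for m in budgets:
        correct = 0
        for ci in chars:
            mask = epochs.char_index == ci
            cand, tot = aggregate_scores(scores[mask], epochs.codes[mask],
                                         epochs.repetition_index[mask], m,
                                         candidates=paradigm.codes)
            for code, val in zip(cand, tot):
                score_rows.append((int(ci), m, int(code), float(val)))
            if paradigm.kind == RCP:
                nr = paradigm.n_rows
                predicted = select_character_rcp(tot[:nr], tot[nr:],
                                                 paradigm.alphabet)
                true_val = truth[ci]
            else:
                predicted = select_group_rsvp(tot)
                true_val = paradigm.group_of(truth[ci])
            ok = predicted == true_val
            correct += ok
            pred_rows.append((int(ci), m, predicted, true_val, bool(ok)))
        accuracy[m] = correct / len(chars)

    predictions = pd.DataFrame(
        pred_rows, columns=["char_index", "budget", "predicted", "truth", "correct"]
    )
    scores_table = pd.DataFrame(
        score_rows, columns=["char_index", "budget", "code", "score"]
    )
    return DecodeResult(predictions=predictions,
                        accuracy_by_repetition=accuracy,
                        scores_table=scores_table)
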