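"""Window-level ROC evaluation: partial AUC to 5% FPR (pAUC5).

Only the area under the empirical ROC curve for false positive rates up
to 0.05 is scored, excluding the low-specificity region; values are
rescaled so a random classifier scores 1 (its area over the strip is
0.05^2 / 2 = 0.00125).  Any per-window statistic can be scored — WPPA
for this package, or e.g. a minimum-p-value summary for a frequentist
comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .windows import EFFECT_TYPES, WindowTable

__all__ = ["RocInput", "pauc5", "rescale_pauc5", "evaluate_run"]

FPR_CUT = 0.05
RANDOM_AREA = FPR_CUT**2 / 2.0


@dataclass
class RocInput:
    """Per-window scores (higher = more associated) and binary truth."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels).astype(bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and aligned")
        if self.labels.all() or not self.labels.any():
            raise ValueError("need at least one positive and one negative label")


def pauc5(input: RocInput) -> float:
    """Raw partial area under the empirical ROC for FPR in [0, 0.05].

    Ties in scores move the threshold simultaneously (standard empirical
    ROC); the curve is interpolated vertically at FPR = 0.05.
    """
    fpr, tpr, _ = roc_curve(input.labels, input.scores, drop_intermediate=False)
    # height at the cut: bottom of any vertical rise located exactly at it
    # (zero-width segments must not contribute area), else linear
    # interpolation inside the segment straddling the cut
    idx = int(np.searchsorted(fpr, FPR_CUT, side="left"))
    if idx >= len(fpr):
        tpr_cut = tpr[-1]
    elif fpr[idx] == FPR_CUT:
        tpr_cut = tpr[idx]
    else:
        span = fpr[idx] - fpr[idx - 1]
        frac = (FPR_CUT - fpr[idx - 1]) / span
        tpr_cut = tpr[idx - 1] + frac * (tpr[idx] - tpr[idx - 1])
    keep = fpr < FPR_CUT
    xs = np.append(fpr[keep], FPR_CUT)
    ys = np.append(tpr[keep], float(tpr_cut))
    return float(np.trapezoid(ys, xs))


def rescale_pauc5(raw: float) -> float:
    """Rescale so the random classifier's pAUC5 equals 1."""
    return raw / RANDOM_AREA


def evaluate_run(window_table: WindowTable, truth: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rescaled pAUC5 of WPPA against simulation truth.

    One row per (effect type, trait).  Traits for which an effect type
    does not exist (no true window for it anywhere, e.g. indirect
    effects on a source trait) or whose truth is degenerate (all
    positive) get NaN with an explanatory note.
    """
    rows = []
    for name in EFFECT_TYPES:
        if name not in window_table.wppa:
            continue
        scores_all = window_table.wppa[name]
        labels_all = np.asarray(truth[name], dtype=bool)
        for k in range(scores_all.shape[1]):
            labels = labels_all[:, k]
            note = ""
            raw = rescaled = np.nan
            if not labels.any():
                note = "not applicable: no true window for this effect type"
            elif labels.all():
                note = "degenerate truth: no negative window"
            else:
                raw = pauc5(RocInput(scores_all[:, k], labels))
                rescaled = rescale_pauc5(raw)
            rows.append(
                {
                    "trait": k,
                    "effect_type": name,
                    "raw_pauc5": raw,
                    "rescaled_pauc5": rescaled,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
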