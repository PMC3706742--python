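"""Linear score-level fusion of the machine-learning and thesaurus runs.

Both rankings are normalized to [0, 1], then combined(t) = w * ml(t) +
(1 - w) * tb(t) with w = 0.7 by default — the mixing weight at which the
combined run improves on either single classifier.  A term absent from one
run contributes 0 from that run; the combined term set is the union of the
two input term sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .predictions import Prediction, rank_terms

DEFAULT_WEIGHT_ML = 0.7


@dataclass
class CombinerConfig:
    weight_ml: float = DEFAULT_WEIGHT_ML

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_ml <= 1.0:
            raise ValueError(f"weight_ml must be in [0, 1], got {self.weight_ml}")


def normalize_run(predictions: Sequence[Prediction]) -> list[Prediction]:
    """Scale scores to [0, 1] with the lower anchor fixed at 0.

    Classifier scores are nonnegative with a natural zero (no evidence), so
    the run is normalized by its maximum: max score -> 1, score 0 -> 0, and
    a score of half the maximum keeps weight 0.5 rather than being crushed
    to the observed minimum.  This makes normalization idempotent.  A
    single-item or all-equal run normalizes to 1.0 everywhere — presence in
    a run is evidence.  Runs containing negative scores (foreign input)
    fall back to true min-max.
    """
    if not predictions:
        return []
    scores = [p.score for p in predictions]
    hi, lo = max(scores), min(scores)
    if hi == lo:
        return [Prediction(p.go_id, 1.0, p.rank) for p in predictions]
    if lo < 0.0:
        return [
            Prediction(p.go_id, (p.score - lo) / (hi - lo), p.rank)
            for p in predictions
        ]
    return [Prediction(p.go_id, p.score / hi, p.rank) for p in predictions]


def combine(
    run_ml: Sequence[Prediction],
    run_tb: Sequence[Prediction],
    config: CombinerConfig | None = None,
) -> list[Prediction]:
    """Fuse two rankings for the same query into one."""
    if config is None:
        config = CombinerConfig()
    w = config.weight_ml
    ml_scores = {p.go_id: p.score for p in normalize_run(run_ml)}
    tb_scores = {p.go_id: p.score for p in normalize_run(run_tb)}
    combined = {
        go_id: w * ml_scores.get(go_id, 0.0) + (1.0 - w) * tb_scores.get(go_id, 0.0)
        for go_id in set(ml_scores) | set(tb_scores)
    }
    return rank_terms(combined)
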