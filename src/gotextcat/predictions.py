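"""Ranked GO-term predictions and TREC run-format I/O.

Both classifiers and the combiner emit the same shape: a per-query ranked
list of (GO id, score), written in the standard whitespace-separated TREC
run format ``<query id> Q0 <GO id> <rank> <score> <run tag>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

#: rankings are truncated to this depth when written as runs
DEFAULT_RUN_DEPTH = 100


@dataclass(frozen=True)
class Prediction:
    go_id: str
    score: float
    rank: int


def as_predictions(scored: Iterable[tuple[str, float]]) -> list[Prediction]:
    """Attach 1-based ranks; input must already be sorted."""
    return [
        Prediction(go_id=go_id, score=score, rank=i)
        for i, (go_id, score) in enumerate(scored, start=1)
    ]


def rank_terms(scores: Mapping[str, float]) -> list[Prediction]:
    """Sort score descending, ties by ascending GO id, and rank."""
    ordered = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return as_predictions(ordered)


def write_run(
    runs: Mapping[str, list[Prediction]],
    stream: IO[str],
    run_tag: str,
    depth: int = DEFAULT_RUN_DEPTH,
) -> None:
    for query_id in runs:
        for p in runs[query_id][:depth]:
            stream.write(
                f"{query_id} Q0 {p.go_id} {p.rank} {p.score:.6f} {run_tag}\n"
            )


def read_run(stream: IO[str] | str) -> dict[str, list[Prediction]]:
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    runs: dict[str, list[Prediction]] = {}
    for line in lines:
        if not line.strip():
            continue
        qid, _q0, go_id, rank, score, _tag = line.split()
        runs.setdefault(qid, []).append(
            Prediction(go_id=go_id, score=float(score), rank=int(rank))
        )
    for preds in runs.values():
        preds.sort(key=lambda p: p.rank)
    return runs
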