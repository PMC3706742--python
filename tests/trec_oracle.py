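"""Independent reference for the TREC evaluation measures.

A deliberately separate, file-based re-implementation of the standard
evaluator's recip_rank and recall_k measures: it reads TREC run and qrels
files from disk and shares no code with gotextcat.evaluation.  Rankings are
rebuilt from the score column (descending score, ties by descending
document id — the reference evaluator's sort), not from the rank column.
"""

from __future__ import annotations


def _read_qrels(path: str) -> dict[str, set[str]]:
    gold: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            qid, _iter, docno, rel = parts
            if int(rel) > 0:
                gold.setdefault(qid, set()).add(docno)
    return gold


def _read_run(path: str) -> dict[str, list[str]]:
    rows: dict[str, list[tuple[float, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            qid, _q0, docno, _rank, score, _tag = parts
            rows.setdefault(qid, []).append((float(score), docno))
    ranked: dict[str, list[str]] = {}
    for qid, items in rows.items():
        # descending score; break score ties by descending docno
        # (two stable sorts: docno desc first, then score desc)
        items.sort(key=lambda t: t[1], reverse=True)
        items.sort(key=lambda t: t[0], reverse=True)
        ranked[qid] = [docno for _score, docno in items]
    return ranked


def trec_measures(run_path: str, qrels_path: str, ks=(5, 20)):
    """Mean recip_rank and recall_k over all qrels queries."""
    gold = _read_qrels(qrels_path)
    ranked = _read_run(run_path)
    n = len(gold)
    rr_total = 0.0
    recall_totals = {k: 0.0 for k in ks}
    for qid, rel in gold.items():
        docs = ranked.get(qid, [])
        for position, docno in enumerate(docs, start=1):
            if docno in rel:
                rr_total += 1.0 / position
                break
        for k in ks:
            hits = sum(1 for docno in docs[:k] if docno in rel)
            recall_totals[k] += hits / len(rel)
    return {
        "recip_rank": rr_total / n if n else 0.0,
        **{f"recall_{k}": recall_totals[k] / n if n else 0.0 for k in ks},
    }
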