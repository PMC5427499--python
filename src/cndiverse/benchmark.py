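"""Truth-vs-call evaluation by reciprocal-overlap matching.

Used to measure how well the caller recovers simulated ground truth: a call
matches a truth interval when both cover at least ``min_reciprocal`` of
each other and agree on the event class (dup/del).
"""

from __future__ import annotations

import pandas as pd

from .calling import CNVR


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when disjoint."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def match_strain(
    calls: list[CNVR],
    truth: pd.DataFrame,
    min_reciprocal: float = 0.8,
    require_class: bool = True,
) -> tuple[int, int, int]:
    """(matched calls, total calls, matched truth intervals) for one strain.

    ``truth`` has columns chrom/start/end/class with one row per interval
    where the strain's CN differs from baseline.  Matching is many-to-one:
    a call (or truth row) counts as matched when any counterpart passes the
    reciprocal-overlap and class checks.
    """
    truth_rows = truth.to_dict("records")

    def is_match(r: CNVR, t: dict) -> bool:
        return (
            r.chromosome == t["chrom"]
            and (not require_class or r.event_class == t["class"])
            and reciprocal_overlap(r.start, r.end, t["start"], t["end"])
            >= min_reciprocal
        )

    matched_calls = sum(
        1 for r in calls if any(is_match(r, t) for t in truth_rows)
    )
    matched_truth = sum(
        1 for t in truth_rows if any(is_match(r, t) for r in calls)
    )
    return matched_calls, len(calls), matched_truth


def precision_recall(
    calls_by_strain: dict[str, list[CNVR]],
    truth_by_strain: dict[str, pd.DataFrame],
    min_reciprocal: float = 0.8,
    require_class: bool = True,
) -> dict[str, float]:
    """Pooled precision and recall across strains."""
    tp_calls = n_calls = tp_truth = n_truth = 0
    for sid, truth in truth_by_strain.items():
        calls = calls_by_strain.get(sid, [])
        mc, nc, mt = match_strain(calls, truth, min_reciprocal, require_class)
        tp_calls += mc
        n_calls += nc
        tp_truth += mt
        n_truth += len(truth)
    return {
        "precision": tp_calls / n_calls if n_calls else float("nan"),
        "recall": tp_truth / n_truth if n_truth else float("nan"),
        "n_calls": n_calls,
        "n_truth": n_truth,
    }
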