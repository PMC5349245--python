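"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths of the package: identity comes
from a full-matrix dynamic program built here (no edlib), clustering
from a direct transcription of the greedy rule with no word prescreen,
and excision from slicing printed 1-based coordinates directly.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTRYSWKMBDHVNU", "TGCAYRSWMKVHDBNA")


def semiglobal_distance_oracle(query: str, target: str) -> int:
    """Min edit distance of *query* against any substring of *target*.

    Full (m+1)×(n+1) matrix; first row zero (free leading target gap),
    answer is the minimum of the last row (free trailing target gap).
    """
    m, n = len(query), len(target)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    j = np.arange(1, n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = prev[:-1] + (t != q[i - 1])
        dele = prev[1:] + 1
        best = np.minimum(sub, dele)
        # gap-in-target column: cur[j] = min(best[j], cur[j-1]+1); the
        # left-to-right recurrence equals j + running-min of (best[i]-i, i)
        g = np.concatenate(([np.int32(i)], best - j))
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        cur[1:] = j + np.minimum.accumulate(g)[:-1]
        cur[1:] = np.minimum(cur[1:], best)
        prev = cur
    return int(prev.min())


def identity_oracle(a: str, b: str) -> float:
    """Semi-global identity, 1 − d/len(shorter), symmetric."""
    if a == b:
        return 1.0
    if len(a) > len(b):
        a, b = b, a
    d = semiglobal_distance_oracle(a, b)
    if len(a) == len(b):
        d = min(d, semiglobal_distance_oracle(b, a))
    return 1.0 - d / len(a)


def greedy_cluster_oracle(entries, threshold: float) -> list[list[str]]:
    """The greedy rule, naively: no prescreen, exhaustive alignment.

    *entries* are objects with .seqid and .sequence; returns member-id
    lists, centroid first, in centroid creation order.
    """
    ordered = sorted(entries, key=lambda e: (-len(e.sequence), e.seqid))
    clusters: list[list] = []
    for entry in ordered:
        for members in clusters:
            if identity_oracle(entry.sequence, members[0].sequence) >= threshold:
                members.append(entry)
                break
        else:
            clusters.append([entry])
    return [[e.seqid for e in members] for members in clusters]


def excise_by_printed_coordinates(sequence: str, printed_spans, reverse: bool) -> str:
    """Excision oracle: slice 1-based inclusive printed coordinates directly."""
    chunk = "".join(sequence[lo - 1:hi] for lo, hi in printed_spans)
    if reverse:
        chunk = chunk.translate(_COMP)[::-1]
    return chunk
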