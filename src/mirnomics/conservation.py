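"""Mouse-to-human conservation screening of mature miRNA sequences.

A pair is conserved when the longest exactly matching contiguous run
(longest common substring over all offsets, U treated as T,
case-insensitive) reaches the threshold k (default 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

DEFAULT_MIN_RUN = 7


@dataclass
class ConservationCall:
    mouse_id: str
    human_id: str
    longest_run: int
    conserved: bool


def _canonical(seq: str) -> str:
    return seq.upper().replace("U", "T")


def longest_consecutive_match(seq_a: str, seq_b: str) -> int:
    """Length of the longest common contiguous substring of two sequences.

    Classic dynamic programme over suffix match lengths; O(|a| * |b|).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = _canonical(seq_a)
    b = _canonical(seq_b)
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def screen_conservation(
    mouse_seqs: Mapping[str, str],
    human_seqs: Mapping[str, str],
    pairs: Iterable[tuple[str, str]],
    k: int = DEFAULT_MIN_RUN,
) -> list[ConservationCall]:
    """Score each (mouse, human) pair; conserved iff longest run >= k."""
    calls = []
    for mouse_id, human_id in pairs:
        if mouse_id not in mouse_seqs:
            raise KeyError(f"mouse sequence missing: {mouse_id!r}")
        if human_id not in human_seqs:
            raise KeyError(f"human sequence missing: {human_id!r}")
        run = longest_consecutive_match(mouse_seqs[mouse_id], human_seqs[human_id])
        calls.append(ConservationCall(mouse_id, human_id, run, run >= k))
    return calls


def conservation_table(calls: list[ConservationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [c.mouse_id for c in calls],
            "human_id": [c.human_id for c in calls],
            "longest_run": [c.longest_run for c in calls],
            "conserved": [c.conserved for c in calls],
        }
    )
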