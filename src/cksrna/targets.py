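"""Plant-style sRNA target prediction by complementarity expectation scoring.

The sRNA is aligned antiparallel and gapless against every window of every
transcript (sense strand). Position i counts from the sRNA 5' end: a
Watson-Crick pair scores 0, a G:U wobble 0.5 and a mismatch 1.0; penalties
double in the seed region (positions 2-13 inclusive). The expectation is the
total penalty — 0 means perfect complementarity. Any non-match in the
central positions 9-11 predicts translational inhibition instead of
cleavage. Sites at or below the expectation cutoff are reported, best site
per transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .util import normalize, revcomp

SEED_START = 2       # 1-based sRNA positions with doubled penalties
SEED_END = 13
CENTRAL = (9, 11)    # cleavage/translation decision window

MATCH, MISMATCH, GU = "match", "mismatch", "G:U"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DuplexScore:
    srna_seq: str
    transcript_id: str
    site_start: int
    site_end: int
    expectation: float
    states: tuple
    inhibition: str      # 'cleavage' | 'translation'


def _position_weight(pos_1based: int) -> float:
    return 2.0 if SEED_START <= pos_1based <= SEED_END else 1.0


def score_duplex(srna_seq: str, target_window: str,
                 transcript_id: str = "", site_start: int = 0) -> DuplexScore:
    """Score one sRNA against one equal-length transcript window."""
    s = normalize(srna_seq)
    w = normalize(target_window)
    if len(s) != len(w):
        raise ValueError("target window length must equal sRNA length")
    if not set(s + w) <= set("ACGT"):
        raise ValueError("sequences must be A/C/G/T(U) only")
    n = len(s)
    states = []
    expectation = 0.0
    translation = False
    for i in range(n):
        t = w[n - 1 - i]  # transcript base paired with sRNA position i
        if t == _COMP[s[i]]:
            state, penalty = MATCH, 0.0
        elif (s[i] == "G" and t == "T") or (s[i] == "T" and t == "G"):
            state, penalty = GU, 0.5
        else:
            state, penalty = MISMATCH, 1.0
        expectation += penalty * _position_weight(i + 1)
        if state != MATCH and CENTRAL[0] <= i + 1 <= CENTRAL[1]:
            translation = True
        states.append(state)
    return DuplexScore(
        s, transcript_id, site_start, site_start + n, expectation,
        tuple(states), "translation" if translation else "cleavage",
    )


def _expectations_vectorized(srna: str, transcript: str) -> np.ndarray:
    """Expectation of every window of ``transcript`` against ``srna``."""
    n = len(srna)
    arr = np.frombuffer(transcript.encode(), dtype=np.uint8)
    windows = sliding_window_view(arr, n)
    # window position j pairs with sRNA position i = n-1-j
    rc = np.frombuffer(revcomp(srna).encode(), dtype=np.uint8)
    s_rev = np.frombuffer(srna[::-1].encode(), dtype=np.uint8)
    match = windows == rc
    g, t = ord("G"), ord("T")
    wobble = ((s_rev == g) & (windows == t)) | ((s_rev == t) & (windows == g))
    penalty = np.where(match, 0.0, np.where(wobble, 0.5, 1.0))
    weights = np.array([_position_weight(n - j) for j in range(n)])
    return penalty @ weights


def predict_targets(srna_seq: str, transcriptome: Mapping[str, str],
                    cutoff: float = 5.0,
                    max_reported_per_transcript: int = 1) -> list:
    """Exhaustive scan of an sRNA against every transcript window.

    Returns qualifying DuplexScores (expectation <= cutoff), at most
    ``max_reported_per_transcript`` sites per transcript (best first, ties by
    smaller start), sorted by (expectation, transcript_id, site_start).
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    s = normalize(srna_seq)
    if not 15 <= len(s) <= 35:
        raise ValueError("sRNA length must lie in [15, 35]")
    results = []
    for tx_id in transcriptome:
        tx = normalize(transcriptome[tx_id])
        if len(tx) < len(s):
            continue
        exps = _expectations_vectorized(s, tx)
        order = np.lexsort((np.arange(len(exps)), exps))
        for j in order[:max_reported_per_transcript]:
            if exps[j] <= cutoff:
                results.append(score_duplex(s, tx[j : j + len(s)], tx_id, int(j)))
    results.sort(key=lambda d: (d.expectation, d.transcript_id, d.site_start))
    return results
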