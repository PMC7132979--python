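"""Majority-vote grade classification from within-sample gene-pair orderings.

Each oriented signature pair casts one vote per sample: if the gene
that is higher in HG1 tumors is indeed the higher of the two, the vote
is HG1; if the ordering is flipped, HG3. A sample is called HG3 when
at least half of its evaluable pairs (``ceil(k/2)`` of k) vote HG3,
otherwise HG1. Because only within-sample orderings are consulted, the
call is invariant to any strictly increasing per-sample transformation
(normalization, log scaling, monotone batch distortions) and needs no
cross-sample normalization: one sample can be classified alone.

``TEN_GENE_PAIR_SIGNATURE`` (the "10-GPS") is the published 10-pair
breast-cancer histological-grade signature, keyed by Entrez gene ID
with the convention that the first gene of each pair is higher in HG1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix
from .signature import Signature

__all__ = [
    "GradeCall",
    "TEN_GENE_PAIR_SIGNATURE",
    "pair_vote",
    "classify_sample",
    "classify_matrix",
    "calls_to_frame",
]

HG1 = "HG1"
HG3 = "HG3"
NOT_EVALUABLE = "not_evaluable"

#: The published 10-gene-pair histological grade signature (Entrez IDs;
#: first gene of each pair is the one higher in HG1 tumors).
TEN_GENE_PAIR_SIGNATURE = Signature.from_pairs(
    [
        ("80127", "9319"),   # BBOF1 > TRIP13
        ("22885", "24137"),  # ABLIM3 > KIF4A
        ("1848", "11065"),   # DUSP6 > UBE2C
        ("9486", "9319"),    # CHST10 > TRIP13
        ("11122", "9833"),   # PTPRT > MELK
        ("6271", "9319"),    # S100A1 > TRIP13
        ("23403", "8140"),   # FBXO46 > SLC7A5
        ("23303", "27346"),  # KIF13B > TMEM97
        ("1101", "11004"),   # CHAD > KIF2C
        ("51310", "9212"),   # SLC22A17 > AURKB
    ],
    symbols={
        "80127": "BBOF1", "9319": "TRIP13", "22885": "ABLIM3", "24137": "KIF4A",
        "1848": "DUSP6", "11065": "UBE2C", "9486": "CHST10", "11122": "PTPRT",
        "9833": "MELK", "6271": "S100A1", "23403": "FBXO46", "8140": "SLC7A5",
        "23303": "KIF13B", "27346": "TMEM97", "1101": "CHAD", "11004": "KIF2C",
        "51310": "SLC22A17", "9212": "AURKB",
    },
)


@dataclass(frozen=True)
class GradeCall:
    """One sample's classification: vote tally and final label."""

    sample_id: str
    hg3_votes: int
    evaluable_pairs: int
    total_pairs: int
    call: str  # HG1 | HG3 | not_evaluable


def pair_vote(sample_values: Mapping[str, float], pair: tuple[str, str]) -> str:
    """Vote of one oriented pair (high-in-HG1 gene first) for one sample.

    HG1 if the ordering matches the HG1 convention, HG3 if flipped;
    a missing gene or an exact tie makes the pair non-evaluable.
    """
    hi, lo = pair
    a = sample_values.get(hi)
    b = sample_values.get(lo)
    if a is None or b is None or not (math.isfinite(a) and math.isfinite(b)):
        return NOT_EVALUABLE
    if a > b:
        return HG1
    if a < b:
        return HG3
    return NOT_EVALUABLE


def classify_sample(
    sample_values: Mapping[str, float],
    signature: Signature,
    min_evaluable_fraction: float = 0.5,
    sample_id: str = "",
) -> GradeCall:
    """Classify one sample by majority vote over the signature pairs.

    HG3 iff at least half of the evaluable pairs vote HG3
    (``hg3_votes >= ceil(evaluable/2)``); ``not_evaluable`` when fewer
    than ``min_evaluable_fraction`` of the pairs can vote.
    """
    votes = [pair_vote(sample_values, pair) for pair in signature.pairs]
    hg3_votes = sum(v == HG3 for v in votes)
    evaluable = sum(v != NOT_EVALUABLE for v in votes)
    total = len(signature)
    if evaluable == 0 or evaluable / total < min_evaluable_fraction:
        call = NOT_EVALUABLE
    elif hg3_votes >= math.ceil(evaluable / 2):
        call = HG3
    else:
        call = HG1
    return GradeCall(sample_id, hg3_votes, evaluable, total, call)


def classify_matrix(
    matrix: ExpressionMatrix,
    signature: Signature,
    min_evaluable_fraction: float = 0.5,
) -> list[GradeCall]:
    """Classify every sample of a matrix; one GradeCall per column, in order."""
    present = signature.genes & set(matrix.gene_ids)
    if not present:
        raise ValueError(
            f"no signature gene present in matrix; missing {sorted(signature.genes)}"
        )
    idx = {g: i for i, g in enumerate(matrix.data.index)}
    X = matrix.data.to_numpy()
    k = len(signature)
    # (pair, sample) vote table: 1 = HG3, 0 = HG1, NaN = non-evaluable
    votes = np.full((k, X.shape[1]), np.nan)
    for p, (hi, lo) in enumerate(signature.pairs):
        if hi not in idx or lo not in idx:
            continue
        a, b = X[idx[hi]], X[idx[lo]]
        votes[p, a < b] = 1.0
        votes[p, a > b] = 0.0
    hg3_votes = np.nansum(votes, axis=0).astype(int)
    evaluable = np.sum(~np.isnan(votes), axis=0)
    calls: list[GradeCall] = []
    for j, sample_id in enumerate(matrix.sample_ids):
        ev = int(evaluable[j])
        if ev == 0 or ev / k < min_evaluable_fraction:
            call = NOT_EVALUABLE
        elif hg3_votes[j] >= math.ceil(ev / 2):
            call = HG3
        else:
            call = HG1
        calls.append(GradeCall(sample_id, int(hg3_votes[j]), ev, k, call))
    return calls


def calls_to_frame(calls: list[GradeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "hg3_votes": c.hg3_votes,
                "evaluable_pairs": c.evaluable_pairs,
                "total_pairs": c.total_pairs,
                "call": c.call,
            }
            for c in calls
        ],
        columns=["sample_id", "hg3_votes", "evaluable_pairs", "total_pairs", "call"],
    )
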