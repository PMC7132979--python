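"""Discovery of stable and reversal relative expression orderings (REOs).

Within one sample, the REO of a gene pair is simply which of the two
genes is expressed higher. A pair is *stable* within a phenotype group
when one ordering recurs in significantly more samples than the chance
expectation under a binomial null (success probability p0 = 0.5),
with Benjamini-Hochberg control of the false discovery rate across all
tested pairs. A *reversal pair* is stably ordered one way in the pHG1
group and the opposite way in the pHG3 group of the same cohort;
consensus reversal pairs recur with identical orientation across
cohorts. The final signature is chosen from the consensus pairs by
forward-stepwise maximization of the F-score (harmonic mean of
sensitivity and specificity) of the majority-vote classifier.

Pairs are stored in canonical order (gene_a < gene_b as strings) with
the direction normalized accordingly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .expr_io import ExpressionMatrix
from .signature import Signature

__all__ = [
    "GenePairREO",
    "ReversalPair",
    "SelectionStep",
    "binomial_reo_pvalue",
    "bh_adjust",
    "find_stable_pairs",
    "find_reversal_pairs",
    "intersect_reversal_pairs",
    "confusion_f_score",
    "forward_stepwise_select",
    "reversal_pairs_to_frame",
    "stable_pairs_to_frame",
]

logger = logging.getLogger(__name__)

A_GT_B = "A_gt_B"
A_LT_B = "A_lt_B"


@dataclass(frozen=True)
class GenePairREO:
    """A gene pair with its within-group ordering stability statistics.

    ``s`` of ``n`` evaluable samples (both genes measured, not tied)
    exhibit ``direction``; ``p_value`` is the one-sided binomial upper
    tail for that direction and ``fdr`` its BH-adjusted value.
    """

    gene_a: str
    gene_b: str
    direction: str  # A_gt_B | A_lt_B
    s: int
    n: int
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("gene_a and gene_b must differ")
        if self.gene_a > self.gene_b:
            raise ValueError("pair not in canonical order (gene_a < gene_b)")
        if not 0 <= self.s <= self.n:
            raise ValueError(f"need 0 <= s <= n, got s={self.s}, n={self.n}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def margin(self) -> int:
        """|2s - n|: how far the ordering count is from a 50/50 split."""
        return abs(2 * self.s - self.n)


@dataclass(frozen=True)
class ReversalPair:
    """A pair stably ordered oppositely in the pHG1 and pHG3 groups."""

    gene_a: str
    gene_b: str
    hg1_direction: str
    hg3_direction: str
    hg1: GenePairREO
    hg3: GenePairREO
    margin: float  # tie-break score: min per-group |2s-n|, summed over datasets

    def __post_init__(self) -> None:
        if self.hg1_direction == self.hg3_direction:
            raise ValueError("a reversal pair must change direction between groups")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def oriented(self) -> tuple[str, str]:
        """(high-in-HG1 gene, low-in-HG1 gene) — the signature orientation."""
        if self.hg1_direction == A_GT_B:
            return (self.gene_a, self.gene_b)
        return (self.gene_b, self.gene_a)


@dataclass(frozen=True)
class SelectionStep:
    step: int
    gene_a: str  # oriented: higher in HG1
    gene_b: str
    sensitivity: float
    specificity: float
    f_score: float


def binomial_reo_pvalue(s: int, n: int, p0: float = 0.5) -> float:
    """Upper-tail binomial probability P(X >= s) for X ~ Binomial(n, p0).

    The significance of observing one ordering of a gene pair in ``s``
    of ``n`` samples when each sample shows it with chance probability
    ``p0``. ``s = 0`` returns 1 (the full mass).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= s <= n:
        raise ValueError(f"need 0 <= s <= n, got s={s}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(binom.sf(s - 1, n, p0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"degenerate pair ({a}, {b})")
    return (a, b) if a < b else (b, a)


def _pair_counts(
    matrix: ExpressionMatrix,
    samples: Sequence[str] | None,
    candidate_pairs: Sequence[tuple[str, str]] | None,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Count, per candidate pair, samples with gene_a > gene_b and <."""
    data = matrix.data if samples is None else matrix.data[list(samples)]
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples for REO stability testing")
    if candidate_pairs is None:
        genes = sorted(matrix.gene_ids)
        X = data.loc[genes].to_numpy()
        g = len(genes)
        gt = np.zeros((g, g), dtype=np.int64)
        for col in X.T:  # NaN compares False on both sides -> non-evaluable
            gt += col[:, None] > col[None, :]
        iu, ju = np.triu_indices(g, k=1)
        pairs = [(genes[i], genes[j]) for i, j in zip(iu, ju)]
        return pairs, gt[iu, ju], gt[ju, iu]
    pairs = [_canonical_pair(str(a), str(b)) for a, b in candidate_pairs]
    idx = {g: i for i, g in enumerate(data.index)}
    missing = sorted({g for p in pairs for g in p if g not in idx})
    if missing:
        raise KeyError(f"candidate-pair genes absent from matrix: {missing[:10]}")
    X = data.to_numpy()
    ia = np.array([idx[a] for a, _ in pairs])
    ib = np.array([idx[b] for _, b in pairs])
    gt_ab = (X[ia] > X[ib]).sum(axis=1)
    gt_ba = (X[ib] > X[ia]).sum(axis=1)
    return pairs, gt_ab, gt_ba


def find_stable_pairs(
    matrix: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
    fdr_threshold: float = 0.1,
    p0: float = 0.5,
) -> list[GenePairREO]:
    """Find gene pairs with a significantly stable ordering in a sample group.

    For each candidate pair (default: all unordered pairs of the
    matrix), the tested direction is the observed majority ordering;
    ties and missing values make a sample non-evaluable for that pair.
    P-values come from the one-sided binomial tail and are BH-adjusted
    across all tested pairs; pairs with ``fdr < fdr_threshold`` are
    returned. Pairs with fewer than 2 evaluable samples are skipped
    (logged, not an error).
    """
    pairs, gt_ab, gt_ba = _pair_counts(matrix, samples, candidate_pairs)
    n = gt_ab + gt_ba
    testable = n >= 2
    n_skipped = int((~testable).sum())
    if n_skipped:
        skipped = [pairs[i] for i in np.flatnonzero(~testable)[:20]]
        logger.info(
            "skipping %d pair(s) with < 2 evaluable samples (first few: %s)",
            n_skipped,
            skipped,
        )
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        return []
    s = np.maximum(gt_ab[idx], gt_ba[idx])  # majority direction; tie -> A_gt_B
    direction_a_gt_b = gt_ab[idx] >= gt_ba[idx]
    nn = n[idx]
    p = binom.sf(s - 1, nn, p0)
    fdr = bh_adjust(p)
    out: list[GenePairREO] = []
    for k in np.flatnonzero(fdr < fdr_threshold):
        a, b = pairs[idx[k]]
        out.append(
            GenePairREO(
                gene_a=a,
                gene_b=b,
                direction=A_GT_B if direction_a_gt_b[k] else A_LT_B,
                s=int(s[k]),
                n=int(nn[k]),
                p_value=float(p[k]),
                fdr=float(fdr[k]),
            )
        )
    return out


def find_reversal_pairs(
    stable_hg1: Iterable[GenePairREO], stable_hg3: Iterable[GenePairREO]
) -> list[ReversalPair]:
    """Pairs stable in both groups with opposite directions."""
    by_key_hg1 = {r.key: r for r in stable_hg1}
    out: list[ReversalPair] = []
    for r3 in stable_hg3:
        r1 = by_key_hg1.get(r3.key)
        if r1 is None or r1.direction == r3.direction:
            continue
        out.append(
            ReversalPair(
                gene_a=r1.gene_a,
                gene_b=r1.gene_b,
                hg1_direction=r1.direction,
                hg3_direction=r3.direction,
                hg1=r1,
                hg3=r3,
                margin=float(min(r1.margin, r3.margin)),
            )
        )
    out.sort(key=lambda r: r.key)
    return out


def intersect_reversal_pairs(
    per_dataset_sets: Sequence[Iterable[ReversalPair]],
) -> list[ReversalPair]:
    """Consensus reversal pairs: present in every dataset with the same
    orientation. Tie-break margins are summed across datasets."""
    if len(per_dataset_sets) == 0:
        raise ValueError("need at least one dataset's reversal pairs")
    sets = [list(s) for s in per_dataset_sets]
    consensus = {r.key: r for r in sets[0]}
    margins = {r.key: r.margin for r in sets[0]}
    for dataset in sets[1:]:
        by_key = {r.key: r for r in dataset}
        for key in list(consensus):
            other = by_key.get(key)
            if other is None or other.hg1_direction != consensus[key].hg1_direction:
                del consensus[key]
                del margins[key]
            else:
                margins[key] += other.margin
    out = [replace(consensus[k], margin=margins[k]) for k in sorted(consensus)]
    return out


def confusion_f_score(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0).

    Note this is not the precision/recall F1: specificity, not
    precision, enters the harmonic mean.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if sensitivity + specificity == 0:
        return 0.0
    return 2 * sensitivity * specificity / (sensitivity + specificity)


def _vote_table(
    matrix: ExpressionMatrix, oriented_pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Per (pair, sample) HG3 vote: 1 hg3, 0 hg1, NaN non-evaluable."""
    idx = {g: i for i, g in enumerate(matrix.data.index)}
    X = matrix.data.to_numpy()
    votes = np.full((len(oriented_pairs), X.shape[1]), np.nan)
    for k, (hi, lo) in enumerate(oriented_pairs):
        if hi not in idx or lo not in idx:
            continue
        a, b = X[idx[hi]], X[idx[lo]]
        votes[k, a < b] = 1.0  # ordering flipped relative to HG1 -> HG3 vote
        votes[k, a > b] = 0.0
    return votes


def _score_subset(
    votes: np.ndarray, subset: Sequence[int], is_hg3: np.ndarray
) -> tuple[float, float, float]:
    """Sensitivity/specificity/F of the majority vote over a pair subset.

    A sample with no evaluable pair counts as misclassified for its
    class (it cannot be called correctly).
    """
    sub = votes[list(subset)]
    hg3_votes = np.nansum(sub, axis=0)
    evaluable = np.sum(~np.isnan(sub), axis=0)
    threshold = np.ceil(evaluable / 2.0)
    called_hg3 = (evaluable > 0) & (hg3_votes >= threshold)
    called_hg1 = (evaluable > 0) & ~called_hg3
    sens = float(np.mean(called_hg3[is_hg3])) if is_hg3.any() else 0.0
    spec = float(np.mean(called_hg1[~is_hg3])) if (~is_hg3).any() else 0.0
    return sens, spec, confusion_f_score(sens, spec)


def forward_stepwise_select(
    candidates: Sequence[ReversalPair],
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
) -> tuple[Signature, list[SelectionStep]]:
    """Greedy forward selection of the pair subset maximizing the F-score.

    Starting from the empty set, each step tentatively adds every
    remaining candidate, classifies all pooled training samples with
    the majority-vote rule, and accepts the pair giving the largest
    strict F-score improvement; selection stops when no addition
    improves. Ties are broken by larger consensus margin, then by
    lexicographic pair order, so the procedure is fully deterministic.

    ``labels`` maps each sample of ``matrix`` to ``pHG1`` or ``pHG3``.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate pairs to select from")
    labels = pd.Series(labels)
    sample_ids = matrix.sample_ids
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise KeyError(f"samples without grade labels: {missing[:10]}")
    lab = labels.loc[sample_ids]
    bad = sorted(set(lab) - {"pHG1", "pHG3"})
    if bad:
        raise ValueError(f"stepwise selection needs pHG1/pHG3 labels only; got {bad}")
    is_hg3 = (lab == "pHG3").to_numpy()
    if not is_hg3.any() or is_hg3.all():
        raise ValueError("both pHG1 and pHG3 samples are required")

    ordered = sorted(candidates, key=lambda r: r.key)
    oriented = [r.oriented for r in ordered]
    votes = _vote_table(matrix, oriented)

    selected: list[int] = []
    remaining = list(range(len(ordered)))
    best_f = -math.inf
    trace: list[SelectionStep] = []
    while remaining:
        best = None  # (j, sens, spec, f)
        for j in remaining:
            sens, spec, f = _score_subset(votes, selected + [j], is_hg3)
            if best is None:
                best = (j, sens, spec, f)
                continue
            jb, _, _, fb = best
            # larger F wins; ties: larger margin, then earlier lexicographic key
            if f > fb or (
                f == fb
                and (
                    ordered[j].margin > ordered[jb].margin
                    or (ordered[j].margin == ordered[jb].margin and ordered[j].key < ordered[jb].key)
                )
            ):
                best = (j, sens, spec, f)
        j, sens, spec, f = best
        if f <= best_f:
            break
        selected.append(j)
        remaining.remove(j)
        best_f = f
        trace.append(
            SelectionStep(
                step=len(selected),
                gene_a=ordered[j].oriented[0],
                gene_b=ordered[j].oriented[1],
                sensitivity=sens,
                specificity=spec,
                f_score=f,
            )
        )
    signature = Signature.from_pairs([ordered[j].oriented for j in selected])
    return signature, trace


def stable_pairs_to_frame(
    pairs: Iterable[GenePairREO], group: str = "", dataset: str = ""
) -> pd.DataFrame:
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "direction": r.direction,
            "s": r.s,
            "n": r.n,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "group": group,
            "dataset": dataset,
        }
        for r in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "direction", "s", "n", "p_value", "fdr", "group", "dataset"],
    )


def reversal_pairs_to_frame(pairs: Iterable[ReversalPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "hg1_direction": r.hg1_direction,
            "hg3_direction": r.hg3_direction,
            "margin": r.margin,
        }
        for r in pairs
    ]
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "hg1_direction", "hg3_direction", "margin"]
    )


def selection_trace_to_frame(trace: Iterable[SelectionStep]) -> pd.DataFrame:
    rows = [
        {
            "step": t.step,
            "gene_a": t.gene_a,
            "gene_b": t.gene_b,
            "sensitivity": t.sensitivity,
            "specificity": t.specificity,
            "f_score": t.f_score,
        }
        for t in trace
    ]
    return pd.DataFrame(
        rows, columns=["step", "gene_a", "gene_b", "sensitivity", "specificity", "f_score"]
    )
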