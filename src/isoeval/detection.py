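"""Detection scoring against ground-truth transcript sets and cross-submission
agreement statistics.

Ground truth here is a set of transcripts whose structures are known exactly —
spike-in annotations (SIRV-style), simulated transcripts, or manually curated
models. Matching is at the junction-chain level: a prediction detects a truth
transcript when their chains are identical (mono-exon truths, which have no
chain, are matched by same-strand overlap instead). End accuracy upgrades a
chain match to a full true positive when both the 5' and 3' ends fall within
the window (default 50 nt) of the truth ends.

Truth-side counts: TP (chain + ends), PTP (chain only), FN (no chain match).
Prediction-side: precision (chain-and-end-matching predictions over all
predictions), FP (predictions matching no truth chain), redundancy (chain-
matching predictions per distinct truth matched).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    JunctionChain,
    ReferenceCatalog,
    TranscriptModel,
    build_catalog,
    group_loci,
    junction_chain,
)
from .classify import DEFAULT_WINDOW, classify


@dataclass
class DetectionResult:
    tp: int
    ptp: int
    fn: int
    fp: int
    sensitivity: float
    precision: float
    f1: float
    pdr: float
    redundancy: Optional[float]  # None when no prediction matches any truth
    non_redundant_precision: float
    n_truth: int
    n_predictions: int

    @property
    def inv_redundancy(self) -> Optional[float]:
        return None if self.redundancy is None else 1.0 / self.redundancy

    def to_dict(self) -> Dict[str, Optional[float]]:
        return {
            "TP": self.tp,
            "PTP": self.ptp,
            "FN": self.fn,
            "FP": self.fp,
            "Sen": self.sensitivity,
            "Pre": self.precision,
            "F1": self.f1,
            "PDR": self.pdr,
            "redundancy": self.redundancy,
            "1/redundancy": self.inv_redundancy,
            "nrPred": self.non_redundant_precision,
            "n_truth": self.n_truth,
            "n_predictions": self.n_predictions,
        }


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def _matches_truth(
    pred: TranscriptModel, truth: TranscriptModel, window: int
) -> Tuple[bool, bool]:
    """(chain match, chain + both ends within window)."""
    if pred.chrom != truth.chrom or pred.strand != truth.strand:
        return False, False
    if truth.n_exons == 1:
        # unspliced truth (long spike-in analog): same-strand overlap
        chain_ok = pred.n_exons == 1 and pred.start < truth.end and truth.start < pred.end
    else:
        chain_ok = junction_chain(pred).introns == junction_chain(truth).introns
    if not chain_ok:
        return False, False
    ends_ok = (
        abs(pred.tss - truth.tss) <= window and abs(pred.tts - truth.tts) <= window
    )
    return True, ends_ok


def evaluate_detection(
    predictions: Sequence[TranscriptModel],
    truth: Sequence[TranscriptModel],
    window: int = DEFAULT_WINDOW,
) -> DetectionResult:
    """Score a prediction set against ground-truth transcripts.

    Raises ``ValueError`` on empty truth. Empty predictions give an all-zero
    result with redundancy undefined (``None``).
    """
    truth = list(truth)
    if not truth:
        raise ValueError("ground-truth transcript set is empty")
    predictions = list(predictions)

    # index truth by (chrom, strand, chain) for multi-exon, scan mono-exon
    chain_to_truth: Dict[Tuple, List[int]] = defaultdict(list)
    mono_truth = []
    for ti, t in enumerate(truth):
        if t.n_exons == 1:
            mono_truth.append(ti)
        else:
            chain_to_truth[(t.chrom, t.strand, junction_chain(t).introns)].append(ti)

    truth_chain_hit: Set[int] = set()
    truth_full_hit: Set[int] = set()
    n_pred_chain = 0
    n_pred_full = 0
    full_hit_truths_per_pred: List[Set[int]] = []

    for p in predictions:
        hit_chain = False
        hit_full: Set[int] = set()
        if p.n_exons > 1:
            cands = chain_to_truth.get((p.chrom, p.strand, junction_chain(p).introns), [])
        else:
            cands = mono_truth
        for ti in cands:
            chain_ok, ends_ok = _matches_truth(p, truth[ti], window)
            if chain_ok:
                hit_chain = True
                truth_chain_hit.add(ti)
                if ends_ok:
                    hit_full.add(ti)
                    truth_full_hit.add(ti)
        if hit_chain:
            n_pred_chain += 1
        if hit_full:
            n_pred_full += 1
            full_hit_truths_per_pred.append(hit_full)

    tp = len(truth_full_hit)
    ptp = len(truth_chain_hit - truth_full_hit)
    fn = len(truth) - len(truth_chain_hit)
    fp = len(predictions) - n_pred_chain

    n_truth = len(truth)
    sensitivity = tp / n_truth
    pdr = len(truth_chain_hit) / n_truth
    precision = n_pred_full / len(predictions) if predictions else 0.0
    redundancy = (
        n_pred_chain / len(truth_chain_hit) if truth_chain_hit else None
    )
    nr_precision = len(truth_full_hit) / len(predictions) if predictions else 0.0

    return DetectionResult(
        tp=tp,
        ptp=ptp,
        fn=fn,
        fp=fp,
        sensitivity=sensitivity,
        precision=precision,
        f1=_f1(precision, sensitivity),
        pdr=pdr,
        redundancy=redundancy,
        non_redundant_precision=nr_precision,
        n_truth=n_truth,
        n_predictions=len(predictions),
    )


def lrc(model_length: int, covered: Iterable[Tuple[int, int]]) -> float:
    """Long-read coverage: merged covered length over the model length.

    ``covered`` are intervals on the transcript model, 0-based half-open,
    within ``[0, model_length]``.
    """
    if model_length <= 0:
        raise ValueError("model_length must be positive")
    ivs = sorted(covered)
    total = 0
    cur_start = cur_end = None
    for s, e in ivs:
        if s < 0 or e > model_length or s >= e:
            raise ValueError(f"invalid coverage interval ({s},{e})")
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total / model_length


def ujc_set(models: Sequence[TranscriptModel]) -> Set[JunctionChain]:
    """Distinct junction chains of the spliced models in a submission."""
    return {junction_chain(m) for m in models if m.n_exons > 1}


def pairwise_ujc_overlap(
    submissions: Mapping[str, Set[JunctionChain]]
) -> pd.DataFrame:
    """Row-normalized asymmetric agreement matrix of unique junction chains.

    Entry (r, c) is |UJC(r) ∩ UJC(c)| / |UJC(r)|: the row submission's chains
    act as the reference set; the fraction recovered by the column submission
    is reported. Empty-row submissions yield NaN rows.
    """
    labels = list(submissions)
    if len(labels) < 2:
        raise ValueError("need at least two submissions")
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, r in enumerate(labels):
        if not submissions[r]:
            continue
        for j, c in enumerate(labels):
            mat[i, j] = len(submissions[r] & submissions[c]) / len(submissions[r])
    return pd.DataFrame(mat, index=labels, columns=labels)


def detection_agreement(
    submissions: Mapping[str, Sequence[TranscriptModel]],
    catalog: ReferenceCatalog,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Agreement in UJC detection across pipelines, stratified by category.

    For each chain in the union of all submissions, counts the number of
    submissions containing it, and classifies a representative model against
    the catalog. Returns counts indexed by (category, n_detecting).
    """
    if len(submissions) < 2:
        raise ValueError("need at least two submissions")
    chain_count: Counter = Counter()
    representative: Dict[JunctionChain, TranscriptModel] = {}
    for models in submissions.values():
        seen = set()
        for m in models:
            if m.n_exons == 1:
                continue
            c = junction_chain(m)
            representative.setdefault(c, m)
            if c not in seen:
                chain_count[c] += 1
                seen.add(c)

    rows: Counter = Counter()
    for c, n in chain_count.items():
        category = classify(representative[c], catalog, window=window).category
        rows[(category, n)] += 1
    df = pd.DataFrame(
        [
            {"category": cat, "n_detecting": n, "n_ujc": count}
            for (cat, n), count in sorted(rows.items())
        ]
    )
    return df


def transcripts_per_locus(
    models: Sequence[TranscriptModel], pool_strands: bool = False
) -> Dict[int, int]:
    """Distribution of locus sizes: {members per locus: number of loci}."""
    sizes = Counter(l.n_transcripts for l in group_loci(models, pool_strands))
    return dict(sorted(sizes.items()))
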