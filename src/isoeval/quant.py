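"""Transcript quantification evaluation statistics.

With a ground truth Θ and an estimate Θ̂ (both in TPM):

* **SCC** — Spearman rank correlation of Θ̂ against Θ (average ranks on ties).
* **MRD** — median over i of |θ_i − θ̂_i| / θ_i, restricted to θ_i > 0.
* **NRMSE** — RMSE(Θ, Θ̂) / s_Θ, where s_Θ is the sample (n−1) s.d. of Θ;
  invariant under joint positive scaling of both vectors.
* **PET** — percentage of truly expressed transcripts recovered with TPM > 0.

Without ground truth, over a transcripts × (group, replicate) matrix θ̂_igr,
all on the log(TPM + 1) scale:

* **IM** — sqrt of the mean squared per-(transcript, group) coefficient of
  variation CV_ig = s_ig / u_ig (the irreproducibility measure). The s.d.
  s_ig uses a 1/R denominator; transcripts with u_ig = 0 are excluded (the
  exclusion count is reported).
* **ACVC** — area under the curve of bin-averaged CV versus mean abundance
  u_ig (equal-frequency bins, trapezoidal rule).
* **C(α) / CM / ACC** — the consistency measure: the fraction of replicate
  pairs agreeing on expressed-or-not at threshold α (both < α or both ≥ α);
  CM is C(α) at α = 1, ACC the trapezoidal area of the curve over the α grid
  (default 0..10, step 0.1).
* **RE** — resolution entropy: abundances binned into M groups of width
  max(Θ̂)/M; RE = −Σ P_m ln P_m over non-empty bins. 0 when every transcript
  has the same estimate; ln(M) when estimates fill all bins uniformly.

Per-gene structure complexity:

* **K-value** — condition number σ_max/σ_min of the gene's binary
  exon-isoform matrix A (rows isoforms, columns distinct exon intervals);
  +inf for rank-deficient structures such as duplicated isoform rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel

TPM_TOTAL = 1_000_000.0
DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


# ---------------------------------------------------------------------------
# containers


class QuantMatrix:
    """Transcripts × (group, replicate) TPM estimates θ̂_igr.

    Wraps a DataFrame whose index is transcript ids and whose columns are a
    (group, replicate) MultiIndex. Values must be non-negative and the grid
    complete (every group has the same replicate labels is *not* required,
    but every (group, replicate) column is dense; missing estimates are 0).
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("columns must be a (group, replicate) MultiIndex")
        if values.shape[0] < 1:
            raise ValueError("need at least one transcript")
        if (values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.values = values.astype(float)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def groups(self) -> List[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def replicates(self, group: str) -> List[str]:
        return list(self.values[group].columns)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_arrays(
        cls,
        transcript_ids: Sequence[str],
        groups: Sequence[str],
        replicates: Sequence[str],
        data: np.ndarray,
    ) -> "QuantMatrix":
        """Build from a dense I × G × R array."""
        data = np.asarray(data, dtype=float)
        cols = pd.MultiIndex.from_product([groups, replicates], names=["group", "replicate"])
        flat = data.reshape(len(transcript_ids), len(groups) * len(replicates))
        return cls(pd.DataFrame(flat, index=list(transcript_ids), columns=cols))

    @classmethod
    def from_long_tsv(cls, path) -> "QuantMatrix":
        """Read long format: columns ``transcript_id  group  replicate  TPM``."""
        df = pd.read_csv(path, sep="\t")
        required = {"transcript_id", "group", "replicate", "TPM"}
        if not required.issubset(df.columns):
            raise ValueError(f"long-format TSV needs columns {sorted(required)}")
        wide = df.pivot_table(
            index="transcript_id",
            columns=["group", "replicate"],
            values="TPM",
            fill_value=0.0,
            aggfunc="sum",
        )
        wide.columns.names = ["group", "replicate"]
        return cls(wide)

    @classmethod
    def from_wide_tsv(cls, path) -> "QuantMatrix":
        """Read wide format: ``transcript_id`` then ``<group>_<rep>`` columns."""
        df = pd.read_csv(path, sep="\t").set_index("transcript_id")
        cols = []
        for c in df.columns:
            if "_" not in c:
                raise ValueError(f"wide-format column {c!r} is not '<group>_<replicate>'")
            g, r = c.rsplit("_", 1)
            cols.append((g, r))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["group", "replicate"])
        return cls(df)

    def to_long_tsv(self, path) -> None:
        long = (
            self.values.stack(["group", "replicate"], future_stack=True)
            .rename("TPM")
            .reset_index()
            .rename(columns={"level_0": "transcript_id"})
        )
        long.columns = ["transcript_id", "group", "replicate", "TPM"]
        long.to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path) -> pd.Series:
    """Read a ``transcript_id  TPM`` table into an abundance vector."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["TPM"].values, index=df["transcript_id"].values, dtype=float)


def align_to_truth(est: pd.Series, truth: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluation id set: all ground-truth ids; unreported estimates are 0."""
    e = est.reindex(truth.index).fillna(0.0)
    return e.to_numpy(dtype=float), truth.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# ground-truth metrics


def scc(est: pd.Series, truth: pd.Series) -> float:
    """Spearman rank correlation between estimate and truth.

    NaN when either vector is constant (rank correlation undefined).
    """
    e, t = align_to_truth(est, truth)
    if len(t) < 2 or np.all(e == e[0]) or np.all(t == t[0]):
        return float("nan")
    return float(stats.spearmanr(t, e).statistic)


def mrd(est: pd.Series, truth: pd.Series) -> float:
    """Median relative difference over transcripts with positive truth."""
    e, t = align_to_truth(est, truth)
    mask = t > 0
    if not mask.any():
        raise ValueError("no transcripts with positive ground-truth abundance")
    return float(np.median(np.abs(t[mask] - e[mask]) / t[mask]))


def nrmse(est: pd.Series, truth: pd.Series, ddof: int = 1) -> float:
    """Root mean square error normalized by the sample s.d. of the truth."""
    e, t = align_to_truth(est, truth)
    if len(t) < 2:
        raise ValueError("need at least two transcripts")
    s = float(np.std(t, ddof=ddof))
    if s == 0:
        raise ValueError("constant ground truth: NRMSE undefined")
    return float(np.sqrt(np.mean((t - e) ** 2)) / s)


def pet(est: pd.Series, truly_expressed_ids: Iterable[str]) -> float:
    """Percentage of truly expressed transcripts estimated with TPM > 0."""
    ids = list(truly_expressed_ids)
    if not ids:
        raise ValueError("empty set of truly expressed transcripts")
    vals = est.reindex(ids).fillna(0.0)
    return 100.0 * float((vals > 0).sum()) / len(ids)


# ---------------------------------------------------------------------------
# replicate reproducibility / consistency


@dataclass
class IrreproducibilityResult:
    im: float
    acvc: float
    curve: pd.DataFrame  # columns: u (bin mean abundance), cv (bin mean CV)
    n_excluded: int  # (i, g) cells with u_ig = 0, excluded from CV


def replicate_stats(q: QuantMatrix, ddof: int = 0) -> pd.DataFrame:
    """Per (transcript, group) mean, s.d. and CV of log(TPM + 1).

    CV is NaN where the mean is 0 (all-zero transcript in that group).
    """
    rows = []
    for g in q.groups:
        block = np.log(q.values[g].to_numpy(dtype=float) + 1.0)
        u = block.mean(axis=1)
        s = block.std(axis=1, ddof=ddof)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(u > 0, s / u, np.nan)
        rows.append(
            pd.DataFrame(
                {"transcript_id": q.transcript_ids, "group": g, "u": u, "s": s, "cv": cv}
            )
        )
    return pd.concat(rows, ignore_index=True)


def irreproducibility(
    q: QuantMatrix, acvc_bins: int = 50, ddof: int = 0
) -> IrreproducibilityResult:
    """Irreproducibility measure and area under the CV curve.

    IM = sqrt( mean of CV_ig^2 ) over the defined CVs. The CV curve plots
    bin-averaged CV against bin-averaged mean abundance u over
    ``acvc_bins`` equal-frequency bins; ACVC is its trapezoidal area.
    """
    if any(len(q.replicates(g)) < 2 for g in q.groups):
        raise ValueError("every group needs at least two replicates")
    st = replicate_stats(q, ddof=ddof)
    defined = st.dropna(subset=["cv"])
    n_excluded = len(st) - len(defined)
    if defined.empty:
        return IrreproducibilityResult(0.0, 0.0, pd.DataFrame(columns=["u", "cv"]), n_excluded)

    im = float(np.sqrt(np.mean(defined["cv"].to_numpy() ** 2)))

    srt = defined.sort_values(["u", "transcript_id"], kind="mergesort")
    n_bins = min(acvc_bins, len(srt))
    edges = np.array_split(np.arange(len(srt)), n_bins)
    us = np.array([srt["u"].to_numpy()[idx].mean() for idx in edges])
    cvs = np.array([srt["cv"].to_numpy()[idx].mean() for idx in edges])
    acvc = float(np.trapezoid(cvs, us)) if len(us) > 1 else 0.0
    curve = pd.DataFrame({"u": us, "cv": cvs})
    return IrreproducibilityResult(im, acvc, curve, n_excluded)


@dataclass
class ConsistencyCurve:
    alphas: np.ndarray
    values: np.ndarray
    cm: float  # C(α) at α = 1
    acc: float  # trapezoidal area over the α grid

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alphas, "C": self.values})


def consistency(
    q: QuantMatrix, alphas: Optional[Sequence[float]] = None
) -> ConsistencyCurve:
    """Consistency measure C(α) over an α grid.

    For each transcript, group, and unordered replicate pair, the pair agrees
    at threshold α when both log(TPM+1) values are below α or both are at or
    above α; C(α) is the fraction of agreeing (i, g, pair) events. C(0) = 1
    since log values are non-negative.
    """
    if alphas is None:
        alphas = DEFAULT_ALPHA_GRID
    alphas = np.asarray(alphas, dtype=float)
    if any(len(q.replicates(g)) < 2 for g in q.groups):
        raise ValueError("every group needs at least two replicates")

    values = np.zeros_like(alphas)
    n_events = 0
    # accumulate agreement counts per alpha across all replicate pairs
    agree = np.zeros_like(alphas)
    for g in q.groups:
        block = np.log(q.values[g].to_numpy(dtype=float) + 1.0)
        reps = block.shape[1]
        for r1, r2 in combinations(range(reps), 2):
            a = block[:, r1][:, None] < alphas[None, :]
            b = block[:, r2][:, None] < alphas[None, :]
            agree += (a == b).sum(axis=0)
            n_events += block.shape[0]
    values = agree / n_events
    cm = float(_c_at(q, 1.0))
    acc = float(np.trapezoid(values, alphas))
    return ConsistencyCurve(alphas, values, cm, acc)


def _c_at(q: QuantMatrix, alpha: float) -> float:
    agree = 0
    total = 0
    for g in q.groups:
        block = np.log(q.values[g].to_numpy(dtype=float) + 1.0)
        for r1, r2 in combinations(range(block.shape[1]), 2):
            agree += int(((block[:, r1] < alpha) == (block[:, r2] < alpha)).sum())
            total += block.shape[0]
    return agree / total


def resolution_entropy(est: pd.Series, M: int = 100) -> float:
    """Resolution entropy of an abundance profile.

    Estimates are binned into M groups of width max(Θ̂)/M (top edge
    inclusive, so the maximum is always counted); RE = −Σ P_m ln P_m over
    non-empty bins. 0 for a constant profile (including all-zero, by
    convention), up to ln(M) for a uniform spread.
    """
    vals = np.asarray(est, dtype=float)
    if len(vals) == 0:
        raise ValueError("empty abundance vector")
    top = vals.max()
    if top <= 0:
        return 0.0
    alpha = top / M
    bins = np.minimum((vals / alpha).astype(int), M - 1)
    counts = np.bincount(bins, minlength=M)
    p = counts[counts > 0] / counts.sum()
    val = float(-(p * np.log(p)).sum())
    return 0.0 if val == 0 else val


# ---------------------------------------------------------------------------
# exon-isoform structure complexity


def exon_isoform_matrix(
    gene_isoforms: Sequence[TranscriptModel], mode: str = "exact"
) -> np.ndarray:
    """Binary isoform × exon matrix A for one gene.

    ``mode='exact'``: columns are the distinct exact (start, end) exon
    intervals across the gene's isoforms. ``mode='segments'``: columns are
    the disjoint genomic segments induced by all exon boundaries; a_ie = 1
    when the isoform covers the segment.
    """
    if not gene_isoforms:
        raise ValueError("need at least one isoform")
    if mode == "exact":
        exon_ids = sorted({e for t in gene_isoforms for e in t.exons})
        col = {e: j for j, e in enumerate(exon_ids)}
        A = np.zeros((len(gene_isoforms), len(exon_ids)))
        for i, t in enumerate(gene_isoforms):
            for e in t.exons:
                A[i, col[e]] = 1.0
        return A
    if mode == "segments":
        bounds = sorted({x for t in gene_isoforms for e in t.exons for x in e})
        segments = [
            (bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)
        ]
        keep = []
        for s, e in segments:
            if any(es <= s and e <= ee for t in gene_isoforms for es, ee in t.exons):
                keep.append((s, e))
        A = np.zeros((len(gene_isoforms), len(keep)))
        for i, t in enumerate(gene_isoforms):
            for j, (s, e) in enumerate(keep):
                if any(es <= s and e <= ee for es, ee in t.exons):
                    A[i, j] = 1.0
        return A
    raise ValueError(f"unknown mode {mode!r}")


def k_value(
    gene_isoforms: Sequence[TranscriptModel],
    mode: str = "exact",
    rank_tol: float = 1e-12,
) -> float:
    """Condition number of the gene's exon-isoform binary matrix.

    K = σ_max / σ_min over the min(I, E) singular values; structures whose
    smallest singular value vanishes (e.g. two isoforms with identical exon
    sets) report +inf.
    """
    A = exon_isoform_matrix(gene_isoforms, mode=mode)
    sv = np.linalg.svd(A, compute_uv=False)
    smax, smin = float(sv.max()), float(sv.min())
    if smin < rank_tol * smax:
        return float("inf")
    return smax / smin


# ---------------------------------------------------------------------------
# cell-mixing evaluation


def mixing_expected(
    tpm_a: pd.Series, tpm_b: pd.Series, w: float, normalize: bool = True
) -> pd.Series:
    """Expected abundance of a two-sample mixture: w·a + (1−w)·b.

    The union of ids is used (absent ids count as 0); the result is
    re-normalized to sum to 10^6 TPM when ``normalize``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixing ratio w must lie in [0, 1]")
    ids = tpm_a.index.union(tpm_b.index, sort=False)
    a = tpm_a.reindex(ids).fillna(0.0)
    b = tpm_b.reindex(ids).fillna(0.0)
    mixed = w * a + (1.0 - w) * b
    if normalize and mixed.sum() > 0:
        mixed = mixed * (TPM_TOTAL / mixed.sum())
    return mixed


def evaluate_mixing(
    observed_mixed: pd.Series, tpm_a: pd.Series, tpm_b: pd.Series, w: float
) -> Dict[str, float]:
    """SCC, MRD and NRMSE of an observed mixed-sample quantification against
    the expectation from the individually quantified components."""
    expected = mixing_expected(tpm_a, tpm_b, w)
    return {
        "SCC": scc(observed_mixed, expected),
        "MRD": mrd(observed_mixed, expected),
        "NRMSE": nrmse(observed_mixed, expected),
    }


def recover_mixing_ratio(
    observed_mixed: pd.Series,
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Estimate the (undisclosed) mixing ratio by grid search.

    Returns the w on the grid (default 0..1 step 0.01) minimizing NRMSE
    between the observed mixed quantification and the expected mixture.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    best_w, best_err = None, math.inf
    for w in grid:
        err = nrmse(observed_mixed, mixing_expected(tpm_a, tpm_b, float(w)))
        if err < best_err:
            best_w, best_err = float(w), err
    return best_w


# ---------------------------------------------------------------------------
# feature-stratified evaluation


def stratified_report(
    est: pd.Series,
    truth: pd.Series,
    features: pd.DataFrame,
    bin_specs: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Recompute SCC/MRD/NRMSE within bins of per-transcript features.

    ``features`` is indexed by transcript id (e.g. columns truth TPM, number
    of exons, length, isoforms per gene, K of gene); ``bin_specs`` maps a
    feature column to its bin edges (right-open, last bin right-closed).
    Also reports a min–max normalized MRD across the bins of each feature.
    Empty bins yield missing values, not zeros.
    """
    rows = []
    for feature, edges in bin_specs.items():
        if feature not in features.columns:
            raise ValueError(f"unknown feature {feature!r}")
        edges = list(edges)
        fvals = features[feature]
        for lo, hi in zip(edges[:-1], edges[1:]):
            last = hi == edges[-1]
            in_bin = (fvals >= lo) & ((fvals <= hi) if last else (fvals < hi))
            ids = features.index[in_bin]
            ids = ids.intersection(truth.index)
            row = {
                "feature": feature,
                "bin_low": lo,
                "bin_high": hi,
                "n": len(ids),
                "SCC": np.nan,
                "MRD": np.nan,
                "NRMSE": np.nan,
            }
            if len(ids) >= 2:
                t_sub = truth.loc[ids]
                e_sub = est.reindex(ids).fillna(0.0)
                row["SCC"] = scc(e_sub, t_sub)
                if (t_sub > 0).any():
                    row["MRD"] = mrd(e_sub, t_sub)
                if t_sub.std(ddof=1) > 0:
                    row["NRMSE"] = nrmse(e_sub, t_sub)
            rows.append(row)
    df = pd.DataFrame(rows)
    # min-max normalized MRD within each feature's set of bins
    def _norm(group: pd.Series) -> pd.Series:
        lo, hi = group.min(), group.max()
        if not np.isfinite(lo) or hi == lo:
            return pd.Series(np.nan, index=group.index)
        return (group - lo) / (hi - lo)

    df["normalized_MRD"] = df.groupby("feature")["MRD"].transform(_norm)
    return df
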