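"""Synthetic benchmark generator: annotations, submissions, quantifications.

Everything the evaluation modules consume can be generated here from an
explicit seed: a multi-isoform gene annotation with a toy genome (canonical
GT-AG splice motifs stamped in, with a configurable non-canonical fraction),
labeled query submissions mixing the structural categories with bounded end
jitter, replicate TPM matrices with multiplicative log-normal noise and
Bernoulli dropout, and a two-component cell-mixing scenario.

Category constructions follow the category definitions directly: FSM queries
copy a reference chain; ISM queries keep a consecutive run of a reference's
introns (5'/3' truncation); NIC queries either skip an exon (a novel junction
formed from annotated donor/acceptor sites) or retain an intron; NNC queries
shift one annotated splice site by several bases; "other" queries are
antisense copies or intergenic mono-exon models. End jitter perturbs only
terminal exon ends, never junctions, so it changes end-support flags but not
the category.

No biological realism is claimed for the genome sequence beyond splice
motifs; truth abundances are heavy-tailed (log-normal) so that the
quantification metrics are stressed by many low-TPM transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    Interval,
    ReferenceCatalog,
    TranscriptModel,
    build_catalog,
    is_consecutive_subchain,
    junction_chain,
    junction_key,
)
from .quant import TPM_TOTAL, QuantMatrix, mixing_expected

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "other")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic benchmark; the seed is mandatory."""

    seed: int
    n_genes: int = 20
    isoforms_per_gene: Tuple[int, int] = (2, 4)  # inclusive range
    exon_slots_per_gene: Tuple[int, int] = (5, 9)
    exon_length: Tuple[int, int] = (80, 300)
    intron_length: Tuple[int, int] = (200, 1500)
    intergenic_gap: int = 5000
    noncanonical_fraction: float = 0.0
    category_mix: Dict[str, float] = field(
        default_factory=lambda: {"FSM": 0.5, "ISM": 0.15, "NIC": 0.15, "NNC": 0.1, "other": 0.1}
    )
    n_queries: int = 500
    end_jitter_sd: float = 20.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.05
    groups: int = 2
    replicates: int = 3
    mixing_w: float = 0.5
    tpm_meanlog: float = 1.0
    tpm_sdlog: float = 1.5
    submission_label: str = "sim"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix proportions must sum to 1, got {total}")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        for name in ("n_genes", "n_queries", "groups", "replicates", "intergenic_gap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.mixing_w <= 1.0:
            raise ValueError("mixing_w must lie in [0, 1]")


@dataclass
class GeneLayout:
    gene_id: str
    chrom: str
    strand: str
    slots: Tuple[Interval, ...]  # all exon slots of the full isoform
    isoform_ids: Tuple[str, ...]
    single_skips: frozenset  # slot indices skipped alone by some reference isoform


@dataclass
class SyntheticAnnotation:
    models: List[TranscriptModel]
    genome: Dict[str, str]
    genes: List[GeneLayout]


@dataclass
class QueryLabel:
    category: str
    source_reference_id: Optional[str]
    detail: str = ""


@dataclass
class LabeledSubmission:
    models: List[TranscriptModel]
    labels: Dict[str, QueryLabel]


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# annotation + genome


def gen_annotation(cfg: SimulationConfig) -> SyntheticAnnotation:
    """Generate a non-overlapping multi-isoform gene annotation and genome.

    Each gene is built from a ladder of exon "slots"; the first isoform uses
    every slot and the others skip small subsets of internal slots, so every
    gene offers the >= 2 isoforms and >= 3 introns the submission generator
    needs. Splice motifs are stamped canonically (GT..AG in transcription
    direction) except for a configurable fraction of introns.
    """
    rng = _rng(cfg, 0xA)
    lo_s, hi_s = cfg.exon_slots_per_gene
    if lo_s < 4:
        raise ValueError("exon_slots_per_gene minimum must be >= 4")
    chrom = "chr1"
    cursor = cfg.intergenic_gap
    models: List[TranscriptModel] = []
    genes: List[GeneLayout] = []
    noncanonical_introns: List[Tuple[Interval, str]] = []

    for g in range(cfg.n_genes):
        n_slots = int(rng.integers(lo_s, hi_s + 1))
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_slots)
        intron_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, n_slots - 1
        )
        slots: List[Interval] = []
        pos = cursor
        for k in range(n_slots):
            slots.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_slots - 1:
                pos += int(intron_lens[k])
        strand = str(rng.choice(["+", "-"]))
        gene_id = f"G{g:04d}"

        iso_exons: List[Tuple[Interval, ...]] = [tuple(slots)]
        skip_patterns: List[frozenset] = [frozenset()]
        n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
        internal = list(range(1, n_slots - 1))
        attempts = 0
        while len(iso_exons) < n_iso and attempts < 50:
            attempts += 1
            size = int(rng.integers(1, min(2, len(internal)) + 1))
            skip = frozenset(rng.choice(internal, size=size, replace=False).tolist())
            if skip in skip_patterns:
                continue
            skip_patterns.append(skip)
            iso_exons.append(tuple(s for k, s in enumerate(slots) if k not in skip))

        iso_ids = tuple(f"{gene_id}.{j + 1}" for j in range(len(iso_exons)))
        for tid, exons in zip(iso_ids, iso_exons):
            models.append(
                TranscriptModel(tid, gene_id, chrom, strand, exons, source_label="reference")
            )
        genes.append(
            GeneLayout(
                gene_id,
                chrom,
                strand,
                tuple(slots),
                iso_ids,
                frozenset(k for p in skip_patterns for k in p if len(p) == 1),
            )
        )
        cursor = slots[-1][1] + cfg.intergenic_gap

    genome_len = cursor + cfg.intergenic_gap
    seq = rng.integers(0, 4, genome_len)
    genome = np.array(list("ACGT"))[seq]

    # stamp splice motifs at every annotated intron (union over isoforms)
    introns = sorted(
        {
            (intron, m.strand)
            for m in models
            for intron in junction_chain(m).introns
        }
    )
    for (a, b), strand in introns:
        noncanon = rng.random() < cfg.noncanonical_fraction
        if strand == "+":
            five, three = ("CT", "AC") if noncanon else ("GT", "AG")
            genome[a], genome[a + 1] = five[0], five[1]
            genome[b - 2], genome[b - 1] = three[0], three[1]
        else:
            # transcription right-to-left: donor motif at the intron's right edge
            five, three = ("GT", "AG") if noncanon else ("CT", "AC")
            genome[a], genome[a + 1] = five[0], five[1]
            genome[b - 2], genome[b - 1] = three[0], three[1]

    return SyntheticAnnotation(models, {chrom: "".join(genome)}, genes)


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# submissions


def _jitter_ends(
    exons: Tuple[Interval, ...],
    rng: np.random.Generator,
    sd: float,
    genome_len: int,
    min_exon: int = 10,
) -> Tuple[Interval, ...]:
    """Perturb the transcript's terminal ends only, never its junctions."""
    if sd <= 0:
        return exons
    exons = list(exons)
    s0, e0 = exons[0]
    d5 = int(round(rng.normal(0.0, sd)))
    s0 = min(max(s0 + d5, 0), e0 - min_exon)
    exons[0] = (s0, e0)
    s1, e1 = exons[-1]
    d3 = int(round(rng.normal(0.0, sd)))
    e1 = max(min(e1 + d3, genome_len), s1 + min_exon)
    exons[-1] = (s1, e1)
    return tuple(exons)


class ConstructionError(RuntimeError):
    """A requested category cannot be built from the reference topology."""


def gen_submission(
    annotation: SyntheticAnnotation, cfg: SimulationConfig
) -> LabeledSubmission:
    """Generate a labeled query submission from the category mix.

    Each query is constructed so that, classified against the reference, it
    receives its intended category: constructions are checked against the
    catalog's chain index and splice-site sets at build time.
    """
    rng = _rng(cfg, 0xB)
    catalog = build_catalog(annotation.models)
    genome_len = len(next(iter(annotation.genome.values())))
    multi = [m for m in annotation.models if m.n_exons > 1]
    by_gene = {g.gene_id: g for g in annotation.genes}
    all_chains = {
        (m.chrom, m.strand, junction_chain(m).introns) for m in annotation.models
    }

    categories = list(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in categories])
    draws = rng.choice(len(categories), size=cfg.n_queries, p=probs)

    models: List[TranscriptModel] = []
    labels: Dict[str, QueryLabel] = {}

    for qi, ci in enumerate(draws):
        category = categories[int(ci)]
        qid = f"Q{qi:05d}"
        builder = {
            "FSM": _build_fsm,
            "ISM": _build_ism,
            "NIC": _build_nic,
            "NNC": _build_nnc,
            "other": _build_other,
        }[category]
        exons, chrom, strand, source_ref, detail = builder(
            annotation, catalog, multi, by_gene, all_chains, rng
        )
        exons = _jitter_ends(exons, rng, cfg.end_jitter_sd, genome_len)
        models.append(
            TranscriptModel(qid, f"gene_{qid}", chrom, strand, exons, cfg.submission_label)
        )
        labels[qid] = QueryLabel(category, source_ref, detail)
    return LabeledSubmission(models, labels)


def _build_fsm(annotation, catalog, multi, by_gene, all_chains, rng):
    ref = multi[int(rng.integers(len(multi)))]
    return ref.exons, ref.chrom, ref.strand, ref.transcript_id, "copy"


def _build_ism(annotation, catalog, multi, by_gene, all_chains, rng):
    for _ in range(100):
        ref = multi[int(rng.integers(len(multi)))]
        n = ref.n_exons - 1
        if n < 2:
            continue
        length = int(rng.integers(1, n))
        start = int(rng.integers(0, n - length + 1))
        exons = ref.exons[start : start + length + 1]
        chain = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        if (ref.chrom, ref.strand, chain) in all_chains:
            continue  # accidental FSM of another isoform
        return exons, ref.chrom, ref.strand, ref.transcript_id, f"truncate[{start}:{start+length}]"
    raise ConstructionError("ISM unconstructible: no reference with >= 2 introns")


def _build_nic(annotation, catalog, multi, by_gene, all_chains, rng):
    modes = ["skip", "retention"]
    order = rng.permutation(2)
    for mode_i in order:
        mode = modes[int(mode_i)]
        for _ in range(100):
            if mode == "skip":
                gene = annotation.genes[int(rng.integers(len(annotation.genes)))]
                internal = [
                    k
                    for k in range(1, len(gene.slots) - 1)
                    if k not in gene.single_skips
                ]
                if not internal:
                    continue
                k = int(rng.choice(internal))
                exons = tuple(s for j, s in enumerate(gene.slots) if j != k)
                chrom, strand = gene.chrom, gene.strand
                source = gene.isoform_ids[0]
                detail = f"exon-skip:{k}"
            else:
                ref = multi[int(rng.integers(len(multi)))]
                n = ref.n_exons - 1
                if n < 3:
                    continue
                k = int(rng.integers(1, n - 1))  # internal intron
                exons = list(ref.exons)
                merged = (exons[k][0], exons[k + 1][1])
                exons = tuple(exons[:k] + [merged] + exons[k + 2 :])
                chrom, strand = ref.chrom, ref.strand
                source = ref.transcript_id
                detail = f"intron-retention:{k}"
            chain = tuple(
                (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
            )
            if (chrom, strand, chain) in all_chains:
                continue
            ref_chains = [
                junction_chain(m).introns
                for m in multi
                if m.chrom == chrom and m.strand == strand
            ]
            if any(is_consecutive_subchain(chain, rc) for rc in ref_chains):
                continue  # accidental ISM
            return exons, chrom, strand, source, detail
    raise ConstructionError("NIC unconstructible from reference topology")


def _build_nnc(annotation, catalog, multi, by_gene, all_chains, rng):
    for _ in range(200):
        ref = multi[int(rng.integers(len(multi)))]
        exons = list(ref.exons)
        k = int(rng.integers(len(exons) - 1))  # intron index
        side = str(rng.choice(["donor", "acceptor"]))  # genomic left/right edge
        delta = int(rng.choice([-1, 1])) * int(rng.integers(3, 13))
        if side == "donor":  # move intron start = end of exon k
            s, e = exons[k]
            new_e = e + delta
            if new_e - s < 10 or exons[k + 1][0] - new_e < 30:
                continue
            new_site = new_e
            exons[k] = (s, new_e)
        else:  # move intron end = start of exon k+1
            s, e = exons[k + 1]
            new_s = s + delta
            if e - new_s < 10 or new_s - exons[k][1] < 30:
                continue
            new_site = new_s
            exons[k + 1] = (new_s, e)
        key = (ref.chrom, ref.strand, new_site)
        if key in catalog.donor_set or key in catalog.acceptor_set:
            continue
        return (
            tuple(exons),
            ref.chrom,
            ref.strand,
            ref.transcript_id,
            f"site-shift:{k}:{side}:{delta:+d}",
        )
    raise ConstructionError("NNC unconstructible from reference topology")


def _build_other(annotation, catalog, multi, by_gene, all_chains, rng):
    if rng.random() < 0.5:
        ref = multi[int(rng.integers(len(multi)))]
        flipped = "-" if ref.strand == "+" else "+"
        return ref.exons, ref.chrom, flipped, ref.transcript_id, "antisense"
    # intergenic mono-exon in the gap upstream of a random gene
    gene = annotation.genes[int(rng.integers(len(annotation.genes)))]
    gap_end = gene.slots[0][0] - 1000
    gap_start = gap_end - 600
    if gap_start < 0:
        gap_start, gap_end = 100, 700
    strand = str(rng.choice(["+", "-"]))
    return ((gap_start, gap_end),), gene.chrom, strand, None, "intergenic"


# ---------------------------------------------------------------------------
# quantification


def gen_quant(
    truth_ids: Sequence[str], cfg: SimulationConfig
) -> Tuple[QuantMatrix, pd.Series]:
    """Replicate TPM estimates with known truth.

    Truth TPM is log-normal, normalized to 10^6. Estimates apply
    multiplicative log-normal noise exp(N(0, noise_sd)) per (i, g, r), then
    Bernoulli dropout, then per-column renormalization to 10^6. Noise,
    dropout and truth use independent seed streams so varying one parameter
    leaves the other draws fixed.
    """
    ids = list(truth_ids)
    rng_truth = _rng(cfg, 0xC0)
    rng_noise = _rng(cfg, 0xC1)
    rng_drop = _rng(cfg, 0xC2)

    truth = rng_truth.lognormal(cfg.tpm_meanlog, cfg.tpm_sdlog, len(ids))
    truth = truth * (TPM_TOTAL / truth.sum())
    truth_s = pd.Series(truth, index=ids)

    shape = (len(ids), cfg.groups, cfg.replicates)
    eps = rng_noise.standard_normal(shape) * cfg.noise_sd
    est = truth[:, None, None] * np.exp(eps)
    if cfg.dropout_rate > 0:
        est = np.where(rng_drop.random(shape) < cfg.dropout_rate, 0.0, est)
    col_sums = est.sum(axis=0)
    est = np.divide(
        est * TPM_TOTAL, col_sums[None, :, :], out=est, where=col_sums[None, :, :] > 0
    )
    q = QuantMatrix.from_arrays(
        ids,
        [f"group{g + 1}" for g in range(cfg.groups)],
        [f"rep{r + 1}" for r in range(cfg.replicates)],
        est,
    )
    return q, truth_s


def gen_component_truths(
    truth_ids: Sequence[str], cfg: SimulationConfig
) -> Tuple[pd.Series, pd.Series]:
    """Two independent log-normal truth profiles over the same ids (the two
    pure samples of the mixing design)."""
    ids = list(truth_ids)
    rng = _rng(cfg, 0xD0)
    out = []
    for _ in range(2):
        v = rng.lognormal(cfg.tpm_meanlog, cfg.tpm_sdlog, len(ids))
        out.append(pd.Series(v * (TPM_TOTAL / v.sum()), index=ids))
    return out[0], out[1]


def gen_mixing(
    truth_a: pd.Series, truth_b: pd.Series, cfg: SimulationConfig
) -> Tuple[QuantMatrix, pd.Series]:
    """Observed mixed-sample replicates for a known mixing ratio.

    The mixed truth is w·a + (1−w)·b renormalized to 10^6; observed
    replicates carry the same noise/dropout model as :func:`gen_quant`.
    Returns (observed QuantMatrix with one 'mix' group, mixed truth).
    """
    mixed = mixing_expected(truth_a, truth_b, cfg.mixing_w)
    rng_noise = _rng(cfg, 0xD1)
    rng_drop = _rng(cfg, 0xD2)
    shape = (len(mixed), 1, cfg.replicates)
    eps = rng_noise.standard_normal(shape) * cfg.noise_sd
    est = mixed.to_numpy()[:, None, None] * np.exp(eps)
    if cfg.dropout_rate > 0:
        est = np.where(rng_drop.random(shape) < cfg.dropout_rate, 0.0, est)
    col_sums = est.sum(axis=0)
    est = np.divide(
        est * TPM_TOTAL, col_sums[None, :, :], out=est, where=col_sums[None, :, :] > 0
    )
    q = QuantMatrix.from_arrays(
        list(mixed.index), ["mix"], [f"rep{r + 1}" for r in range(cfg.replicates)], est
    )
    return q, mixed
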