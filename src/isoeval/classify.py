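"""Structural classification of transcript models against a reference catalog.

Every query is assigned exactly one structural category:

* **FSM** — full splice match: the query's junction chain equals a reference
  transcript's chain exactly.
* **ISM** — incomplete splice match: the chain is a consecutive, proper
  sub-run of one reference chain (5'/3' truncation).
* **NIC** — novel in catalog: every splice site is annotated but the
  transcript is new — a new combination of known junctions, a novel junction
  formed from known donor/acceptor sites, or unannotated intron retention.
* **NNC** — novel not in catalog: at least one unannotated donor or acceptor.
* **other** — antisense / fusion / genic / intergenic / mono-exon-match.

Precedence is FSM > ISM > NNC > fusion > NIC > other: a chain with any novel
splice site is NNC unconditionally, and multi-locus-spanning chains built
from annotated sites are called fusions before the NIC combination catch-all
can absorb them.

End-support flags (reference windows, CAGE, poly(A) motif / 3'-end peaks,
short-read junction counts) compose into the SRTM/SNTM "fully supported
model" calls. The reference window defaults to 50 nt, inclusive.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    AnnotationError,
    Interval,
    JunctionChain,
    JunctionKey,
    ReferenceCatalog,
    TranscriptModel,
    acceptor_site,
    donor_site,
    is_consecutive_subchain,
    junction_chain,
    junction_key,
)

DEFAULT_WINDOW = 50
POLYA_MOTIFS = ("AATAAA", "ATTAAA")
POLYA_UPSTREAM = 50  # bases upstream of the 3' end scanned for the hexamer
CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ConfigurationError(ValueError):
    """An evidence check was requested without the data it needs."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CategoryCall:
    query_id: str
    category: str  # FSM | ISM | NIC | NNC | other
    other_subtype: str = "none"  # antisense|fusion|genic|intergenic|mono-exon-match|none
    matched_reference_id: Optional[str] = None
    tss_distance: Optional[int] = None  # signed, + means query 5' end downstream of ref
    tts_distance: Optional[int] = None
    nic_reason: str = "none"  # junction-combination|novel-junction-known-sites|intron-retention|none


@dataclass
class SupportEvidence:
    """Orthogonal evidence: 5' CAGE peaks, 3' end peaks, junction read counts,
    and an optional genome for splice-motif and poly(A)-hexamer checks.

    ``genome`` may be any mapping from chromosome name to sequence (a plain
    dict or a ``pyfaidx.Fasta``). Any component may be absent; dependent flags
    then evaluate as unavailable rather than false-negative.
    """

    cage_peaks: Optional[pd.DataFrame] = None  # chrom/start/end[/name/score/strand]
    tts_peaks: Optional[pd.DataFrame] = None
    junction_counts: Optional[Dict[JunctionKey, int]] = None
    genome: Optional[Mapping[str, object]] = None
    polya_motifs: Tuple[str, ...] = POLYA_MOTIFS
    _cage_trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _tts_trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._cage_trees = _peak_trees(self.cage_peaks)
        self._tts_trees = _peak_trees(self.tts_peaks)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self.genome is None:
            raise ConfigurationError("genome sequence required but not provided")
        seq = self.genome[chrom]
        return str(seq[max(start, 0) : end]).upper()


def _peak_trees(peaks: Optional[pd.DataFrame]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    if peaks is None:
        return {}
    strands = peaks["strand"] if "strand" in peaks.columns else ["."] * len(peaks)
    for chrom, start, end, strand in zip(
        peaks["chrom"], peaks["start"], peaks["end"], strands
    ):
        trees[str(chrom)].addi(int(start), int(end), str(strand))
    return dict(trees)


def _peak_near(
    trees: Dict[str, IntervalTree], chrom: str, strand: str, pos: int, window: int
) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    for iv in tree.overlap(pos - window, pos + window + 1):
        if iv.data in (".", strand):
            return True
    return False


@dataclass
class SupportFlags:
    ref_5p: bool = False
    ref_3p: bool = False
    cage_5p: bool = False
    polya_3p: bool = False
    reference_match: bool = False
    srtm: Optional[bool] = None  # defined only for FSM/ISM
    sntm: Optional[bool] = None  # defined only for NIC/NNC
    junctions_supported_fraction: Optional[float] = None
    all_junctions_supported: Optional[bool] = None
    n_novel_junctions: int = 0
    n_noncanonical_junctions: Optional[int] = None


def _end_distances(query: TranscriptModel, ref: TranscriptModel) -> Tuple[int, int]:
    """Signed (TSS, TTS) distances; positive = query end downstream of ref's."""
    sign = 1 if query.strand == "+" else -1
    return sign * (query.tss - ref.tss), sign * (query.tts - ref.tts)


def _best_reference(
    query: TranscriptModel, candidates: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Tie-break among chain-matching references: minimize |dTSS| + |dTTS|."""
    return min(
        candidates,
        key=lambda r: (
            abs(query.tss - r.tss) + abs(query.tts - r.tts),
            r.transcript_id,
        ),
    )


def classify(
    query: TranscriptModel, catalog: ReferenceCatalog, window: int = DEFAULT_WINDOW
) -> CategoryCall:
    """Assign the structural category of one query transcript.

    Mono-exon queries are routed to :func:`classify_mono_exon`; FSM is never
    assigned to them.
    """
    if query.n_exons == 1:
        return classify_mono_exon(query, catalog, window=window)

    chain = junction_chain(query)

    # FSM: exact chain match
    ref_ids = catalog.chain_index.get(chain)
    if ref_ids:
        ref = _best_reference(query, [catalog.transcripts[i] for i in ref_ids])
        d5, d3 = _end_distances(query, ref)
        return CategoryCall(
            query.transcript_id,
            "FSM",
            matched_reference_id=ref.transcript_id,
            tss_distance=d5,
            tts_distance=d3,
        )

    # ISM: consecutive proper sub-run of a reference chain at the same locus;
    # candidates necessarily share >= 1 junction with the query
    keys = [junction_key(query.chrom, query.strand, i) for i in chain.introns]
    candidate_ids: Set[str] = set()
    for k in keys:
        candidate_ids.update(catalog.junction_to_refs.get(k, ()))
    ism_refs = [
        catalog.transcripts[i]
        for i in sorted(candidate_ids)
        if is_consecutive_subchain(
            chain.introns, junction_chain(catalog.transcripts[i]).introns
        )
    ]
    if ism_refs:
        ref = _best_reference(query, ism_refs)
        d5, d3 = _end_distances(query, ref)
        return CategoryCall(
            query.transcript_id,
            "ISM",
            matched_reference_id=ref.transcript_id,
            tss_distance=d5,
            tts_distance=d3,
        )

    donors = [donor_site(query.chrom, query.strand, i) for i in chain.introns]
    acceptors = [acceptor_site(query.chrom, query.strand, i) for i in chain.introns]
    novel_sites = [d for d in donors if d not in catalog.donor_set] + [
        a for a in acceptors if a not in catalog.acceptor_set
    ]
    overlapped = catalog.overlapping_loci(
        query.chrom, query.strand, query.start, query.end
    )
    known_any = (
        len(novel_sites) < len(donors) + len(acceptors)
        or any(k in catalog.junction_set for k in keys)
    )
    associated = bool(overlapped) or known_any

    if not associated:
        return CategoryCall(
            query.transcript_id, "other", other_subtype=_orphan_subtype(query, catalog)
        )

    if novel_sites:
        return CategoryCall(query.transcript_id, "NNC")

    # all splice sites annotated from here on
    if len(overlapped) >= 2:
        return CategoryCall(query.transcript_id, "other", other_subtype="fusion")

    if _has_intron_retention(query, catalog, overlapped):
        return CategoryCall(query.transcript_id, "NIC", nic_reason="intron-retention")
    if any(k not in catalog.junction_set for k in keys):
        return CategoryCall(
            query.transcript_id, "NIC", nic_reason="novel-junction-known-sites"
        )
    return CategoryCall(query.transcript_id, "NIC", nic_reason="junction-combination")


def _orphan_subtype(query: TranscriptModel, catalog: ReferenceCatalog) -> str:
    opposite = "-" if query.strand == "+" else "+"
    if catalog.overlapping_loci(query.chrom, opposite, query.start, query.end):
        return "antisense"
    return "intergenic"


def _has_intron_retention(
    query: TranscriptModel, catalog: ReferenceCatalog, locus_indices: Sequence[int]
) -> bool:
    """A query exon fully contains an annotated intron of a same-strand
    overlapping reference, both flanking splice sites strictly inside."""
    for li in locus_indices:
        for tid in catalog.loci[li].transcript_ids:
            ref = catalog.transcripts[tid]
            for intron in junction_chain(ref).introns:
                for es, ee in query.exons:
                    if es < intron[0] and intron[1] < ee:
                        return True
    return False


def classify_mono_exon(
    query: TranscriptModel, catalog: ReferenceCatalog, window: int = DEFAULT_WINDOW
) -> CategoryCall:
    """Classify an unspliced query. FSM is never assigned: a mono-exon query
    matching a mono-exon reference (same strand, both ends within ``window``)
    is called other/mono-exon-match; otherwise genic / antisense / intergenic
    by span overlap."""
    for ref in catalog.transcripts.values():
        if (
            ref.n_exons == 1
            and ref.chrom == query.chrom
            and ref.strand == query.strand
            and query.start < ref.end
            and ref.start < query.end
            and abs(query.start - ref.start) <= window
            and abs(query.end - ref.end) <= window
        ):
            d5, d3 = _end_distances(query, ref)
            return CategoryCall(
                query.transcript_id,
                "other",
                other_subtype="mono-exon-match",
                tss_distance=d5,
                tts_distance=d3,
            )
    if catalog.overlapping_loci(query.chrom, query.strand, query.start, query.end):
        return CategoryCall(query.transcript_id, "other", other_subtype="genic")
    return CategoryCall(
        query.transcript_id, "other", other_subtype=_orphan_subtype(query, catalog)
    )


def match_reference(
    call: CategoryCall,
    query: TranscriptModel,
    catalog: ReferenceCatalog,
    window: int = DEFAULT_WINDOW,
) -> Tuple[bool, bool, bool]:
    """Reference end support: ``(ref_5p, ref_3p, reference_match)``.

    ``ref_5p``/``ref_3p`` are true iff the query end lies within ``window``
    (inclusive) of the nearest same-gene reference TSS/TTS; the gene is the
    matched reference's gene for FSM/ISM, otherwise any same-strand
    overlapping locus. ``reference_match`` additionally gates on FSM and on
    both ends of the single matched reference.
    """
    if call.matched_reference_id is not None:
        gene = catalog.transcripts[call.matched_reference_id].gene_id
        candidates = [t for t in catalog.transcripts.values() if t.gene_id == gene]
    else:
        candidates = [
            catalog.transcripts[tid]
            for li in catalog.overlapping_loci(
                query.chrom, query.strand, query.start, query.end
            )
            for tid in catalog.loci[li].transcript_ids
        ]
    if not candidates:
        return False, False, False

    ref_5p = min(abs(query.tss - r.tss) for r in candidates) <= window
    ref_3p = min(abs(query.tts - r.tts) for r in candidates) <= window

    reference_match = False
    if call.category == "FSM" and call.matched_reference_id is not None:
        matched = catalog.transcripts[call.matched_reference_id]
        reference_match = (
            abs(query.tss - matched.tss) <= window
            and abs(query.tts - matched.tts) <= window
        )
    return ref_5p, ref_3p, reference_match


def evidence_support(
    query: TranscriptModel,
    evidence: SupportEvidence,
    window: int = DEFAULT_WINDOW,
    motif: Optional[bool] = None,
) -> Tuple[bool, bool]:
    """Experimental end support: ``(cage_5p, polya_3p)``.

    ``cage_5p`` — the 5' end lies within ``window`` of (or inside) a CAGE
    peak. ``polya_3p`` — the 3' end lies within ``window`` of a 3'-end peak,
    or a poly(A) hexamer (AATAAA/ATTAAA) occurs within 50 bases upstream of
    the 3' end on the transcript strand. ``motif=True`` forces the hexamer
    scan and raises :class:`ConfigurationError` without a genome;
    ``motif=None`` runs it only when a genome is available.
    """
    cage_5p = _peak_near(
        evidence._cage_trees, query.chrom, query.strand, query.tss, window
    )
    polya_3p = _peak_near(
        evidence._tts_trees, query.chrom, query.strand, query.tts, window
    )
    if motif is True and evidence.genome is None:
        raise ConfigurationError("poly(A) motif check requested without a genome")
    do_motif = motif if motif is not None else evidence.genome is not None
    if not polya_3p and do_motif:
        if query.strand == "+":
            upstream = evidence.fetch(query.chrom, query.tts - POLYA_UPSTREAM, query.tts)
        else:
            upstream = revcomp(
                evidence.fetch(query.chrom, query.tts, query.tts + POLYA_UPSTREAM)
            )
        polya_3p = any(m in upstream for m in evidence.polya_motifs)
    return cage_5p, polya_3p


def srtm_sntm(
    call: CategoryCall,
    ref_5p: bool,
    ref_3p: bool,
    cage_5p: bool,
    polya_3p: bool,
    novel_junction_counts: Sequence[int],
) -> Tuple[Optional[bool], Optional[bool]]:
    """Fully-supported model composites.

    SRTM (FSM/ISM): (5' within window of TSS or CAGE) AND (3' within window
    of TTS or poly(A)/3'-seq support). SNTM (NIC/NNC): same end conditions
    AND short-read support (count >= 1) at every novel junction.
    """
    ends_ok = (ref_5p or cage_5p) and (ref_3p or polya_3p)
    srtm = ends_ok if call.category in ("FSM", "ISM") else None
    sntm = None
    if call.category in ("NIC", "NNC"):
        sntm = ends_ok and all(c >= 1 for c in novel_junction_counts)
    return srtm, sntm


def support_flags(
    query: TranscriptModel,
    call: CategoryCall,
    catalog: ReferenceCatalog,
    evidence: Optional[SupportEvidence] = None,
    window: int = DEFAULT_WINDOW,
) -> SupportFlags:
    """Compute the full support-flag set for one classified query."""
    ref_5p, ref_3p, reference_match = match_reference(call, query, catalog, window)
    cage_5p = polya_3p = False
    if evidence is not None:
        cage_5p, polya_3p = evidence_support(query, evidence, window)

    chain = junction_chain(query)
    keys = [junction_key(query.chrom, query.strand, i) for i in chain.introns]
    novel_keys = [k for k in keys if k not in catalog.junction_set]

    counts = evidence.junction_counts if evidence is not None else None
    supported_fraction: Optional[float] = None
    all_supported: Optional[bool] = None
    novel_counts: List[int] = [0] * len(novel_keys)
    if counts is not None and keys:
        per_junction = [counts.get(k, 0) for k in keys]
        supported_fraction = sum(c >= 1 for c in per_junction) / len(per_junction)
        all_supported = all(c >= 1 for c in per_junction)
        novel_counts = [counts.get(k, 0) for k in novel_keys]

    srtm, sntm = srtm_sntm(call, ref_5p, ref_3p, cage_5p, polya_3p, novel_counts)

    n_noncanon: Optional[int] = None
    if evidence is not None and evidence.genome is not None:
        n_noncanon = sum(
            not _is_canonical(evidence, query.chrom, query.strand, intron)
            for intron in chain.introns
        )

    return SupportFlags(
        ref_5p=ref_5p,
        ref_3p=ref_3p,
        cage_5p=cage_5p,
        polya_3p=polya_3p,
        reference_match=reference_match,
        srtm=srtm,
        sntm=sntm,
        junctions_supported_fraction=supported_fraction,
        all_junctions_supported=all_supported,
        n_novel_junctions=len(novel_keys),
        n_noncanonical_junctions=n_noncanon,
    )


def _is_canonical(
    evidence: SupportEvidence, chrom: str, strand: str, intron: Interval
) -> bool:
    left = evidence.fetch(chrom, intron[0], intron[0] + 2)
    right = evidence.fetch(chrom, intron[1] - 2, intron[1])
    if strand == "+":
        pair = (left, right)
    else:
        pair = (revcomp(right), revcomp(left))
    return pair in CANONICAL_PAIRS


def chain_length_ratios(
    call: CategoryCall, query: TranscriptModel, catalog: ReferenceCatalog
) -> Optional[float]:
    """Junction-count ratio relating a query chain to the reference.

    ISM: query junctions / matched reference junctions, in (0, 1).
    NIC/NNC: junctions of the longest same-locus reference / query junctions.
    ``None`` for other categories, or when no spliced same-locus reference
    exists.
    """
    n_query = query.n_exons - 1
    if call.category == "ISM":
        ref = catalog.transcripts[call.matched_reference_id]
        return n_query / (ref.n_exons - 1)
    if call.category in ("NIC", "NNC"):
        locus_refs = [
            catalog.transcripts[tid]
            for li in catalog.overlapping_loci(
                query.chrom, query.strand, query.start, query.end
            )
            for tid in catalog.loci[li].transcript_ids
        ]
        spliced = [r for r in locus_refs if r.n_exons > 1]
        if not spliced or n_query == 0:
            return None
        return max(r.n_exons - 1 for r in spliced) / n_query
    return None


def junction_profile(
    models: Sequence[TranscriptModel],
    catalog: ReferenceCatalog,
    evidence: Optional[SupportEvidence] = None,
) -> Dict[str, Optional[float]]:
    """Submission-level junction quality profile.

    Percentages are over the distinct junctions (respectively the spliced
    transcripts) of the submission. Canonical-site fields require a genome in
    ``evidence`` and are reported as ``None`` — unavailable, not zero — when
    absent; likewise short-read support fields without junction counts.
    """
    junctions: Set[JunctionKey] = set()
    spliced = [m for m in models if m.n_exons > 1]
    for m in spliced:
        for intron in junction_chain(m).introns:
            junctions.add(junction_key(m.chrom, m.strand, intron))

    n_j = len(junctions)
    out: Dict[str, Optional[float]] = {
        "n_junctions": float(n_j),
        "n_spliced_transcripts": float(len(spliced)),
        "pct_novel_junctions": None,
        "pct_noncanonical_junctions": None,
        "pct_noncanonical_transcripts": None,
        "pct_junctions_supported": None,
        "pct_transcripts_fully_supported": None,
    }
    if n_j == 0:
        return out

    out["pct_novel_junctions"] = (
        100.0 * sum(k not in catalog.junction_set for k in junctions) / n_j
    )

    if evidence is not None and evidence.genome is not None:
        noncanon = {
            k
            for k in junctions
            if not _is_canonical(evidence, k[0], k[1], (k[2], k[3]))
        }
        out["pct_noncanonical_junctions"] = 100.0 * len(noncanon) / n_j
        out["pct_noncanonical_transcripts"] = (
            100.0
            * sum(
                any(
                    junction_key(m.chrom, m.strand, i) in noncanon
                    for i in junction_chain(m).introns
                )
                for m in spliced
            )
            / len(spliced)
        )

    if evidence is not None and evidence.junction_counts is not None:
        counts = evidence.junction_counts
        out["pct_junctions_supported"] = (
            100.0 * sum(counts.get(k, 0) >= 1 for k in junctions) / n_j
        )
        out["pct_transcripts_fully_supported"] = (
            100.0
            * sum(
                all(
                    counts.get(junction_key(m.chrom, m.strand, i), 0) >= 1
                    for i in junction_chain(m).introns
                )
                for m in spliced
            )
            / len(spliced)
        )
    return out


def classification_table(
    queries: Sequence[TranscriptModel],
    catalog: ReferenceCatalog,
    evidence: Optional[SupportEvidence] = None,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-transcript classification table (one row per query)."""
    rows = []
    for q in queries:
        call = classify(q, catalog, window=window)
        flags = support_flags(q, call, catalog, evidence=evidence, window=window)
        rows.append(
            {
                "query_id": q.transcript_id,
                "category": call.category,
                "subtype": call.other_subtype,
                "nic_reason": call.nic_reason,
                "matched_reference_id": call.matched_reference_id,
                "tss_distance": call.tss_distance,
                "tts_distance": call.tts_distance,
                "n_exons": q.n_exons,
                "length": q.exonic_length,
                "ref_5p": flags.ref_5p,
                "ref_3p": flags.ref_3p,
                "cage_5p": flags.cage_5p,
                "polya_3p": flags.polya_3p,
                "reference_match": flags.reference_match,
                "srtm": flags.srtm,
                "sntm": flags.sntm,
                "junctions_supported_fraction": flags.junctions_supported_fraction,
                "all_junctions_supported": flags.all_junctions_supported,
                "n_novel_junctions": flags.n_novel_junctions,
                "n_noncanonical_junctions": flags.n_noncanonical_junctions,
            }
        )
    return pd.DataFrame(rows)
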