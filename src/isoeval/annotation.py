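"""Core representation of transcript models, junction chains, and reference catalogs.

Coordinates are 0-based, half-open throughout. Conversion to/from the 1-based
inclusive GTF convention happens only at I/O time (see :mod:`isoeval.gtf`).

A transcript model is an ordered list of exon intervals on one chromosome and
strand. Its *junction chain* — the ordered list of intron intervals between
consecutive exons — identifies the transcript structure independently of the
exact 5'/3' end positions; two models with the same chain are the same "unique
junction chain" (UJC). The chain is the unit of comparison for structural
classification and cross-pipeline agreement analyses.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

Interval = Tuple[int, int]


class AnnotationError(ValueError):
    """Invalid transcript model or catalog input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons on a single chromosome and strand.

    Invariants (checked on construction): at least one exon; exons sorted
    ascending, non-overlapping, separated by >= 1 base; start < end for every
    exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.exons) < 1:
            raise AnnotationError(f"transcript {self.transcript_id!r}: needs >= 1 exon")
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: exon ({start},{end}) has start >= end"
                )
            if prev_end is not None and start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: exons overlap or touch "
                    f"(previous end {prev_end}, next start {start}); "
                    "possible duplicate transcript_id in input"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the biological 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Genomic coordinate of the biological 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class JunctionChain:
    """Ordered intron coordinates identifying a transcript structure (UJC).

    Empty for mono-exon transcripts. Identity is exact: (chrom, strand, exact
    intron coordinate list). End variability is handled elsewhere, at TSS/TTS
    evaluation, never here.
    """

    chrom: str
    strand: str
    introns: Tuple[Interval, ...]

    def __len__(self) -> int:
        return len(self.introns)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.introns) == 0


def junction_chain(t: TranscriptModel) -> JunctionChain:
    """Derive the junction chain: gaps between consecutive exons."""
    introns = tuple(
        (t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)
    )
    return JunctionChain(t.chrom, t.strand, introns)


def is_consecutive_subchain(
    query: Tuple[Interval, ...], ref: Tuple[Interval, ...]
) -> bool:
    """True iff ``query`` introns form a consecutive *proper* run of ``ref``."""
    nq, nr = len(query), len(ref)
    if nq == 0 or nq >= nr:
        return False
    return any(ref[o : o + nq] == query for o in range(nr - nq + 1))


JunctionKey = Tuple[str, str, int, int]  # (chrom, strand, start, end)
SiteKey = Tuple[str, str, int]  # (chrom, strand, position)


def junction_key(chrom: str, strand: str, intron: Interval) -> JunctionKey:
    return (chrom, strand, intron[0], intron[1])


def donor_site(chrom: str, strand: str, intron: Interval) -> SiteKey:
    """Donor position of an intron: intron start on '+', intron end on '-'."""
    return (chrom, strand, intron[0] if strand == "+" else intron[1])


def acceptor_site(chrom: str, strand: str, intron: Interval) -> SiteKey:
    return (chrom, strand, intron[1] if strand == "+" else intron[0])


@dataclass(frozen=True)
class Locus:
    """Single-linkage cluster of transcripts connected by exonic overlap."""

    chrom: str
    strand: Optional[str]  # None when strands were pooled
    start: int
    end: int
    transcript_ids: Tuple[str, ...]

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)


def group_loci(
    models: Sequence[TranscriptModel], pool_strands: bool = False
) -> List[Locus]:
    """Cluster transcripts into loci by single-linkage exonic overlap.

    Two transcripts belong to the same locus iff they are connected by a chain
    of pairwise exon-overlapping transcripts on the same chromosome (and same
    strand unless ``pool_strands``). The result partitions the input: every
    model lands in exactly one locus.
    """
    groups: Dict[Tuple, List[int]] = defaultdict(list)
    for i, m in enumerate(models):
        key = (m.chrom,) if pool_strands else (m.chrom, m.strand)
        groups[key].append(i)

    parent = list(range(len(models)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for key, idxs in groups.items():
        # sweep over exons: overlapping exon intervals connect their transcripts
        exons = sorted(
            (s, e, i) for i in idxs for (s, e) in models[i].exons
        )
        cluster_rep = -1
        cluster_max_end = -1
        for s, e, i in exons:
            if s < cluster_max_end:
                union(cluster_rep, i)
                cluster_max_end = max(cluster_max_end, e)
            else:
                cluster_rep = i
                cluster_max_end = e

    members: Dict[int, List[int]] = defaultdict(list)
    for i in range(len(models)):
        members[find(i)].append(i)

    loci = []
    for idxs in members.values():
        ms = [models[i] for i in idxs]
        loci.append(
            Locus(
                chrom=ms[0].chrom,
                strand=None if pool_strands else ms[0].strand,
                start=min(m.start for m in ms),
                end=max(m.end for m in ms),
                transcript_ids=tuple(sorted(m.transcript_id for m in ms)),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.strand or "", l.start, l.end))
    return loci


@dataclass
class ReferenceCatalog:
    """Indexed reference annotation: chains, splice sites, ends, and loci.

    ``chain_index`` covers exactly the multi-exon reference transcripts;
    ``donor_set``/``acceptor_set`` are the strand-aware projections of
    ``junction_set``.
    """

    transcripts: Dict[str, TranscriptModel]
    chain_index: Dict[JunctionChain, Tuple[str, ...]]
    junction_set: Set[JunctionKey]
    donor_set: Set[SiteKey]
    acceptor_set: Set[SiteKey]
    junction_to_refs: Dict[JunctionKey, Tuple[str, ...]]
    loci: List[Locus]
    locus_of: Dict[str, int]  # transcript_id -> index into loci
    _locus_trees: Dict[Tuple[str, str], IntervalTree] = field(default_factory=dict)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def overlapping_loci(
        self, chrom: str, strand: str, start: int, end: int
    ) -> List[int]:
        """Indices of same-strand loci whose span overlaps [start, end)."""
        tree = self._locus_trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def gene_transcripts(self, gene_id: str) -> List[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


def build_catalog(
    models: Sequence[TranscriptModel], pool_strands: bool = False
) -> ReferenceCatalog:
    """Index a reference annotation for classification and detection scoring."""
    transcripts: Dict[str, TranscriptModel] = {}
    for m in models:
        if m.transcript_id in transcripts:
            raise AnnotationError(f"duplicate transcript_id {m.transcript_id!r}")
        transcripts[m.transcript_id] = m

    chain_index: Dict[JunctionChain, List[str]] = defaultdict(list)
    junction_set: Set[JunctionKey] = set()
    donor_set: Set[SiteKey] = set()
    acceptor_set: Set[SiteKey] = set()
    junction_to_refs: Dict[JunctionKey, List[str]] = defaultdict(list)

    for m in models:
        chain = junction_chain(m)
        if not chain.is_mono_exon:
            chain_index[chain].append(m.transcript_id)
            for intron in chain.introns:
                key = junction_key(m.chrom, m.strand, intron)
                junction_set.add(key)
                donor_set.add(donor_site(m.chrom, m.strand, intron))
                acceptor_set.add(acceptor_site(m.chrom, m.strand, intron))
                junction_to_refs[key].append(m.transcript_id)

    loci = group_loci(models, pool_strands=pool_strands)
    locus_of = {}
    trees: Dict[Tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for idx, locus in enumerate(loci):
        for tid in locus.transcript_ids:
            locus_of[tid] = idx
        strands = ("+", "-") if locus.strand is None else (locus.strand,)
        for strand in strands:
            trees[(locus.chrom, strand)].addi(locus.start, locus.end, idx)

    return ReferenceCatalog(
        transcripts=transcripts,
        chain_index={c: tuple(ids) for c, ids in chain_index.items()},
        junction_set=junction_set,
        donor_set=donor_set,
        acceptor_set=acceptor_set,
        junction_to_refs={k: tuple(v) for k, v in junction_to_refs.items()},
        loci=loci,
        locus_of=locus_of,
        _locus_trees=dict(trees),
    )
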