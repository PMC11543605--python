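"""GTF and BED I/O for transcript models.

Reads the GENCODE GTF dialect (``exon`` features with ``transcript_id "X";
gene_id "Y";`` attributes) into :class:`~isoeval.annotation.TranscriptModel`
objects, converting 1-based inclusive coordinates to the internal 0-based
half-open convention, and writes them back losslessly (read ∘ write is the
identity on valid models).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd
import pyranges as pr

from .annotation import AnnotationError, TranscriptModel, junction_chain

PathLike = Union[str, Path]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    """Malformed GTF input, reported with the offending line number."""


def _validate_lines(path: PathLike) -> None:
    # Pre-pass so parse failures can name the line; pyranges silently
    # tolerates malformed attribute blocks.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            for required in ("transcript_id", "gene_id"):
                if required not in attrs:
                    raise GTFParseError(
                        f"{path}:{lineno}: exon feature missing {required!r} attribute"
                    )
            if not fields[3].isdigit() or not fields[4].isdigit():
                raise GTFParseError(f"{path}:{lineno}: non-numeric coordinates")


def read_gtf(path: PathLike, source_label: str = "") -> List[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Raises :class:`GTFParseError` naming the offending line on malformed
    input, and :class:`~isoeval.annotation.AnnotationError` naming the
    transcript when a transcript mixes chromosomes or strands.
    """
    _validate_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    gr = pr.read_gtf(str(path))
    df = gr.df
    if df.empty:
        return []
    df = df[df.Feature == "exon"]
    if df.empty:
        return []

    models: List[TranscriptModel] = []
    for tid, sub in df.groupby("transcript_id", sort=True, observed=True):
        chroms = set(map(str, sub.Chromosome))
        strands = set(map(str, sub.Strand))
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {tid!r} spans multiple chromosomes or strands: "
                f"{sorted(chroms)} / {sorted(strands)}"
            )
        gene_ids = set(map(str, sub.gene_id))
        exons = sorted(zip(sub.Start.astype(int), sub.End.astype(int)))
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=sorted(gene_ids)[0],
                chrom=chroms.pop(),
                strand=strands.pop(),
                exons=tuple(exons),
                source_label=source_label,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path: PathLike) -> None:
    """Write models as GTF exon features (1-based inclusive), byte-stable."""
    with open(path, "w") as fh:
        for m in models:
            source = m.source_label or "isoeval"
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_bed6(models: Sequence[TranscriptModel], path: PathLike) -> None:
    """Write one BED6 line per model span (UJC visualization track)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.transcript_id}\t0\t{m.strand}\n"
            )


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read a BED file (>= 3 columns) into a DataFrame with standard names."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"extra{i}" for i in range(df.shape[1] - 6)]
    return df
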