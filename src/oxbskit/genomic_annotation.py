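"""Genomic annotation of DMRs against a transcript model.

Each differentially methylated region (DMR) is assigned to exactly one
genomic category — promoter, exon, TTS, intron or intergenic — by locating
its midpoint and resolving overlaps with a fixed precedence
(promoter > exon > TTS > intron > intergenic).  Category-by-direction
tallies summarise where hyper- and hypomethylated regions fall.

Window definitions are strand-aware and configurable: the promoter spans
TSS −1000..+100 bp and the TTS window spans TTS −100..+1000 bp by default.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("promoter", "exon", "TTS", "intron", "intergenic")


@dataclass(frozen=True)
class Transcript:
    """One transcript: 0-based half-open span with exon sub-intervals.

    For a ``+`` strand transcript the TSS is ``start`` and the TTS is
    ``end``; on the ``-`` strand they swap.
    """

    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("transcript span must be non-empty and non-negative")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError("exon outside transcript span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModel:
    """A set of transcripts plus the promoter/TTS window conventions.

    promoter_window / tts_window are (upstream, downstream) distances in bp
    relative to the TSS / TTS, applied in the direction of transcription.
    """

    transcripts: list[Transcript] = field(default_factory=list)
    promoter_window: tuple[int, int] = (1000, 100)
    tts_window: tuple[int, int] = (100, 1000)

    def promoter_interval(self, t: Transcript) -> tuple[int, int]:
        up, down = self.promoter_window
        if t.strand == "+":
            lo, hi = t.tss - up, t.tss + down
        else:
            lo, hi = t.tss - down + 1, t.tss + up + 1
        return max(0, lo), max(0, hi)

    def tts_interval(self, t: Transcript) -> tuple[int, int]:
        up, down = self.tts_window
        if t.strand == "+":
            lo, hi = t.tts - up, t.tts + down
        else:
            lo, hi = t.tts - down + 1, t.tts + up + 1
        return max(0, lo), max(0, hi)

    def annotate_point(self, chrom: str, point: int) -> str:
        """Category of a single genomic position, by precedence."""
        hits = set()
        for t in self.transcripts:
            if t.chrom != chrom:
                continue
            lo, hi = self.promoter_interval(t)
            if lo <= point < hi:
                hits.add("promoter")
            if t.start <= point < t.end:
                if any(s <= point < e for s, e in t.exons):
                    hits.add("exon")
                else:
                    hits.add("intron")
            lo, hi = self.tts_interval(t)
            if lo <= point < hi:
                hits.add("TTS")
        for cat in CATEGORIES[:-1]:
            if cat in hits:
                return cat
        return "intergenic"

    def to_bed12(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                sizes = ",".join(str(e - s) for s, e in t.exons) + ","
                starts = ",".join(str(s - t.start) for s, e in t.exons) + ","
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            str(t.start),
                            str(t.end),
                            t.name or ".",
                            "0",
                            t.strand,
                            str(t.start),
                            str(t.end),
                            "0",
                            str(len(t.exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_bed12(cls, path: str, **kwargs) -> "GeneModel":
        transcripts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offsets, sizes)
                )
                transcripts.append(
                    Transcript(chrom, start, end, strand, exons, name=name)
                )
        return cls(transcripts=transcripts, **kwargs)


def annotate_dmr(dmr, gene_model: GeneModel) -> str:
    """Assign one category to a DMR via its midpoint.

    Midpoint assignment makes the partition property trivial: every DMR
    receives exactly one label.
    """
    if not gene_model.transcripts:
        warnings.warn("empty gene model: annotating everything as intergenic")
        return "intergenic"
    mid = (dmr.start + dmr.end) // 2
    return gene_model.annotate_point(dmr.chrom, mid)


def annotate_dmrs(dmrs: Sequence, gene_model: GeneModel) -> list[str]:
    return [annotate_dmr(d, gene_model) for d in dmrs]


def category_counts(dmrs: Iterable, categories: Iterable[str]) -> pd.DataFrame:
    """Tabulate (category x direction) counts for annotated DMRs.

    ``categories`` gives one label per DMR in order.  The returned frame has
    one row per category (all five, even if zero) and columns hyper / hypo.
    """
    counts: Counter = Counter()
    for dmr, cat in zip(dmrs, categories, strict=True):
        counts[(cat, dmr.direction)] += 1
    table = pd.DataFrame(
        {
            "hyper": [counts[(c, "hyper")] for c in CATEGORIES],
            "hypo": [counts[(c, "hypo")] for c in CATEGORIES],
        },
        index=pd.Index(CATEGORIES, name="category"),
    )
    table["total"] = table["hyper"] + table["hypo"]
    return table
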