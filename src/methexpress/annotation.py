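"""Genomic context annotation for methylation array probes.

Models CpG-island (CGI) and transcript geometry and derives, for every
probe, two categorical location labels:

* **gene context** — position class relative to a transcript: within
  1500 bp (``TSS1500``) or 200 bp (``TSS200``) upstream of the
  transcription start site, in the 5'UTR, the first exon, the gene body
  or the 3'UTR;
* **island context** — ``Island`` when the probe lies inside a CGI,
  ``Shore`` when it lies within 4 kb of the nearest CGI boundary
  (a single merged flanking class, i.e. no separate shelf and no
  north/south distinction), and ``OpenSea`` beyond that.

Coordinates are 1-based and inclusive throughout (the convention of the
Illumina ``MAPINFO`` column); the BED exporters convert to 0-based
half-open at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GENE_CONTEXTS",
    "ISLAND_CONTEXTS",
    "SHORE_BP",
    "GenomicInterval",
    "TranscriptModel",
    "ProbeRecord",
    "ManifestError",
    "derive_island_context",
    "derive_gene_context",
    "read_manifest",
    "write_manifest",
    "export_bed",
]

#: Canonical ordering used in tables and factor encodings.
GENE_CONTEXTS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3")
ISLAND_CONTEXTS = ("Island", "Shore", "OpenSea")

#: Width, in bp, of the merged shore flanking each CGI (boundary inclusive).
SHORE_BP = 4000


class ManifestError(ValueError):
    """Raised for malformed or inconsistent manifest files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance_to(self, pos: int) -> int:
        """0 when ``pos`` is inside, otherwise bp to the nearest boundary."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript geometry used to classify probe positions.

    ``tss`` sits at the strand-appropriate end of ``body`` (the 5' end
    reading along the strand); ``first_exon`` lies within ``body``;
    ``utr5``/``utr3`` may be ``None`` for non-coding models.
    """

    transcript_id: str
    chrom: str
    strand: str
    tss: int
    first_exon: GenomicInterval
    body: GenomicInterval
    utr5: GenomicInterval | None = None
    utr3: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("first_exon", "body", "utr5", "utr3"):
            iv = getattr(self, name)
            if iv is not None and iv.chrom != self.chrom:
                raise ValueError(f"{name} on {iv.chrom}, transcript on {self.chrom}")
        if not (self.body.start <= self.first_exon.start
                and self.first_exon.end <= self.body.end):
            raise ValueError("first_exon must lie within body")
        expected_tss = self.body.start if self.strand == "+" else self.body.end
        if self.tss != expected_tss:
            raise ValueError(
                f"tss ({self.tss}) must sit at the strand-appropriate end of "
                f"body ({expected_tss} for strand {self.strand})")


@dataclass
class ProbeRecord:
    """One array probe with its derived context labels.

    ``gene_links`` holds ``(transcript_id, gene_context)`` pairs; a probe
    may link to several transcripts, or to none at all (roughly one in
    five CpGs on a 450K-style array is unlinked).
    """

    probe_id: str
    chrom: str
    pos: int
    island_context: str
    gene_links: list[tuple[str, str]] = field(default_factory=list)
    is_cpg: bool = True

    def __post_init__(self) -> None:
        if self.island_context not in ISLAND_CONTEXTS:
            raise ValueError(f"unknown island context {self.island_context!r}")
        for _, ctx in self.gene_links:
            if ctx not in GENE_CONTEXTS:
                raise ValueError(f"unknown gene context {ctx!r}")


def derive_island_context(
    pos: int,
    islands: Sequence[GenomicInterval | tuple[int, int]],
    shore_bp: int = SHORE_BP,
) -> str:
    """Classify a position against the CGIs of its chromosome.

    ``Island`` if ``pos`` lies inside any CGI (boundaries inclusive),
    ``Shore`` if the distance to the nearest CGI boundary is in
    ``[1, shore_bp]`` (so exactly ``shore_bp`` bp away is still Shore),
    ``OpenSea`` otherwise.  An empty island set — e.g. an entire
    chromosome without annotated CGIs — legally yields ``OpenSea``.
    """
    best = None
    for isl in islands:
        if not isinstance(isl, GenomicInterval):
            start, end = isl
            isl = GenomicInterval("_", start, end)
        d = isl.distance_to(pos)
        if d == 0:
            return "Island"
        best = d if best is None else min(best, d)
    if best is not None and best <= shore_bp:
        return "Shore"
    return "OpenSea"


def derive_gene_context(pos: int, tx: TranscriptModel) -> str | None:
    """Classify a position relative to one transcript, or ``None``.

    Precedence among overlapping classes is
    TSS200 > TSS1500 > FirstExon > UTR5 > UTR3 > Body; "upstream" is
    measured against the transcript strand.  Positions outside the body
    and more than 1500 bp upstream of the TSS are unclassified.
    """
    upstream = (tx.tss - pos) if tx.strand == "+" else (pos - tx.tss)
    if 0 <= upstream <= 200:
        return "TSS200"
    if 200 < upstream <= 1500:
        return "TSS1500"
    if tx.first_exon.contains(pos):
        return "FirstExon"
    if tx.utr5 is not None and tx.utr5.contains(pos):
        return "UTR5"
    if tx.utr3 is not None and tx.utr3.contains(pos):
        return "UTR3"
    if tx.body.contains(pos):
        return "Body"
    return None


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

_MANIFEST_FIELDS = ["ProbeID", "Chr", "Pos", "IsCpG", "GeneLinks", "IslandContext",
                    "CGI_Start", "CGI_End"]


def _format_links(links: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{tid}:{ctx}" for tid, ctx in links)


def _parse_links(text: str, line_no: int) -> list[tuple[str, str]]:
    links: list[tuple[str, str]] = []
    if not text:
        return links
    for part in text.split(";"):
        if ":" not in part:
            raise ManifestError(f"line {line_no}: malformed gene link {part!r}")
        tid, ctx = part.rsplit(":", 1)
        if ctx not in GENE_CONTEXTS:
            raise ManifestError(f"line {line_no}: unknown gene context {ctx!r}")
        links.append((tid, ctx))
    return links


def read_manifest(path: str | Path) -> list[ProbeRecord]:
    """Read a probe manifest CSV into :class:`ProbeRecord` objects.

    Island context is taken from the ``IslandContext`` column when
    present and non-empty; otherwise it is derived from the probe's
    nearest-CGI coordinates (``CGI_Start``/``CGI_End``; both empty means
    no CGI within reach, i.e. OpenSea).
    """
    records: list[ProbeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "ProbeID" not in reader.fieldnames:
            raise ManifestError(f"{path}: missing header with ProbeID column")
        for line_no, row in enumerate(reader, start=2):
            pid = (row.get("ProbeID") or "").strip()
            if not pid:
                raise ManifestError(f"line {line_no}: empty ProbeID")
            if pid in seen:
                raise ManifestError(f"line {line_no}: duplicate probe id {pid!r}")
            seen.add(pid)
            try:
                pos = int(row["Pos"])
                chrom = row["Chr"].strip()
                if not chrom:
                    raise KeyError("Chr")
            except (KeyError, TypeError, ValueError) as exc:
                raise ManifestError(f"line {line_no}: malformed row ({exc})") from exc
            island = (row.get("IslandContext") or "").strip()
            if not island:
                cgi_s = (row.get("CGI_Start") or "").strip()
                cgi_e = (row.get("CGI_End") or "").strip()
                if cgi_s and cgi_e:
                    try:
                        islands = [GenomicInterval(chrom, int(cgi_s), int(cgi_e))]
                    except ValueError as exc:
                        raise ManifestError(
                            f"line {line_no}: bad CGI coordinates ({exc})") from exc
                else:
                    islands = []
                island = derive_island_context(pos, islands)
            elif island not in ISLAND_CONTEXTS:
                raise ManifestError(f"line {line_no}: unknown island context {island!r}")
            is_cpg_raw = (row.get("IsCpG") or "1").strip()
            try:
                records.append(ProbeRecord(
                    probe_id=pid,
                    chrom=chrom,
                    pos=pos,
                    island_context=island,
                    gene_links=_parse_links((row.get("GeneLinks") or "").strip(), line_no),
                    is_cpg=is_cpg_raw not in ("0", "false", "False"),
                ))
            except ValueError as exc:
                raise ManifestError(f"line {line_no}: {exc}") from exc
    return records


def write_manifest(records: Iterable[ProbeRecord], path: str | Path) -> None:
    """Write records as a manifest CSV (round-trips with :func:`read_manifest`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_FIELDS)
        for rec in records:
            writer.writerow([
                rec.probe_id, rec.chrom, rec.pos,
                "1" if rec.is_cpg else "0",
                _format_links(rec.gene_links),
                rec.island_context, "", "",
            ])


def export_bed(
    islands: Iterable[GenomicInterval],
    path: str | Path,
    shores: bool = False,
    shore_bp: int = SHORE_BP,
) -> None:
    """Export CGI (or flanking shore) intervals as BED (0-based half-open).

    With ``shores=True``, each island contributes its two flanking
    intervals of ``shore_bp`` bp, clipped at position 1; overlap between
    neighbouring shores is not merged.
    """
    with open(path, "w") as fh:
        for isl in islands:
            if shores:
                left_start = max(1, isl.start - shore_bp)
                if left_start < isl.start:
                    fh.write(f"{isl.chrom}\t{left_start - 1}\t{isl.start - 1}\tshore\n")
                fh.write(f"{isl.chrom}\t{isl.end}\t{isl.end + shore_bp}\tshore\n")
            else:
                fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\tCGI\n")
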