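"""Readers and writers for the plain-text formats the pipeline touches.

BED is consumed verbatim (already 0-based half-open); Bismark coverage
files are 1-based inclusive and converted on read. JASPAR PFM text accepts
both the bare-matrix and the bracketed ``A [ 1 2 ]`` dialects. Every reader
has a matching writer that round-trips bit-identically on integer data.
"""

from __future__ import annotations

import os
import warnings
from typing import Dict, Iterable, List, Tuple

from .core import BASE_INDEX, CpGSite, GenomicInterval, MethylationSample, PFM, RegionSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_methylation_table",
    "write_methylation_table",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


def read_bed(path: str | os.PathLike, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a RegionSet.

    ``track`` and ``browser`` header lines and blank lines are skipped.
    Coordinates are taken verbatim.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ParseError(f"{path}:{lineno}: require 0 <= start < end, got {start}, {end}")
            intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(name=name or os.path.splitext(os.path.basename(path))[0], intervals=intervals)


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in regions.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_methylation_table(
    path: str | os.PathLike, sample_id: str, group: str = ""
) -> MethylationSample:
    """Read a Bismark-coverage-style 6-column TSV into a MethylationSample.

    Columns: chrom, start, end (1-based inclusive), methylation percentage,
    count methylated, count unmethylated. Positions are converted to the
    package's 0-based convention. If the stated percentage disagrees with
    the counts by more than 0.5 percentage points a warning is issued and
    the counts take precedence. Duplicate sites are rejected.
    """
    counts: Dict[CpGSite, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            chrom = fields[0]
            try:
                pos1 = int(fields[1])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative counts")
            n_total = n_meth + n_unmeth
            if n_total > 0 and abs(pct - 100.0 * n_meth / n_total) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: stated methylation {pct}% inconsistent with "
                    f"counts ({n_meth}/{n_total}); counts take precedence",
                    stacklevel=2,
                )
            site = CpGSite(chrom, pos1 - 1)
            if site in counts:
                raise ParseError(f"{path}:{lineno}: duplicate CpG record at {chrom}:{pos1}")
            counts[site] = (n_meth, n_total)
    return MethylationSample(sample_id=sample_id, group=group, counts=counts)


def write_methylation_table(sample: MethylationSample, path: str | os.PathLike) -> None:
    """Write Bismark-coverage format (1-based inclusive positions)."""
    with open(path, "w") as fh:
        for site in sorted(sample.counts):
            m, n = sample.counts[site]
            pct = 100.0 * m / n if n > 0 else 0.0
            fh.write(f"{site.chrom}\t{site.pos + 1}\t{site.pos + 1}\t{pct:g}\t{m}\t{n - m}\n")


def _finish_pfm(motif_id: str, rows: Dict[str, List[float]], path, lineno) -> PFM:
    if set(rows) != set("ACGT"):
        missing = sorted(set("ACGT") - set(rows))
        raise ParseError(f"{path}:{lineno}: motif {motif_id} missing base row(s) {missing}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ParseError(f"{path}:{lineno}: motif {motif_id} has rows of unequal width")
    width = widths.pop()
    counts = [[rows[b][i] for b in "ACGT"] for i in range(width)]
    return PFM(motif_id=motif_id, counts=counts)


def read_jaspar_pfm(path: str | os.PathLike) -> List[PFM]:
    """Read one or more JASPAR-style PFMs from a text file.

    Rows may be labeled (``A [ 1 2 3 ]``) in any order or bare and
    unlabeled, in which case A,C,G,T order is assumed.
    """
    pfms: List[PFM] = []
    motif_id: str | None = None
    rows: Dict[str, List[float]] = {}
    bare_order = "ACGT"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if motif_id is not None:
                    pfms.append(_finish_pfm(motif_id, rows, path, lineno))
                motif_id = line[1:].split()[0] if line[1:].split() else f"motif{len(pfms) + 1}"
                rows = {}
                continue
            if motif_id is None:
                raise ParseError(f"{path}:{lineno}: matrix row before any '>' header")
            base: str | None = None
            body = line
            if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
                base = line[0].upper()
                body = line[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric matrix entry") from exc
            if base is None:
                if len(rows) >= 4:
                    raise ParseError(f"{path}:{lineno}: more than 4 unlabeled rows")
                base = bare_order[len(rows)]
            if base in rows:
                raise ParseError(f"{path}:{lineno}: duplicate {base} row")
            rows[base] = values
    if motif_id is not None:
        pfms.append(_finish_pfm(motif_id, rows, path, "EOF"))
    return pfms


def write_jaspar_pfm(pfms: Iterable[PFM], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id}\n")
            for base in "ACGT":
                b = BASE_INDEX[base]
                vals = " ".join(f"{col[b]:g}" for col in pfm.counts)
                fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: Dict[str, List[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
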