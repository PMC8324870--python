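"""Barcode deconvolution: FASTQ reads -> per-hairpin counts.

Read layout (targeting libraries, 1-based inclusive coordinates as in
the screen's amplicon design): positions 1-17 vector sequence, a 4-bp
spacer ``CGAA`` at positions 18-21 (one mismatch tolerated; ``N``
counts as a mismatch), position 22 skipped, and the 18-nt hairpin
barcode at positions 23-40. Nontargeting libraries carry the barcode
at positions 1-18 with no spacer filter. Coordinates are converted to
0-based half-open slices once, here.

Extracted barcodes are matched to the library by exact lookup, then by
unique Hamming-distance-1 lookup; a sequence at distance 1 from two or
more distinct barcodes is left unassigned. Matching is deterministic
and ungapped, which is appropriate for fixed-length barcode tags.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError
from .library import BARCODE_LENGTH, CountMatrix, SampleSheet, ShrnaLibrary, TALLY_KEYS

SPACER = "CGAA"
SPACER_SLICE = slice(17, 21)          # 1-based 18..21
TARGETING_SLICE = slice(22, 40)       # 1-based 23..40
NONTARGETING_SLICE = slice(0, 18)     # 1-based 1..18
MIN_TARGETING_LENGTH = 40

_ALPHABET = "ACGT"


def match_spacer(sequence: str) -> bool:
    """True iff bases 18-21 (1-based) differ from ``CGAA`` at <= 1 position.

    Reads shorter than 21 nt fail the filter (returned as ``False``,
    never an exception); ``N`` bases count as mismatches.
    """
    if len(sequence) < 21:
        return False
    window = sequence[SPACER_SLICE]
    mismatches = sum(a != b for a, b in zip(window, SPACER))
    return mismatches <= 1


def extract_barcode(sequence: str, layout: str = "targeting_layout") -> str | None:
    """Positional 18-nt barcode slice, or ``None`` if the read is too short."""
    if layout == "targeting_layout":
        if len(sequence) < MIN_TARGETING_LENGTH:
            return None
        return sequence[TARGETING_SLICE]
    if layout == "nontargeting_layout":
        if len(sequence) < BARCODE_LENGTH:
            return None
        return sequence[NONTARGETING_SLICE]
    raise ValueError(f"unknown layout {layout!r}")


class BarcodeMatcher:
    """Exact + unique-1-mismatch barcode lookup for one library.

    All Hamming-1 neighbors of every library barcode are precomputed
    into a dictionary; neighbors claimed by two different hairpins are
    marked ambiguous so :meth:`assign` can refuse them in O(1).
    """

    _AMBIGUOUS = object()

    def __init__(self, library: ShrnaLibrary):
        self._exact: dict[str, str] = {
            e.barcode: e.hairpin_id for e in library.entries
        }
        neighbors: dict[str, object] = {}
        for e in library.entries:
            bc = e.barcode
            for pos in range(len(bc)):
                for base in _ALPHABET:
                    if base == bc[pos]:
                        continue
                    variant = bc[:pos] + base + bc[pos + 1 :]
                    claimed = neighbors.get(variant)
                    if claimed is None:
                        neighbors[variant] = e.hairpin_id
                    elif claimed != e.hairpin_id:
                        neighbors[variant] = self._AMBIGUOUS
        self._neighbors = neighbors

    def assign(self, seq: str) -> str | None:
        """hairpin_id for ``seq``, or ``None`` (unassigned).

        Exact match wins; otherwise a unique Hamming-1 neighbor; a
        sequence equidistant (d=1) from several barcodes, or farther
        than 1 from all, is unassigned.
        """
        hit = self._exact.get(seq)
        if hit is not None:
            return hit
        near = self._neighbors.get(seq)
        if near is None or near is self._AMBIGUOUS:
            return None
        # a neighbor that is itself a library barcode was caught by the
        # exact branch above, so `near` is a genuine 1-mismatch call
        return near  # type: ignore[return-value]


def _open_fastq(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def _iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from plain or gzipped FASTQ."""
    with _open_fastq(path) as fh:
        for read_index, (title, seq, _qual) in enumerate(FastqGeneralIterator(fh)):
            yield title, seq.upper()


def count_sample(
    fastq_path: str | Path,
    library: ShrnaLibrary,
    layout: str | None = None,
    matcher: BarcodeMatcher | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Deconvolve one FASTQ into per-hairpin counts plus read tallies.

    Returns ``(counts, tallies)`` where counts is indexed by
    hairpin_id in library order and tallies has keys ``total_reads``,
    ``spacer_fail``, ``extraction_fail``, ``unassigned``. Conservation
    holds: ``counts.sum() + spacer_fail + extraction_fail + unassigned
    == total_reads``.
    """
    layout = layout or library.library_type
    matcher = matcher or BarcodeMatcher(library)
    counts = {hid: 0 for hid in library.hairpin_ids}
    tallies = dict.fromkeys(TALLY_KEYS, 0)
    read_index = -1
    try:
        for read_index, (_rid, seq) in enumerate(_iter_reads(fastq_path)):
            tallies["total_reads"] += 1
            if layout == "targeting_layout" and not match_spacer(seq):
                tallies["spacer_fail"] += 1
                continue
            barcode = extract_barcode(seq, layout)
            if barcode is None:
                tallies["extraction_fail"] += 1
                continue
            hit = matcher.assign(barcode)
            if hit is None:
                tallies["unassigned"] += 1
            else:
                counts[hit] += 1
    except ValueError as exc:  # truncated / malformed FASTQ record
        raise ParseError(f"{fastq_path}: bad FASTQ near read {read_index + 2}: {exc}") from exc
    return pd.Series(counts, name="count"), tallies


def count_samples(
    sheet: SampleSheet,
    library: ShrnaLibrary,
    fastq_dir: str | Path | None = None,
) -> CountMatrix:
    """Deconvolve every sample in a sheet into one :class:`CountMatrix`."""
    matcher = BarcodeMatcher(library)
    cols: dict[str, pd.Series] = {}
    tallies: dict[str, dict[str, int]] = {}
    for sample in sheet.samples:
        path = Path(sample.fastq_path)
        if fastq_dir is not None and not path.is_absolute():
            path = Path(fastq_dir) / path
        counts, t = count_sample(path, library, matcher=matcher)
        cols[sample.sample_id] = counts
        tallies[sample.sample_id] = t
    matrix = CountMatrix(pd.DataFrame(cols), tallies)
    matrix.validate_against(library)
    return matrix
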