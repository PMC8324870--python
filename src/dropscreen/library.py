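"""shRNA library manifests, sample sheets and count matrices.

A pooled screen is described by three flat-file artifacts:

* a **library manifest** (TSV) listing every hairpin with its 18-nt
  barcode, target gene symbol and class (``targeting``,
  ``positive_control`` or ``negative_control``);
* a **sample sheet** (TSV) mapping each sequenced sample to a screen
  (one reference pool plus >= 1 tumor replicates per screen);
* a **count matrix** (TSV + JSON sidecar) of per-hairpin read counts,
  rows exactly matching the library, with per-sample read tallies
  (total / spacer-fail / extraction-fail / unassigned) kept out of the
  matrix so that the row count equals the library size N used by the
  gene-level statistics.

All files are tab-separated text with a mandatory header; gene symbols
are taken verbatim and compared case-sensitively.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

KLASSES = frozenset({"targeting", "positive_control", "negative_control"})
LIBRARY_TYPES = frozenset({"targeting_layout", "nontargeting_layout"})
ROLES = frozenset({"reference", "tumor_replicate"})
BARCODE_LENGTH = 18
_DNA = frozenset("ACGT")

_MANIFEST_COLUMNS = ("hairpin_id", "barcode", "gene", "class")
_SHEET_COLUMNS = ("sample_id", "screen_id", "role", "replicate_index", "fastq_path")

#: tally keys attached to every deconvolved sample
TALLY_KEYS = ("total_reads", "spacer_fail", "extraction_fail", "unassigned")


@dataclass(frozen=True)
class Hairpin:
    """One library entry: a hairpin, its barcode and its target gene."""

    hairpin_id: str
    barcode: str
    gene: str
    klass: str


class ShrnaLibrary:
    """Validated, ordered collection of :class:`Hairpin` entries.

    Parameters
    ----------
    entries
        Hairpins in manifest order. Barcodes and hairpin ids must be
        unique; for the targeting layout every barcode must be an
        18-nt ACGT string. A gene symbol may not mix classes (control
        genes carry control classes for every one of their hairpins).
    library_type
        ``targeting_layout`` (barcode at read positions 23-40, behind
        the spacer) or ``nontargeting_layout`` (barcode at 1-18).
    """

    def __init__(self, entries: Iterable[Hairpin], library_type: str = "targeting_layout"):
        entries = tuple(entries)
        if library_type not in LIBRARY_TYPES:
            raise ValidationError(f"unknown library_type {library_type!r}")
        if not entries:
            raise ValidationError("library has no entries")
        seen_ids: set[str] = set()
        seen_bc: set[str] = set()
        gene_klass: dict[str, str] = {}
        for e in entries:
            if e.hairpin_id in seen_ids:
                raise ValidationError(f"duplicate hairpin_id {e.hairpin_id!r}")
            if e.barcode in seen_bc:
                raise ValidationError(f"duplicate barcode {e.barcode!r}")
            if not e.gene:
                raise ValidationError(f"hairpin {e.hairpin_id!r} has empty gene symbol")
            if e.klass not in KLASSES:
                raise ValidationError(f"hairpin {e.hairpin_id!r} has unknown class {e.klass!r}")
            if len(e.barcode) != BARCODE_LENGTH:
                raise ValidationError(
                    f"hairpin {e.hairpin_id!r}: barcode length {len(e.barcode)} != {BARCODE_LENGTH}"
                )
            if not set(e.barcode) <= _DNA:
                raise ValidationError(f"hairpin {e.hairpin_id!r}: barcode has non-ACGT characters")
            prev = gene_klass.setdefault(e.gene, e.klass)
            if prev != e.klass:
                raise ValidationError(f"gene {e.gene!r} mixes classes {prev!r} and {e.klass!r}")
            seen_ids.add(e.hairpin_id)
            seen_bc.add(e.barcode)
        self.entries = entries
        self.library_type = library_type

    # -- basic views -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n(self) -> int:
        """Total number of hairpins N (the RSA population size)."""
        return len(self.entries)

    @property
    def hairpin_ids(self) -> list[str]:
        return [e.hairpin_id for e in self.entries]

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    def gene_of(self) -> dict[str, str]:
        """hairpin_id -> gene symbol."""
        return {e.hairpin_id: e.gene for e in self.entries}

    def klass_of_gene(self) -> dict[str, str]:
        """gene symbol -> class (uniform per gene by validation)."""
        return {e.gene: e.klass for e in self.entries}

    def genes(self, klass: str | None = None) -> list[str]:
        """Distinct gene symbols in manifest order, optionally by class."""
        out: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            if klass is not None and e.klass != klass:
                continue
            if e.gene not in seen:
                seen.add(e.gene)
                out.append(e.gene)
        return out

    def hairpins_of(self, gene: str) -> list[Hairpin]:
        return [e for e in self.entries if e.gene == gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hairpin_id": self.hairpin_ids,
                "barcode": self.barcodes,
                "gene": [e.gene for e in self.entries],
                "class": [e.klass for e in self.entries],
            }
        )


def load_library(path: str | Path, library_type: str = "targeting_layout") -> ShrnaLibrary:
    """Read a library manifest TSV.

    The header must contain ``hairpin_id  barcode  gene  class``.
    Malformed rows raise :class:`ParseError` naming the line number;
    duplicate barcodes/ids raise :class:`ValidationError`.
    """
    path = Path(path)
    entries: list[Hairpin] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty manifest") from None
        missing = [c for c in _MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: header missing columns {missing}")
        idx = {c: header.index(c) for c in _MANIFEST_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}")
            entries.append(
                Hairpin(
                    hairpin_id=row[idx["hairpin_id"]].strip(),
                    barcode=row[idx["barcode"]].strip().upper(),
                    gene=row[idx["gene"]].strip(),
                    klass=row[idx["class"]].strip(),
                )
            )
    return ShrnaLibrary(entries, library_type=library_type)


def write_library(library: ShrnaLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    screen_id: str
    role: str  # reference | tumor_replicate
    replicate_index: int = 0
    fastq_path: str = ""


class SampleSheet:
    """Samples of one or more screens; exactly one reference per screen."""

    def __init__(self, samples: Iterable[Sample]):
        samples = tuple(samples)
        if not samples:
            raise ValidationError("sample sheet is empty")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in sample sheet")
        for s in samples:
            if s.role not in ROLES:
                raise ValidationError(f"sample {s.sample_id!r}: unknown role {s.role!r}")
        for screen in {s.screen_id for s in samples}:
            refs = [s for s in samples if s.screen_id == screen and s.role == "reference"]
            tums = [s for s in samples if s.screen_id == screen and s.role == "tumor_replicate"]
            if len(refs) != 1:
                raise ValidationError(f"screen {screen!r} has {len(refs)} reference samples, expected 1")
            if not tums:
                raise ValidationError(f"screen {screen!r} has no tumor replicates")
        self.samples = samples

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def screens(self) -> list[str]:
        out, seen = [], set()
        for s in self.samples:
            if s.screen_id not in seen:
                seen.add(s.screen_id)
                out.append(s.screen_id)
        return out

    def reference(self, screen_id: str) -> Sample:
        return next(s for s in self.samples if s.screen_id == screen_id and s.role == "reference")

    def tumors(self, screen_id: str) -> list[Sample]:
        return [
            s for s in self.samples if s.screen_id == screen_id and s.role == "tumor_replicate"
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.samples], columns=list(_SHEET_COLUMNS))


def load_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SHEET_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    samples = [
        Sample(
            sample_id=row["sample_id"],
            screen_id=row["screen_id"],
            role=row["role"],
            replicate_index=int(row.get("replicate_index", 0) or 0),
            fastq_path=str(row.get("fastq_path", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

class CountMatrix:
    """Per-hairpin read counts, one integer column per sample.

    ``counts`` is a DataFrame indexed by hairpin_id. ``tallies`` holds
    one dict per sample with keys ``total_reads``, ``spacer_fail``,
    ``extraction_fail`` and ``unassigned``; for count matrices that
    were never deconvolved from FASTQ (e.g. simulated in count-matrix
    mode) the fail tallies are zero and total_reads equals the column
    sum.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        tallies: Mapping[str, Mapping[str, int]] | None = None,
    ):
        if counts.shape[1] == 0:
            raise ValidationError("count matrix has no samples")
        if counts.shape[0] == 0:
            raise ValidationError("count matrix has no hairpins")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        counts = counts.astype("int64")
        if tallies is None:
            tallies = {
                c: {
                    "total_reads": int(counts[c].sum()),
                    "spacer_fail": 0,
                    "extraction_fail": 0,
                    "unassigned": 0,
                }
                for c in counts.columns
            }
        tallies = {str(k): dict(v) for k, v in tallies.items()}
        if set(tallies) != set(counts.columns):
            raise ValidationError("tally samples do not match count columns")
        for sample, t in tallies.items():
            assigned = int(counts[sample].sum())
            expect = assigned + t["spacer_fail"] + t["extraction_fail"] + t["unassigned"]
            if t["total_reads"] != expect:
                raise ValidationError(
                    f"sample {sample!r}: total_reads {t['total_reads']} != "
                    f"assigned+fails+unassigned {expect}"
                )
        self.counts = counts
        self.tallies = tallies

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def assigned_total(self, sample: str) -> int:
        """Assigned reads for a sample (the normalization denominator)."""
        return int(self.counts[sample].sum())

    def validate_against(self, library: ShrnaLibrary) -> None:
        if list(self.counts.index) != library.hairpin_ids:
            raise ValidationError("count matrix rows do not match library entries")

    def __eq__(self, other: object) -> bool:  # round-trip identity
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.tallies == other.tallies
        )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts TSV (first column ``hairpin_id``) + JSON tally sidecar."""
    path = Path(path)
    out = matrix.counts.copy()
    out.insert(0, "hairpin_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    _sidecar(path).write_text(json.dumps({"tallies": matrix.tallies}, indent=1, sort_keys=True))


def read_counts(path: str | Path) -> CountMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "hairpin_id" not in df.columns:
        raise ParseError(f"{path}: missing hairpin_id column")
    df = df.set_index("hairpin_id")
    df.index.name = None
    tallies = None
    side = _sidecar(path)
    if side.exists():
        tallies = json.loads(side.read_text())["tallies"]
    return CountMatrix(df, tallies)
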