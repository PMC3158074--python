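"""Readers and writers for the file formats the pipeline touches.

Supported formats
-----------------
* GPR dialect — GenePix-results-style tab-separated files with an ATF-style
  header block.  Required columns: ``Block``, ``Column``, ``Row``, ``ID`` and
  the four fluorescence columns ``F635 Median`` / ``B635 Median`` (red, Cy5
  DNA channel) and ``F532 Median`` / ``B532 Median`` (green, Cy3 protein
  channel).  An optional ``Flags`` column carries spot quality; negative
  flags are retained but marked on the record.
* FASTA — via Biopython; sequences are canonicalized to uppercase.
* PWM — plain text, one row per motif position, four tab-separated columns
  A, C, G, T.  ``#``-prefixed directives may set ``name=`` and
  ``low_threshold=``.
* Results tables — tab-separated with a mandatory header line (pandas).

All readers transparently decompress ``.gz`` paths.  Parsing is
locale-independent: the decimal separator is always a dot.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError
from .motif_scan import MotifMatrix

GPR_COLUMNS = [
    "Block",
    "Column",
    "Row",
    "ID",
    "Name",
    "F635 Median",
    "B635 Median",
    "F532 Median",
    "B532 Median",
    "Flags",
]

_REQUIRED_GPR = [
    "Block",
    "Column",
    "Row",
    "ID",
    "F635 Median",
    "B635 Median",
    "F532 Median",
    "B532 Median",
]


@dataclass
class SpotRecord:
    """One spot's two-channel fluorescence with slide/sequence identity.

    Coordinates are 1-based (GenePix convention).  The red channel (635 nm)
    measures labelled DNA, the green channel (532 nm) the antibody-detected
    protein.
    """

    slide_id: str
    block: int
    column: int
    row: int
    sequence_id: str
    red_fg: float
    red_bg: float
    green_fg: float
    green_bg: float
    flag: int = 0

    def __post_init__(self) -> None:
        if not self.sequence_id:
            raise FormatError("sequence_id must be non-empty")
        for name in ("red_fg", "red_bg", "green_fg", "green_bg"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be non-negative")

    @property
    def is_flagged(self) -> bool:
        """True when the scanner marked the spot bad (negative flag)."""
        return self.flag < 0


@dataclass
class Slide:
    """Ordered spots of one slide plus its experimental group label."""

    slide_id: str
    group: str
    spots: list[SpotRecord] = field(default_factory=list)

    def sequence_ids(self) -> set[str]:
        return {s.sequence_id for s in self.spots}


@dataclass
class ArraySet:
    """Slides of one experiment; all slides share the same sequence universe."""

    slides: list[Slide] = field(default_factory=list)

    def validate(self) -> None:
        if not self.slides:
            return
        universe = self.slides[0].sequence_ids()
        for slide in self.slides[1:]:
            if slide.sequence_ids() != universe:
                raise FormatError(
                    f"slide '{slide.slide_id}' does not share the sequence "
                    "universe of the first slide"
                )
        for slide in self.slides:
            counts = pd.Series([s.sequence_id for s in slide.spots]).value_counts()
            if counts.nunique() > 1:
                raise FormatError(
                    f"slide '{slide.slide_id}' has non-uniform replicate counts"
                )

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.slides]

    def sequence_ids(self) -> list[str]:
        return sorted(self.slides[0].sequence_ids()) if self.slides else []


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, stored uppercase."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.sequence:
            raise FormatError(f"sequence '{self.id}' is empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"sequence '{self.id}' contains non-DNA characters {sorted(bad)}"
            )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# GPR dialect


def read_gpr(path, slide_id: str | None = None, group: str = "") -> list[SpotRecord]:
    """Parse a GPR-dialect file into spot records.

    The file may start with an ATF header (``ATF<tab>1.0`` then a line giving
    the count of optional header records) or directly with the column header
    line.  Rows with negative flags are retained; :attr:`SpotRecord.is_flagged`
    marks them.
    """
    path = Path(path)
    if slide_id is None:
        slide_id = path.name.removesuffix(".gz").removesuffix(".gpr")
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    idx = 0
    if lines[0].split("\t")[0].strip().upper() == "ATF":
        try:
            n_optional = int(lines[1].split("\t")[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed ATF header") from exc
        idx = 2 + n_optional
    if idx >= len(lines):
        raise FormatError(f"{path}: no column header line")
    header = [c.strip().strip('"') for c in lines[idx].split("\t")]
    col_of = {name: i for i, name in enumerate(header)}
    for required in _REQUIRED_GPR:
        if required not in col_of:
            raise FormatError(f"{path}: missing required column '{required}'")
    has_flags = "Flags" in col_of

    records: list[SpotRecord] = []
    for lineno, line in enumerate(lines[idx + 1 :], start=idx + 2):
        if not line.strip():
            continue
        cells = [c.strip().strip('"') for c in line.split("\t")]
        if len(cells) < len(header):
            raise FormatError(f"{path}:{lineno}: row has fewer cells than header")

        def _num(col: str, lineno=lineno, cells=cells) -> float:
            raw = cells[col_of[col]]
            try:
                return float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {raw!r} in column '{col}'"
                ) from exc

        records.append(
            SpotRecord(
                slide_id=slide_id,
                block=int(_num("Block")),
                column=int(_num("Column")),
                row=int(_num("Row")),
                sequence_id=cells[col_of["ID"]],
                red_fg=_num("F635 Median"),
                red_bg=_num("B635 Median"),
                green_fg=_num("F532 Median"),
                green_bg=_num("B532 Median"),
                flag=int(_num("Flags")) if has_flags else 0,
            )
        )
    return records


def _fmt(x: float) -> str:
    """Format a float so that read_gpr round-trips it exactly."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_gpr(records: Sequence[SpotRecord], path) -> None:
    """Write spot records in the GPR dialect (deterministic column order)."""
    with _open_text(path, "wt") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"2\t{len(GPR_COLUMNS)}\n")
        fh.write('"Type=GenePix Results 3"\n')
        fh.write('"Producer=pbmkit"\n')
        fh.write("\t".join(GPR_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        str(r.block),
                        str(r.column),
                        str(r.row),
                        r.sequence_id,
                        r.sequence_id,
                        _fmt(r.red_fg),
                        _fmt(r.red_bg),
                        _fmt(r.green_fg),
                        _fmt(r.green_bg),
                        str(r.flag),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file; sequences are uppercased."""
    with _open_text(path) as fh:
        records = [
            SequenceRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (
                _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
                for r in records
            ),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# Plain-text PWM


def read_pwm(
    path, name: str | None = None, low_threshold: float | None = None
) -> MotifMatrix:
    """Read a plain-text PWM: rows = positions, columns = A, C, G, T.

    ``# name=...`` and ``# low_threshold=...`` directive lines may set the
    motif name and classification threshold; explicit arguments win.
    """
    path = Path(path)
    file_name = path.name.removesuffix(".gz")
    for ext in (".pwm", ".txt", ".tsv", ".mat"):
        file_name = file_name.removesuffix(ext)
    parsed_name: str | None = None
    parsed_threshold: float | None = None
    rows: list[list[float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                directive = line.lstrip("#").strip()
                if "=" in directive:
                    key, _, value = directive.partition("=")
                    key = key.strip().lower()
                    if key == "name":
                        parsed_name = value.strip()
                    elif key == "low_threshold":
                        parsed_threshold = float(value)
                continue
            cells = line.split()
            if not rows and [c.upper() for c in cells] == list("ACGT"):
                continue  # optional column-header line before any data
            if len(cells) != 4:
                raise FormatError(
                    f"{path}:{lineno}: PWM rows must have 4 columns, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric PWM entry") from None
    if not rows:
        raise FormatError(f"{path}: PWM file contains no rows")
    return MotifMatrix(
        name=name or parsed_name or file_name,
        scores=np.array(rows, dtype=float),
        low_threshold=low_threshold if low_threshold is not None else parsed_threshold,
    )


def write_pwm(pwm: MotifMatrix, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# name={pwm.name}\n")
        if pwm.low_threshold is not None:
            fh.write(f"# low_threshold={pwm.low_threshold:g}\n")
        fh.write("A\tC\tG\tT\n")
        for row in pwm.scores:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Tab-separated results tables


def read_table(path) -> pd.DataFrame:
    """Read a tab-separated results table with a mandatory header line."""
    df = pd.read_csv(path, sep="\t")
    if df.columns.str.match(r"^Unnamed").all():
        raise FormatError(f"{path}: results table lacks a header line")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_id_list(path) -> list[str]:
    """Read a one-ID-per-line text file (case folded for matching)."""
    with _open_text(path) as fh:
        return [line.strip().casefold() for line in fh if line.strip()]
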