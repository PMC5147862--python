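"""Map structure chains onto curated multiple-sequence-alignment columns.

The interaction matrix lives on a shared coordinate frame: alignment columns
labeled with reference residue numbers (HRAS numbering on the RAS side, CRAF
numbering on the effector side). This module parses user-supplied,
structure-synchronized alignments (aligned FASTA or Clustal), places each
parsed chain onto its alignment row, and numbers the columns from the
reference row. The alignment is treated as ground truth — curation happened
upstream, nothing is re-aligned here.

Columns are 0-based internally; reports use 1-based indices and reference
labels.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from Bio import AlignIO

from raseff.errors import (
    DuplicateRowError,
    RaggedAlignmentError,
    SequenceMismatchError,
)
from raseff.structure_io import Residue, chain_sequence

logger = logging.getLogger(__name__)


@dataclass
class Alignment:
    """Ordered rows of equal-length gapped sequences."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise RaggedAlignmentError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise RaggedAlignmentError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def row(self, name: str) -> str:
        if name not in self.rows:
            raise KeyError(f"no alignment row named {name!r}; have {sorted(self.rows)}")
        return self.rows[name]


@dataclass
class AlignmentMap:
    """Residue ↔ alignment column ↔ reference numbering for one chain.

    ``residue_to_column`` maps (author residue number, icode) to a 0-based
    alignment column; ``column_to_reference`` maps columns to reference
    residue numbers (defined only where the reference row is non-gap).
    """

    protein_name: str
    residue_to_column: dict[tuple[int, str], int]
    column_to_reference: dict[int, int] = field(default_factory=dict)

    def reference_of(self, residue_key: tuple[int, str]) -> int | None:
        col = self.residue_to_column.get(residue_key)
        if col is None:
            return None
        return self.column_to_reference.get(col)


def parse_alignment(text: str) -> Alignment:
    """Parse aligned FASTA ('>' first) or Clustal text into an Alignment.

    Sequences are upper-cased and '.' gap characters normalized to '-'.
    """
    stripped = text.lstrip()
    fmt = "fasta" if stripped.startswith(">") else "clustal"
    try:
        msa = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        # Biopython reports ragged rows (and other shape problems) as ValueError
        raise RaggedAlignmentError(f"cannot read {fmt} alignment: {exc}") from exc
    rows: dict[str, str] = {}
    for record in msa:
        if record.id in rows:
            raise DuplicateRowError(f"duplicate alignment row name {record.id!r}")
        rows[record.id] = str(record.seq).upper().replace(".", "-")
    return Alignment(rows=rows)


def reference_numbering(
    alignment: Alignment, reference_row: str, start_number: int
) -> dict[int, int]:
    """Number non-gap columns of the reference row consecutively.

    Gap columns of the reference row carry no number (see
    :func:`column_labels` for insertion-suffix labels).
    """
    row = alignment.row(reference_row)
    numbering: dict[int, int] = {}
    n = start_number
    for col, ch in enumerate(row):
        if ch != "-":
            numbering[col] = n
            n += 1
    return numbering


def _suffix(i: int) -> str:
    # 0->A, 25->Z, 26->AA ... (insertion-code style)
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def column_labels(
    alignment: Alignment, reference_row: str, start_number: int
) -> list[str]:
    """Human-readable label per column: reference number, or, for columns
    where the reference row is gapped, the nearest preceding number plus an
    insertion suffix ("31A", "31B", ...)."""
    row = alignment.row(reference_row)
    numbering = reference_numbering(alignment, reference_row, start_number)
    labels: list[str] = []
    last = start_number - 1
    run = 0
    for col in range(len(row)):
        if col in numbering:
            last = numbering[col]
            run = 0
            labels.append(str(last))
        else:
            labels.append(f"{last}{_suffix(run)}")
            run += 1
    return labels


def _best_offset(seq: str, ungapped: str) -> tuple[int, int, int]:
    """Slide `seq` along `ungapped` (overhangs allowed); return the offset
    maximizing exact matches, with (offset, matches, overlap)."""
    best = (0, -1, 0)
    for offset in range(-len(seq) + 1, len(ungapped)):
        lo = max(0, -offset)
        hi = min(len(seq), len(ungapped) - offset)
        if hi <= lo:
            continue
        matches = sum(
            1 for i in range(lo, hi) if seq[i] == ungapped[i + offset]
        )
        if matches > best[1]:
            best = (offset, matches, hi - lo)
    return best


def map_chain(
    chain: tuple[Residue, ...],
    alignment: Alignment,
    row_name: str,
    reference_row: str | None = None,
    reference_start: int = 1,
    min_identity: float = 0.95,
) -> AlignmentMap:
    """Assign each chain residue to the alignment column of its row position.

    Matching is by exact ungapped substring (left-most placement if the
    sequence occurs more than once, with a warning). Failing that, the best
    sliding-overlap placement is accepted when its identity is at least
    `min_identity`; point mismatches are mapped anyway (logged), and
    residues overhanging the row — e.g. expression tags — are dropped with
    a warning.

    The returned map also carries column→reference numbering taken from
    `reference_row` (defaults to `row_name` itself) starting at
    `reference_start`.
    """
    row = alignment.row(row_name)
    # ungapped row characters with their source columns
    cols = [c for c, ch in enumerate(row) if ch != "-"]
    ungapped = "".join(row[c] for c in cols)
    seq = chain_sequence(chain)
    if not seq:
        raise SequenceMismatchError(f"chain for {row_name!r} has no residues")

    idx = ungapped.find(seq)
    if idx >= 0:
        if ungapped.find(seq, idx + 1) >= 0:
            logger.warning(
                "%s: sequence occurs more than once in row; using left-most match",
                row_name,
            )
        offset = idx
    else:
        offset, matches, overlap = _best_offset(seq, ungapped)
        identity = matches / overlap if overlap else 0.0
        if identity < min_identity:
            first_bad = next(
                (
                    chain[i]
                    for i in range(len(seq))
                    if 0 <= i + offset < len(ungapped)
                    and seq[i] != ungapped[i + offset]
                ),
                chain[0],
            )
            raise SequenceMismatchError(
                f"{row_name}: best placement identity {identity:.2f} < "
                f"{min_identity:.2f}; first conflicting residue "
                f"{first_bad.res_name} {first_bad.number}{first_bad.icode}"
            )
        logger.warning(
            "%s: inexact placement (identity %.1f%% over %d residues)",
            row_name,
            100 * identity,
            overlap,
        )

    residue_to_column: dict[tuple[int, str], int] = {}
    dropped = 0
    for i, res in enumerate(chain):
        j = i + offset
        if 0 <= j < len(cols):
            residue_to_column[res.key] = cols[j]
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "%s: dropped %d unmatched leading/trailing residues", row_name, dropped
        )

    ref_row = reference_row if reference_row is not None else row_name
    return AlignmentMap(
        protein_name=row_name,
        residue_to_column=residue_to_column,
        column_to_reference=reference_numbering(alignment, ref_row, reference_start),
    )


def alignment_table(
    alignment: Alignment, reference_row: str, start_number: int
):
    """Column ↔ reference table as a DataFrame (1-based column indices),
    one character column per alignment row. Write with ``to_csv(sep='\\t')``."""
    import pandas as pd

    labels = column_labels(alignment, reference_row, start_number)
    data = {
        "column_index": list(range(1, alignment.length + 1)),
        "reference_label": labels,
    }
    for name, seq in alignment.rows.items():
        data[name] = list(seq)
    return pd.DataFrame(data)
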