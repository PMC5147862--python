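"""Aggregate per-complex contacts into a cross-structure interaction matrix.

Rows are RAS positions in the common reference numbering (HRAS), columns are
effector positions (CRAF numbering); each cell accumulates evidence over all
analyzed complexes. Two counting modes exist: ``per-structure`` (default; a
cell gains +1 per complex showing at least one atom pair there — robust to
crystal-form redundancy) and ``atom-pairs`` (a cell sums atom pairs, giving
S5-figure-style depth). Four sub-matrices split the counts by the mm/ms/sm/ss
backbone/side-chain categories.

Dense blocks of high-count cells are the binding regions. They are detected
by thresholding and grouping cells that lie within a Chebyshev distance of
``1 + bridge`` of one another (8-connectivity when bridge = 0), discarding
tiny components, and ranking by total count — a formalization of calling
blocks on the heatmap by eye.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from raseff.alignment_map import AlignmentMap
from raseff.contact_engine import CATEGORIES, ContactRecord
from raseff.errors import EmptyInputError

MODES = ("per-structure", "atom-pairs")


@dataclass
class InteractionMatrix:
    row_labels: list[int]  # RAS reference numbers (HRAS numbering)
    col_labels: list[int]  # effector reference numbers (CRAF numbering)
    counts: np.ndarray
    category_counts: dict[str, np.ndarray]
    n_structures: int
    per_structure_presence: dict[tuple[int, int], frozenset[str]]
    mode: str = "per-structure"
    skip_report: list[dict] = field(default_factory=list)

    def cell(self, ras_ref: int, eff_ref: int) -> int:
        i = self.row_labels.index(ras_ref)
        j = self.col_labels.index(eff_ref)
        return int(self.counts[i, j])

    def to_frame(self, which: str | None = None) -> pd.DataFrame:
        data = self.counts if which is None else self.category_counts[which]
        return pd.DataFrame(data, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class Region:
    """One connected block of high-count cells, labeled R1, R2, ... by rank."""

    label: str
    cells: frozenset[tuple[int, int]]  # (row index, col index)
    row_span: tuple[int, int]  # inclusive reference-label range
    col_span: tuple[int, int]
    total_count: int

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("region must contain at least one cell")


def build_matrix(
    contacts_by_structure: dict[str, list[ContactRecord]],
    ras_maps: dict[str, AlignmentMap],
    eff_maps: dict[str, AlignmentMap],
    mode: str = "per-structure",
) -> InteractionMatrix:
    """Aggregate contacts from many complexes onto the reference frame.

    Every contact's residues are translated residue → alignment column →
    reference number through the structure's own AlignmentMaps; residues
    without a mapping (expression tags, disordered loops, columns where the
    reference row is gapped) are skipped and itemized in ``skip_report`` —
    they never create matrix rows. The matrix frame is the union of
    reference numbers over all supplied maps, so structure input order
    cannot affect the result.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not contacts_by_structure:
        raise EmptyInputError("no structures supplied")

    row_set: set[int] = set()
    col_set: set[int] = set()
    for m in ras_maps.values():
        row_set.update(m.column_to_reference.values())
    for m in eff_maps.values():
        col_set.update(m.column_to_reference.values())
    row_labels = sorted(row_set)
    col_labels = sorted(col_set)
    row_index = {r: i for i, r in enumerate(row_labels)}
    col_index = {c: j for j, c in enumerate(col_labels)}

    shape = (len(row_labels), len(col_labels))
    atom_counts = np.zeros(shape, dtype=int)
    cat_atom = {c: np.zeros(shape, dtype=int) for c in CATEGORIES}
    presence: dict[tuple[int, int], set[str]] = {}
    cat_presence = {c: {} for c in CATEGORIES}
    skip_report: list[dict] = []

    for sid in sorted(contacts_by_structure):
        ras_map, eff_map = ras_maps[sid], eff_maps[sid]
        for rec in contacts_by_structure[sid]:
            r_ref = ras_map.reference_of(rec.ras_residue[:2])
            e_ref = eff_map.reference_of(rec.effector_residue[:2])
            if r_ref is None or e_ref is None:
                side = "ras" if r_ref is None else "effector"
                residue = rec.ras_residue if r_ref is None else rec.effector_residue
                skip_report.append(
                    {
                        "structure_id": sid,
                        "side": side,
                        "residue": f"{residue[2]}{residue[0]}{residue[1]}",
                    }
                )
                continue
            ij = (row_index[r_ref], col_index[e_ref])
            atom_counts[ij] += rec.atom_pairs_total
            presence.setdefault(ij, set()).add(sid)
            for c in CATEGORIES:
                if rec.category_counts[c]:
                    cat_atom[c][ij] += rec.category_counts[c]
                    cat_presence[c].setdefault(ij, set()).add(sid)

    if mode == "per-structure":
        counts = np.zeros(shape, dtype=int)
        for ij, sids in presence.items():
            counts[ij] = len(sids)
        cats = {}
        for c in CATEGORIES:
            cats[c] = np.zeros(shape, dtype=int)
            for ij, sids in cat_presence[c].items():
                cats[c][ij] = len(sids)
    else:
        counts = atom_counts
        cats = cat_atom

    return InteractionMatrix(
        row_labels=row_labels,
        col_labels=col_labels,
        counts=counts,
        category_counts=cats,
        n_structures=len(contacts_by_structure),
        per_structure_presence={ij: frozenset(s) for ij, s in presence.items()},
        mode=mode,
        skip_report=sorted(
            skip_report, key=lambda d: (d["structure_id"], d["side"], d["residue"])
        ),
    )


def _as_counts(matrix) -> tuple[np.ndarray, list[int], list[int]]:
    if isinstance(matrix, InteractionMatrix):
        return matrix.counts, matrix.row_labels, matrix.col_labels
    arr = np.asarray(matrix)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def detect_regions(
    matrix,
    min_count: int = 2,
    min_cells: int = 3,
    bridge: int = 1,
) -> list[Region]:
    """Find dense interaction regions in a matrix (or plain count array).

    Cells with count >= ``min_count`` are grouped into connected components,
    two cells being connected when their Chebyshev distance is at most
    ``1 + bridge`` (bridge = 0 gives plain 8-connectivity; the default
    bridge = 1 lets blocks jump one sparse row/column, matching how blocks
    are read off a heatmap). Components smaller than ``min_cells`` are
    discarded; survivors are ranked by total count, descending, labeled
    R1, R2, ... Ties rank by (min row, min col) so output is deterministic.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts, row_labels, col_labels = _as_counts(matrix)
    hot = {(int(i), int(j)) for i, j in zip(*np.nonzero(counts >= min_count))}
    reach = 1 + bridge

    components: list[set[tuple[int, int]]] = []
    unseen = set(hot)
    while unseen:
        seed = unseen.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            ci, cj = frontier.pop()
            for di in range(-reach, reach + 1):
                for dj in range(-reach, reach + 1):
                    nb = (ci + di, cj + dj)
                    if nb in unseen:
                        unseen.discard(nb)
                        comp.add(nb)
                        frontier.append(nb)
        components.append(comp)

    scored = []
    for comp in components:
        if len(comp) < min_cells:
            continue
        total = int(sum(counts[ij] for ij in comp))
        min_ij = (min(i for i, _ in comp), min(j for _, j in comp))
        scored.append((total, min_ij, comp))
    scored.sort(key=lambda t: (-t[0], t[1]))

    regions = []
    for rank, (total, _, comp) in enumerate(scored, start=1):
        rows = [i for i, _ in comp]
        cols = [j for _, j in comp]
        regions.append(
            Region(
                label=f"R{rank}",
                cells=frozenset(comp),
                row_span=(row_labels[min(rows)], row_labels[max(rows)]),
                col_span=(col_labels[min(cols)], col_labels[max(cols)]),
                total_count=total,
            )
        )
    return regions


def hotspot_report(
    matrix: InteractionMatrix, regions: list[Region], top_k: int = 5
) -> dict:
    """Per-region hotspot summary plus matrix marginals.

    For each region: the ``top_k`` cells by count with reference labels,
    category breakdown and the fraction of structures contributing; and the
    dominant contact category of each region row (tie-break in the fixed
    order mm, ms, sm, ss). Marginals are per-row and per-column totals over
    the whole matrix.
    """
    out: dict = {"regions": [], "marginals": {}}
    for region in regions:
        cells = sorted(
            region.cells, key=lambda ij: (-int(matrix.counts[ij]), ij)
        )
        top_cells = []
        for ij in cells[:top_k]:
            i, j = ij
            presence = matrix.per_structure_presence.get(ij, frozenset())
            top_cells.append(
                {
                    "ras": matrix.row_labels[i],
                    "effector": matrix.col_labels[j],
                    "count": int(matrix.counts[ij]),
                    "categories": {
                        c: int(matrix.category_counts[c][ij]) for c in CATEGORIES
                    },
                    "fraction_structures": (
                        len(presence) / matrix.n_structures
                        if matrix.n_structures
                        else 0.0
                    ),
                }
            )
        row_dominant: dict[int, str] = {}
        for i in sorted({i for i, _ in region.cells}):
            sums = {
                c: int(
                    sum(
                        matrix.category_counts[c][ij]
                        for ij in region.cells
                        if ij[0] == i
                    )
                )
                for c in CATEGORIES
            }
            row_dominant[matrix.row_labels[i]] = max(
                CATEGORIES, key=lambda c: (sums[c], -CATEGORIES.index(c))
            )
        out["regions"].append(
            {
                "label": region.label,
                "row_span": list(region.row_span),
                "col_span": list(region.col_span),
                "total_count": region.total_count,
                "top_cells": top_cells,
                "row_dominant_category": row_dominant,
            }
        )
    out["marginals"] = {
        "row_totals": {
            int(r): int(t) for r, t in zip(matrix.row_labels, matrix.counts.sum(axis=1))
        },
        "col_totals": {
            int(c): int(t) for c, t in zip(matrix.col_labels, matrix.counts.sum(axis=0))
        },
    }
    return out


def matrix_bundle(
    matrix: InteractionMatrix, regions: list[Region], parameters: dict | None = None
) -> str:
    """Deterministic JSON bundle of counts, categories, regions and skips."""
    payload = {
        "mode": matrix.mode,
        "n_structures": matrix.n_structures,
        "row_labels": matrix.row_labels,
        "col_labels": matrix.col_labels,
        "counts": matrix.counts.tolist(),
        "categories": {c: matrix.category_counts[c].tolist() for c in CATEGORIES},
        "regions": [
            {
                "label": r.label,
                "row_span": list(r.row_span),
                "col_span": list(r.col_span),
                "total_count": r.total_count,
                "cells": sorted(map(list, r.cells)),
            }
            for r in regions
        ],
        "skip_report": matrix.skip_report,
        "parameters": parameters or {},
    }
    return json.dumps(payload, indent=1, sort_keys=True)
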