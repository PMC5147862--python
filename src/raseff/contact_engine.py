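"""Intermolecular residue-residue contacts at a heavy-atom distance cutoff.

A contact is any RAS-residue / effector-residue pair with at least one
heavy-atom pair at Euclidean distance <= cutoff (4.0 Å by default, boundary
inclusive). Each contact is decomposed into four atom-pair categories by
backbone/side-chain class on either side — mm, ms, sm, ss, first letter the
RAS atom — because backbone-mediated contacts (the intermolecular β-sheet in
the central recognition region) behave differently from side-chain ones. A
backbone N···O pair at <= 3.5 Å additionally flags the contact as
hydrogen-bond-like; the flag decorates records and never filters them.

The default search uses a k-d tree over the effector atoms; the brute-force
all-pairs scan is retained as the reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from raseff.structure_io import ComplexStructure, Residue

#: backbone heavy atoms; everything else (CB outward) is side chain
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: N···O distance (Å) below which a backbone pair is hydrogen-bond-like
HBOND_CUTOFF = 3.5

DEFAULT_CUTOFF = 4.0

CATEGORIES = ("mm", "ms", "sm", "ss")


def classify_atom(residue_name: str, atom_name: str) -> str:
    """'main_chain' for N/CA/C/O/OXT, 'side_chain' otherwise.

    Glycine simply contributes no side-chain atoms; unknown atom names fall
    into side_chain.
    """
    return "main_chain" if atom_name in MAIN_CHAIN_ATOMS else "side_chain"


@dataclass(frozen=True)
class ContactRecord:
    """One RAS-effector residue pair in contact.

    `category_counts` holds atom-pair counts keyed mm/ms/sm/ss where the
    first letter classifies the RAS atom and the second the effector atom.
    """

    structure_id: str
    ras_residue: tuple[int, str, str]  # (number, icode, res_name)
    effector_residue: tuple[int, str, str]
    min_distance: float
    atom_pairs_total: int
    category_counts: dict[str, int]
    mm_hbond_like: bool

    def __post_init__(self) -> None:
        if self.atom_pairs_total < 1:
            raise ValueError("contact record must contain at least one atom pair")
        if sum(self.category_counts.values()) != self.atom_pairs_total:
            raise ValueError("category counts must sum to atom_pairs_total")


def _category(ras_res: Residue, ras_atom_name: str, eff_res: Residue, eff_atom_name: str) -> str:
    a = "m" if classify_atom(ras_res.res_name, ras_atom_name) == "main_chain" else "s"
    b = "m" if classify_atom(eff_res.res_name, eff_atom_name) == "main_chain" else "s"
    return a + b


def _is_hbond_like(ras_name: str, eff_name: str, dist: float) -> bool:
    pair = {ras_name, eff_name}
    return pair == {"N", "O"} and dist <= HBOND_CUTOFF


def _records_from_pairs(
    structure_id: str,
    pair_hits: dict[tuple[int, int], list[tuple[str, str, float]]],
    ras: tuple[Residue, ...],
    eff: tuple[Residue, ...],
) -> list[ContactRecord]:
    records = []
    for (i, j), hits in pair_hits.items():
        rres, eres = ras[i], eff[j]
        counts = dict.fromkeys(CATEGORIES, 0)
        hbond = False
        for ras_name, eff_name, dist in hits:
            counts[_category(rres, ras_name, eres, eff_name)] += 1
            hbond = hbond or _is_hbond_like(ras_name, eff_name, dist)
        records.append(
            ContactRecord(
                structure_id=structure_id,
                ras_residue=(rres.number, rres.icode, rres.res_name),
                effector_residue=(eres.number, eres.icode, eres.res_name),
                min_distance=min(d for _, _, d in hits),
                atom_pairs_total=len(hits),
                category_counts=counts,
                mm_hbond_like=hbond,
            )
        )
    records.sort(key=lambda r: (r.ras_residue[:2], r.effector_residue[:2]))
    return records


def _flatten(chain: tuple[Residue, ...]):
    """(coords array, per-atom residue index, per-atom name) for one chain."""
    coords, res_idx, names = [], [], []
    for i, res in enumerate(chain):
        for atom in res.atoms:
            coords.append(atom.coord)
            res_idx.append(i)
            names.append(atom.name)
    return np.asarray(coords, dtype=float).reshape(-1, 3), res_idx, names


def compute_contacts(
    complex_structure: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactRecord]:
    """All intermolecular residue contacts at heavy-atom distance <= cutoff.

    Records are sorted by (RAS residue number, effector residue number).
    Empty chains yield an empty list.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    ras, eff = complex_structure.ras_chain, complex_structure.effector_chain
    rc, r_idx, r_names = _flatten(ras)
    ec, e_idx, e_names = _flatten(eff)
    if rc.size == 0 or ec.size == 0:
        return []
    tree = cKDTree(ec)
    pair_hits: dict[tuple[int, int], list[tuple[str, str, float]]] = {}
    for a, neighbours in enumerate(tree.query_ball_point(rc, cutoff)):
        for b in neighbours:
            dist = float(np.linalg.norm(rc[a] - ec[b]))
            key = (r_idx[a], e_idx[b])
            pair_hits.setdefault(key, []).append((r_names[a], e_names[b], dist))
    return _records_from_pairs(complex_structure.structure_id, pair_hits, ras, eff)


def compute_contacts_bruteforce(
    complex_structure: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactRecord]:
    """O(n²) all-atom-pairs reference implementation (the test oracle)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    ras, eff = complex_structure.ras_chain, complex_structure.effector_chain
    pair_hits: dict[tuple[int, int], list[tuple[str, str, float]]] = {}
    for (i, rres), (j, eres) in product(enumerate(ras), enumerate(eff)):
        for ra, ea in product(rres.atoms, eres.atoms):
            dist = float(
                np.linalg.norm(np.asarray(ra.coord) - np.asarray(ea.coord))
            )
            if dist <= cutoff:
                pair_hits.setdefault((i, j), []).append((ra.name, ea.name, dist))
    return _records_from_pairs(
        complex_structure.structure_id, pair_hits, ras, eff
    )


def contacts_table(records: list[ContactRecord]):
    """Contact list as a DataFrame matching the per-complex TSV layout."""
    import pandas as pd

    rows = [
        {
            "structure_id": r.structure_id,
            "ras_res": f"{r.ras_residue[2]}{r.ras_residue[0]}{r.ras_residue[1]}",
            "eff_res": f"{r.effector_residue[2]}{r.effector_residue[0]}{r.effector_residue[1]}",
            "min_dist": round(r.min_distance, 3),
            "total": r.atom_pairs_total,
            **{c: r.category_counts[c] for c in CATEGORIES},
            "mm_hbond_like": r.mm_hbond_like,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "ras_res",
            "eff_res",
            "min_dist",
            "total",
            *CATEGORIES,
            "mm_hbond_like",
        ],
    )
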