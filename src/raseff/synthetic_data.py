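"""Synthetic fixtures with machine-checkable ground truth.

Every stage of the pipeline is testable without downloading structures or
running an instrument:

* :func:`make_toy_complex` emits a syntactically valid two-chain PDB file in
  which chosen residue pairs realize exact inter-atomic distances between
  atoms of chosen backbone/side-chain classes, while every other inter-chain
  atom pair stays beyond twice the contact cutoff — so the planted contact
  list IS the expected output of the contact engine.
* :func:`make_titration` simulates polarization titrations from the
  quadratic binding model with known K_d, optionally adding seeded Gaussian
  noise as a stand-in for instrument error.
* :func:`make_planted_matrix` builds count matrices of disjoint rectangular
  blocks whose cell sets are the expected output of region detection.
* :func:`make_hotspot_fixture` chains the generators into a miniature
  multi-structure study whose interaction-matrix maximum is the planted
  central recognition block (RAS rows 37-39 × effector columns 66-69,
  backbone-dominated).

Toy residues use a minimal five-atom template (N, CA, C, O + CB) so that
both atom classes exist without rotamer chemistry; geometry is deliberately
unphysical (a toy), but distances are exact to 1e-3 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import seq3

from raseff.alignment_map import Alignment, map_chain
from raseff.contact_engine import DEFAULT_CUTOFF, compute_contacts
from raseff.errors import SpecConflictError
from raseff.kd_titration import TitrationCurve, model_signal
from raseff.reference_data import RECEPTOR_TOTAL_UM, titration_design
from raseff.structure_io import ComplexStructure, Residue, parse_structure

#: non-planted inter-chain atom pairs are guaranteed farther than this (Å)
DECOY_SEPARATION = 8.0

# residue-internal offsets (Å) of the atom cluster around its center
_TEMPLATE_OFFSETS = {
    "N": (0.5, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (-0.5, 0.0, 0.0),
    "O": (0.0, 0.5, 0.0),
    "CB": (0.0, -0.5, 0.0),
}

# which atom carries a planted contact, per side and class
_RAS_CONTACT_ATOM = {"m": "O", "s": "CB"}
_EFF_CONTACT_ATOM = {"m": "N", "s": "CB"}


@dataclass(frozen=True)
class PlantedContactSpec:
    """One residue pair to place at an exact inter-atom distance."""

    ras_residue_index: int  # 0-based along the RAS chain
    effector_residue_index: int
    distance: float  # Å between the two designated atoms
    category: str  # mm | ms | sm | ss (RAS class first)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise SpecConflictError("planted distance must be positive")
        if self.category not in ("mm", "ms", "sm", "ss"):
            raise SpecConflictError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class TitrationSpec:
    """Design of one simulated titration."""

    kd_true: float  # μM
    receptor_total: float = RECEPTOR_TOTAL_UM
    n_points: int = 24
    conc_range: tuple[float, float] = (0.05, 100.0)
    noise_sd: float = 0.0  # a.u., Gaussian on the signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_true <= 0:
            raise ValueError("kd_true must be positive")
        lo, hi = self.conc_range
        if not (0 < lo < hi):
            raise ValueError("conc_range must be positive and increasing")


def _format_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain_id: str,
    res_num: int,
    icode: str,
    coord: tuple[float, float, float],
    occupancy: float = 1.0,
    altloc: str = "",
) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name[:4]
    element = name[0]
    return (
        f"ATOM  {serial:5d} {padded}{altloc or ' '}{res_name:>3s} "
        f"{chain_id}{res_num:4d}{icode or ' '}   "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def complex_to_pdb(structure: ComplexStructure) -> str:
    """Serialize a parsed complex back to PDB text (both chains, TER, END)."""
    lines = []
    serial = 1
    for chain in (structure.ras_chain, structure.effector_chain):
        for res in chain:
            for atom in res.atoms:
                lines.append(
                    _format_atom_line(
                        serial,
                        atom.name,
                        res.res_name,
                        res.chain_id,
                        res.number,
                        res.icode,
                        atom.coord,
                        atom.occupancy,
                        atom.altloc,
                    )
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _residue_atoms(center: np.ndarray, contact: tuple[str, np.ndarray] | None):
    """Atom name → coordinate for one toy residue; `contact` optionally
    pins one named atom to an absolute position."""
    atoms = {
        name: center + np.asarray(off) for name, off in _TEMPLATE_OFFSETS.items()
    }
    if contact is not None:
        name, pos = contact
        atoms[name] = np.asarray(pos, dtype=float)
    return atoms


def make_toy_complex(
    specs: list[PlantedContactSpec],
    chain_lengths: tuple[int, int],
    ras_seq: str | None = None,
    eff_seq: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[str, list[dict]]:
    """Two-chain toy PDB text with planted contacts, plus its ground truth.

    Decoy residues sit on two rails 40 Å apart; each planted pair is moved
    to its own contact site where the two designated atoms face each other
    across exactly ``spec.distance`` (±1e-3 Å) while all remaining
    inter-chain atom pairs stay farther than ``DECOY_SEPARATION``. The
    ground-truth list enumerates every residue pair that must be found at
    the given cutoff, with its category count and hydrogen-bond flag.
    """
    n_ras, n_eff = chain_lengths
    ras_seq = ras_seq or "A" * n_ras
    eff_seq = eff_seq or "A" * n_eff
    if len(ras_seq) != n_ras or len(eff_seq) != n_eff:
        raise SpecConflictError("sequence length must match chain length")

    ras_site: dict[int, PlantedContactSpec] = {}
    eff_site: dict[int, PlantedContactSpec] = {}
    for spec in specs:
        if not (0 <= spec.ras_residue_index < n_ras):
            raise SpecConflictError(
                f"ras index {spec.ras_residue_index} outside chain of {n_ras}"
            )
        if not (0 <= spec.effector_residue_index < n_eff):
            raise SpecConflictError(
                f"effector index {spec.effector_residue_index} outside chain of {n_eff}"
            )
        if spec.ras_residue_index in ras_site or spec.effector_residue_index in eff_site:
            raise SpecConflictError(
                "a residue cannot participate in two planted contacts"
            )
        ras_site[spec.ras_residue_index] = spec
        eff_site[spec.effector_residue_index] = spec

    site_of = {id(s): k for k, s in enumerate(specs)}

    def _chain_positions(n: int, x_rail: float, planted: dict[int, PlantedContactSpec], side: str):
        residues = []
        for i in range(n):
            if i in planted:
                spec = planted[i]
                k = site_of[id(spec)]
                y = -30.0 * (k + 1)
                # arm length keeps the contact atom > DECOY_SEPARATION from
                # every non-partner atom even for short planted distances
                arm = max(6.0, DECOY_SEPARATION + 1.0 - spec.distance)
                half = spec.distance / 2.0
                sign = -1.0 if side == "ras" else 1.0
                center = np.array([sign * (half + arm), y, 0.0])
                cls = spec.category[0] if side == "ras" else spec.category[1]
                atom_name = (
                    _RAS_CONTACT_ATOM[cls] if side == "ras" else _EFF_CONTACT_ATOM[cls]
                )
                contact = (atom_name, np.array([sign * half, y, 0.0]))
            else:
                center = np.array([x_rail, 10.0 * i, 0.0])
                contact = None
            residues.append(_residue_atoms(center, contact))
        return residues

    ras_atoms = _chain_positions(n_ras, -20.0, ras_site, "ras")
    eff_atoms = _chain_positions(n_eff, +20.0, eff_site, "eff")

    lines = []
    serial = 1
    for chain_id, seq, chain_atoms in (("A", ras_seq, ras_atoms), ("B", eff_seq, eff_atoms)):
        for i, atoms in enumerate(chain_atoms):
            res_name = seq3(seq[i]).upper()
            for name in _TEMPLATE_OFFSETS:
                lines.append(
                    _format_atom_line(
                        serial, name, res_name, chain_id, i + 1, "", tuple(atoms[name])
                    )
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    ground_truth = []
    for spec in sorted(specs, key=lambda s: (s.ras_residue_index, s.effector_residue_index)):
        if spec.distance > cutoff:
            continue
        ras_atom = _RAS_CONTACT_ATOM[spec.category[0]]
        eff_atom = _EFF_CONTACT_ATOM[spec.category[1]]
        ground_truth.append(
            {
                "ras_residue": (
                    spec.ras_residue_index + 1,
                    "",
                    seq3(ras_seq[spec.ras_residue_index]).upper(),
                ),
                "effector_residue": (
                    spec.effector_residue_index + 1,
                    "",
                    seq3(eff_seq[spec.effector_residue_index]).upper(),
                ),
                "min_distance": spec.distance,
                "category_counts": {
                    c: (1 if c == spec.category else 0) for c in ("mm", "ms", "sm", "ss")
                },
                "mm_hbond_like": (
                    spec.category == "mm"
                    and {ras_atom, eff_atom} == {"N", "O"}
                    and spec.distance <= 3.5
                ),
            }
        )
    return pdb_text, ground_truth


def make_titration(
    spec: TitrationSpec, p_free: float = 0.0, p_bound: float = 1.0
) -> TitrationCurve:
    """Simulate one polarization titration from the quadratic binding model.

    ``noise_sd = 0`` returns exact model values; otherwise i.i.d. Gaussian
    noise from ``spec.seed`` is added (byte-identical for a fixed seed).
    """
    ligand = titration_design(spec.n_points, spec.conc_range)
    curve = TitrationCurve(
        receptor_total=spec.receptor_total, ligand_totals=ligand
    )
    signals = model_signal(curve, spec.kd_true, p_free, p_bound)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signals = signals + rng.normal(0.0, spec.noise_sd, size=signals.shape)
    curve.signals = np.asarray(signals, dtype=float)
    return curve


def write_titration_tsv(curve: TitrationCurve, path) -> None:
    """Write a titration as the (ligand_total_uM, polarization) TSV dialect."""
    import pandas as pd

    pd.DataFrame(
        {"ligand_total_uM": curve.ligand_totals, "polarization": curve.signals}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def make_planted_matrix(
    blocks: list[tuple[tuple[int, int], tuple[int, int], int]],
    shape: tuple[int, int],
    min_separation: int = 3,
) -> tuple[np.ndarray, list[set[tuple[int, int]]]]:
    """Count matrix that is zero outside rectangular planted blocks.

    ``blocks`` entries are ``((row_lo, row_hi), (col_lo, col_hi), count)``
    with inclusive spans. Blocks must fit the shape, not overlap, and keep a
    pairwise Chebyshev separation of at least ``min_separation`` so that
    default region detection cannot merge them. Returns the matrix and the
    ground-truth cell set of each block (in input order).
    """
    matrix = np.zeros(shape, dtype=int)
    truth: list[set[tuple[int, int]]] = []
    for (r0, r1), (c0, c1), count in blocks:
        if not (0 <= r0 <= r1 < shape[0] and 0 <= c0 <= c1 < shape[1]):
            raise SpecConflictError(f"block ({r0},{r1})x({c0},{c1}) outside {shape}")
        if count < 1:
            raise SpecConflictError("block count must be >= 1")
        cells = {(i, j) for i in range(r0, r1 + 1) for j in range(c0, c1 + 1)}
        for prev in truth:
            sep = min(
                max(abs(a - c), abs(b - d)) for a, b in prev for c, d in cells
            )
            if sep == 0:
                raise SpecConflictError("planted blocks overlap")
            if sep < min_separation:
                raise SpecConflictError(
                    f"planted blocks closer than min_separation={min_separation}"
                )
        matrix[r0 : r1 + 1, c0 : c1 + 1] = count
        truth.append(cells)
    return matrix, truth


# --- end-to-end hotspot fixture ------------------------------------------

#: toy chain sequences; planted RAS indices 2-4 land on reference 37-39,
#: planted effector indices 1-4 on reference 66-69
_RAS_TOY_SEQ = "WGEDSVH"  # reference numbering starts at 35
_EFF_TOY_SEQ = "MKLQRT"  # reference numbering starts at 65

#: per-structure planted contacts: (ras idx, eff idx, distance, category)
_HOTSPOT_PLANS = [
    [(2, 1, 3.0, "mm"), (3, 2, 3.2, "mm"), (4, 3, 3.4, "mm")],
    [(2, 1, 3.1, "mm"), (3, 2, 3.0, "mm"), (4, 3, 3.6, "ss")],
    [(2, 2, 3.3, "mm"), (3, 3, 3.2, "mm"), (4, 4, 3.8, "ss")],
]


def make_hotspot_fixture(n_structures: int = 3, cutoff: float = DEFAULT_CUTOFF):
    """Miniature multi-structure study emulating the central recognition block.

    Builds ``n_structures`` toy complexes whose planted contacts all map to
    RAS rows 37-39 × effector columns 66-69 with backbone-backbone contacts
    dominating rows 37 and 38, runs parsing, contact detection and alignment
    mapping, and returns ``(contacts_by_structure, ras_maps, eff_maps,
    expected)`` where ``expected`` records the planted block bounds.
    """
    ras_alignment = Alignment(rows={"HRAS": _RAS_TOY_SEQ})
    eff_alignment = Alignment(rows={"CRAF": _EFF_TOY_SEQ})

    contacts_by_structure = {}
    ras_maps = {}
    eff_maps = {}
    for k in range(n_structures):
        plan = _HOTSPOT_PLANS[k % len(_HOTSPOT_PLANS)]
        specs = [PlantedContactSpec(*p) for p in plan]
        pdb_text, _ = make_toy_complex(
            specs,
            (len(_RAS_TOY_SEQ), len(_EFF_TOY_SEQ)),
            ras_seq=_RAS_TOY_SEQ,
            eff_seq=_EFF_TOY_SEQ,
            cutoff=cutoff,
        )
        sid = f"toy{k + 1}"
        structure = parse_structure(pdb_text, "A", "B", structure_id=sid)
        contacts_by_structure[sid] = compute_contacts(structure, cutoff)
        ras_maps[sid] = map_chain(
            structure.ras_chain, ras_alignment, "HRAS", reference_start=35
        )
        eff_maps[sid] = map_chain(
            structure.effector_chain, eff_alignment, "CRAF", reference_start=65
        )
    expected = {
        "rows": (37, 39),
        "cols": (66, 69),
        "mm_dominated_rows": (37, 38),
    }
    return contacts_by_structure, ras_maps, eff_maps, expected
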