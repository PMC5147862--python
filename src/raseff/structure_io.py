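"""Parse two-chain RAS-effector complexes from PDB files.

The contact analysis needs only heavy-atom coordinates with author residue
numbering, so parsing reduces each selected chain to an ordered list of
amino-acid residues. Waters, ions, nucleotides and other non-polymer
heteroatoms are discarded; modified amino acids (e.g. selenomethionine) are
kept and translated to the parent one-letter code so alignment matching
works. Where a crystal records alternate conformations only one is kept:
the highest-occupancy conformer, ties broken by the lexicographically
smallest altloc identifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from raseff.errors import (
    AmbiguousChainError,
    ChainNotFoundError,
    MalformedInputError,
)

logger = logging.getLogger(__name__)

#: residue names treated as water and always removed
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB atom name, element, position in Å."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if len(self.coord) != 3 or not all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue with author numbering preserved."""

    chain_id: str
    number: int
    icode: str
    res_name: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_name} {self.number}{self.icode}: no atoms")

    @property
    def key(self) -> tuple[int, str]:
        """(author number, insertion code) — unique within a chain."""
        return (self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return one_letter_code(self.res_name)


@dataclass
class ComplexStructure:
    """A parsed two-chain complex: one RAS chain, one effector chain."""

    structure_id: str
    ras_chain: tuple[Residue, ...]
    effector_chain: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.ras_chain or not self.effector_chain:
            raise ValueError(f"{self.structure_id}: both chains must be non-empty")


def one_letter_code(res_name: str) -> str:
    """Parent one-letter code for a 3-letter residue name ('X' if unknown)."""
    info = gemmi.find_tabulated_residue(res_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_protein_residue(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    if res_name in WATER_NAMES or (info is not None and info.is_water()):
        return False
    return info is not None and info.is_amino_acid()


def _select_altloc(atoms: list[Atom]) -> Atom:
    # highest occupancy wins; tie -> smallest altloc id (blank sorts first)
    return max(atoms, key=lambda a: (a.occupancy, -ord(a.altloc or " ")))


def _convert_chain(chains: list[gemmi.Chain], chain_id: str) -> tuple[Residue, ...]:
    # PDB files list a chain's het residues after TER under the same id;
    # gemmi exposes them as separate Chain objects, so merge by name
    residues: list[Residue] = []
    for res in (r for chain in chains for r in chain):
        if not _is_protein_residue(res.name):
            continue
        by_name: dict[str, list[Atom]] = {}
        order: list[str] = []
        for atom in res:
            if atom.is_hydrogen():
                continue
            altloc = atom.altloc if atom.altloc not in ("\0",) else ""
            a = Atom(
                name=atom.name,
                element=atom.element.name,
                coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                occupancy=min(max(atom.occ, 0.0), 1.0),
                altloc=altloc,
            )
            if atom.name not in by_name:
                order.append(atom.name)
            by_name.setdefault(atom.name, []).append(a)
        if not by_name:
            continue
        atoms = tuple(_select_altloc(by_name[name]) for name in order)
        residues.append(
            Residue(
                chain_id=chain_id,
                number=res.seqid.num,
                icode=(res.seqid.icode or " ").strip(),
                res_name=res.name,
                atoms=atoms,
            )
        )
    return tuple(residues)


def _read_model(pdb_text: str, model_index: int) -> gemmi.Model:
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise MalformedInputError(f"cannot parse PDB text: {exc}") from exc
    if len(structure) == 0:
        raise MalformedInputError("PDB text contains no models")
    if model_index >= len(structure):
        raise MalformedInputError(
            f"model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    if sum(len(ch) for ch in model) == 0:
        raise MalformedInputError("selected model contains no residues")
    return model


def parse_structure(
    pdb_text: str,
    ras_chain_id: str,
    effector_chain_id: str,
    model_index: int = 0,
    structure_id: str = "",
) -> ComplexStructure:
    """Parse PDB text into a two-chain complex.

    Hydrogens and waters are removed, non-amino-acid heteroatoms (ligands,
    nucleotides, ions) are dropped, and exactly one conformer per atom is
    kept. Author residue numbering and insertion codes are preserved.

    Parameters
    ----------
    pdb_text : str
        Contents of a PDB file (ATOM/HETATM/MODEL records).
    ras_chain_id, effector_chain_id : str
        Chain identifiers of the RAS and the effector chain.
    model_index : int
        Which model to use for multi-model (NMR) files; default first.
    structure_id : str
        Free-form tag stored on the result (PDB code plus chain pair).
    """
    model = _read_model(pdb_text, model_index)
    chains: dict[str, list[gemmi.Chain]] = {}
    for ch in model:
        chains.setdefault(ch.name, []).append(ch)
    for cid in (ras_chain_id, effector_chain_id):
        if cid not in chains:
            raise ChainNotFoundError(
                f"chain {cid!r} not found; available: {sorted(chains)}"
            )
    ras = _convert_chain(chains[ras_chain_id], ras_chain_id)
    eff = _convert_chain(chains[effector_chain_id], effector_chain_id)
    if not ras:
        raise ChainNotFoundError(f"chain {ras_chain_id!r} has no amino-acid residues")
    if not eff:
        raise ChainNotFoundError(f"chain {effector_chain_id!r} has no amino-acid residues")
    sid = structure_id or f"{ras_chain_id}-{effector_chain_id}"
    return ComplexStructure(structure_id=sid, ras_chain=ras, effector_chain=eff)


def chain_sequence(residues: tuple[Residue, ...]) -> str:
    """One-letter sequence of a parsed chain in file order."""
    return "".join(r.one_letter for r in residues)


def _sequence_identity(query: str, target: str) -> float:
    """Best exact-overlap identity of `query` slid along `target`.

    Identity is matches over the shorter length; an exact substring scores
    1.0. No gaps are modeled — adequate for construct-vs-database matching
    where the chain is a contiguous fragment of the full-length protein.
    """
    short, long_ = (query, target) if len(query) <= len(target) else (target, query)
    if not short:
        return 0.0
    best = 0
    for offset in range(len(long_) - len(short) + 1):
        matches = sum(1 for a, b in zip(short, long_[offset:]) if a == b)
        best = max(best, matches)
    return best / len(short)


def enumerate_chain_pairs(
    pdb_text: str,
    ras_sequences: dict[str, str],
    effector_sequences: dict[str, str],
    model_index: int = 0,
    pairing: list[tuple[str, str]] | None = None,
    min_identity: float = 0.95,
) -> list[tuple[str, str, tuple[str, str]]]:
    """Find (RAS chain, effector chain) pairs in one model.

    A chain is assigned to a side when its extracted sequence is an exact
    substring of, or >= `min_identity` identical (over the shorter length)
    to, one of the provided reference sequences. Crystals often place more
    than one copy of the complex in the asymmetric unit, so every matching
    RAS chain is paired with every matching effector chain unless an
    explicit `pairing` list of chain-id tuples restricts the combinations
    (the curated biological pairs). Pairs are returned sorted by chain ids.

    Returns a list of ``(ras_chain_id, effector_chain_id, (ras_name,
    effector_name))``; an empty list when nothing matches.
    """
    model = _read_model(pdb_text, model_index)
    merged: dict[str, list[gemmi.Chain]] = {}
    for ch in model:
        merged.setdefault(ch.name, []).append(ch)
    ras_hits: dict[str, str] = {}
    eff_hits: dict[str, str] = {}
    for cid, group in merged.items():
        seq = chain_sequence(_convert_chain(group, cid))
        if not seq:
            continue
        for name, ref in ras_sequences.items():
            if seq in ref or _sequence_identity(seq, ref) >= min_identity:
                ras_hits[cid] = name
                break
        for name, ref in effector_sequences.items():
            if seq in ref or _sequence_identity(seq, ref) >= min_identity:
                eff_hits[cid] = name
                break
    both = sorted(set(ras_hits) & set(eff_hits))
    if both:
        raise AmbiguousChainError(
            f"chains {both} match both a RAS and an effector sequence"
        )
    pairs = [
        (r, e, (ras_hits[r], eff_hits[e]))
        for r in sorted(ras_hits)
        for e in sorted(eff_hits)
    ]
    if pairing is not None:
        wanted = set(pairing)
        pairs = [p for p in pairs if (p[0], p[1]) in wanted]
    elif len(ras_hits) > 1 and len(eff_hits) > 1:
        warnings.warn(
            "multiple RAS and effector chains found without a pairing list; "
            "returning all combinations for review",
            stacklevel=2,
        )
    return pairs
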