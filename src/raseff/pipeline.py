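"""End-to-end drivers for the two workflows.

``run_matrix_pipeline`` goes structure text → parse → alignment mapping →
contacts → aggregated interaction matrix → region detection → hotspot
report, writing deterministic TSV/JSON outputs. ``run_affinity_pipeline``
fits a batch of titration curves and assembles the fitted dissociation
constants into an effectors × RAS-proteins table. Both are plain library
functions; the numbered scripts under ``analysis/`` are their front end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from raseff import alignment_map, contact_engine, interaction_matrix, kd_titration
from raseff.errors import (
    DegenerateDataError,
    EmptyInputError,
    InsufficientDataError,
    RaseffError,
)
from raseff.reference_data import EFFECTOR_DOMAINS, RAS_PROTEINS, RECEPTOR_TOTAL_UM
from raseff.structure_io import parse_structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureEntry:
    """One complex to analyze: PDB text plus chain and alignment-row ids."""

    structure_id: str
    pdb_text: str
    ras_chain_id: str
    effector_chain_id: str
    ras_row: str
    effector_row: str
    model_index: int = 0


@dataclass
class RunConfig:
    """Tunable constants of the contact-mapping workflow."""

    cutoff: float = contact_engine.DEFAULT_CUTOFF  # Å, heavy-atom contact distance
    matrix_mode: str = "per-structure"
    min_count: int = 2  # region detection threshold
    min_cells: int = 3  # smallest reportable region
    bridge: int = 1  # sparse rows/columns a region may jump
    ras_reference_row: str = "HRAS"
    effector_reference_row: str = "CRAF"
    ras_reference_start: int = 1
    effector_reference_start: int = 1
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "matrix_mode": self.matrix_mode,
            "min_count": self.min_count,
            "min_cells": self.min_cells,
            "bridge": self.bridge,
            "ras_reference_row": self.ras_reference_row,
            "effector_reference_row": self.effector_reference_row,
            "ras_reference_start": self.ras_reference_start,
            "effector_reference_start": self.effector_reference_start,
            "top_k": self.top_k,
        }


def run_matrix_pipeline(
    entries: list[StructureEntry],
    ras_alignment_text: str,
    effector_alignment_text: str,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
):
    """Parse, map, count and aggregate; returns (matrix, regions, report).

    Any stage failure is re-raised with the structure id prepended so batch
    runs point at the offending file. When ``out_dir`` is given the matrix,
    per-category sub-matrices, per-complex contact tables, the JSON bundle
    and the hotspot report are written there (re-runs are byte-identical).
    """
    config = config or RunConfig()
    if not entries:
        raise EmptyInputError("no structures to analyze")

    ras_alignment = alignment_map.parse_alignment(ras_alignment_text)
    eff_alignment = alignment_map.parse_alignment(effector_alignment_text)

    contacts_by_structure = {}
    ras_maps = {}
    eff_maps = {}
    for entry in sorted(entries, key=lambda e: e.structure_id):
        try:
            structure = parse_structure(
                entry.pdb_text,
                entry.ras_chain_id,
                entry.effector_chain_id,
                model_index=entry.model_index,
                structure_id=entry.structure_id,
            )
            contacts_by_structure[entry.structure_id] = contact_engine.compute_contacts(
                structure, config.cutoff
            )
            ras_maps[entry.structure_id] = alignment_map.map_chain(
                structure.ras_chain,
                ras_alignment,
                entry.ras_row,
                reference_row=config.ras_reference_row,
                reference_start=config.ras_reference_start,
            )
            eff_maps[entry.structure_id] = alignment_map.map_chain(
                structure.effector_chain,
                eff_alignment,
                entry.effector_row,
                reference_row=config.effector_reference_row,
                reference_start=config.effector_reference_start,
            )
        except RaseffError as exc:
            raise type(exc)(f"[{entry.structure_id}] {exc}") from exc

    matrix = interaction_matrix.build_matrix(
        contacts_by_structure, ras_maps, eff_maps, mode=config.matrix_mode
    )
    regions = interaction_matrix.detect_regions(
        matrix,
        min_count=config.min_count,
        min_cells=config.min_cells,
        bridge=config.bridge,
    )
    report = interaction_matrix.hotspot_report(matrix, regions, top_k=config.top_k)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(out / "interaction_matrix.tsv", sep="\t")
        for cat in contact_engine.CATEGORIES:
            matrix.to_frame(cat).to_csv(out / f"matrix_{cat}.tsv", sep="\t")
        all_contacts = [
            rec for sid in sorted(contacts_by_structure) for rec in contacts_by_structure[sid]
        ]
        contact_engine.contacts_table(all_contacts).to_csv(
            out / "contacts.tsv", sep="\t", index=False
        )
        (out / "matrix_bundle.json").write_text(
            interaction_matrix.matrix_bundle(matrix, regions, config.as_dict())
        )
        (out / "hotspot_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
    return matrix, regions, report


def _ordered(names: list[str], canonical: tuple[str, ...]) -> list[str]:
    known = [n for n in canonical if n in names]
    extra = sorted(n for n in names if n not in canonical)
    return known + extra


def run_affinity_pipeline(
    manifest: list[dict],
    receptor_total: float = RECEPTOR_TOTAL_UM,
    out_dir: str | Path | None = None,
):
    """Fit a batch of titrations; returns (K_d table in μM, diagnostics).

    Manifest entries carry ``ras`` and ``effector`` names plus either a
    ``path`` to a (ligand_total_uM, polarization) TSV or an in-memory
    ``curve``. The output table is effector domains × RAS proteins in the
    canonical benchmark order (unknown names appended alphabetically).
    Curves that cannot be fitted leave their cell as NaN, with the reason
    recorded in the per-fit diagnostics.
    """
    if not manifest:
        raise EmptyInputError("empty titration manifest")

    results: dict[tuple[str, str], float] = {}
    diagnostics: list[dict] = []
    for entry in manifest:
        ras, effector = entry["ras"], entry["effector"]
        if "curve" in entry:
            curve = entry["curve"]
        else:
            path = Path(entry["path"])
            if not path.exists():
                raise FileNotFoundError(f"titration file not found: {path}")
            curve = kd_titration.read_titration_tsv(
                path, receptor_total, meta=(ras, effector)
            )
        diag = {"ras": ras, "effector": effector}
        try:
            fit = kd_titration.fit_titration(curve)
        except (InsufficientDataError, DegenerateDataError) as exc:
            diag.update({"status": "failed", "reason": str(exc)})
            results[(effector, ras)] = float("nan")
        else:
            diag.update(
                {
                    "status": "ok",
                    "kd_uM": fit.kd,
                    "stderr_kd_uM": fit.stderr_kd,
                    "p_free": fit.p_free,
                    "p_bound": fit.p_bound,
                    "residual_norm": fit.residual_norm,
                    "converged": fit.converged,
                }
            )
            results[(effector, ras)] = fit.kd
        diagnostics.append(diag)

    effectors = _ordered(sorted({e for e, _ in results}), EFFECTOR_DOMAINS)
    ras_names = _ordered(sorted({r for _, r in results}), RAS_PROTEINS)
    table = pd.DataFrame(
        [[results.get((e, r), np.nan) for r in ras_names] for e in effectors],
        index=effectors,
        columns=ras_names,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "kd_table_uM.tsv", sep="\t", float_format="%.6g")
        (out / "fit_diagnostics.json").write_text(
            json.dumps(diagnostics, indent=1, sort_keys=True)
        )
    return table, diagnostics
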