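#!/usr/bin/env python
"""Simulate the fluorescence-polarization titration battery.

Writes one noise-free titration TSV per RAS-effector pair of the benchmark
grid (quadratic binding model, receptor 1 μM, 24 log-spaced effector points
0.05-100 μM), plus three noisy replicates of the HRAS / CRAF-RB pair for the
reproducibility demonstration, and a manifest mapping files to pairs.

Outputs: results/titrations/*.tsv, results/titrations/manifest.json
"""

import json
from pathlib import Path

from raseff.reference_data import REFERENCE_KD_UM
from raseff.synthetic_data import TitrationSpec, make_titration, write_titration_tsv

OUT = Path(__file__).resolve().parent.parent / "results" / "titrations"
NOISE_SD = 0.02  # 2% of the unit signal span, per replicate curve
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest, replicates = [], []

    for effector in REFERENCE_KD_UM.index:
        for ras in REFERENCE_KD_UM.columns:
            kd = float(REFERENCE_KD_UM.loc[effector, ras])
            name = f"{ras}__{effector}.tsv".replace("/", "-")
            write_titration_tsv(make_titration(TitrationSpec(kd_true=kd)), OUT / name)
            manifest.append({"ras": ras, "effector": effector, "path": name,
                             "kd_true_uM": kd})

    for i in range(3):
        spec = TitrationSpec(
            kd_true=float(REFERENCE_KD_UM.loc["CRAF-RB", "HRAS"]),
            noise_sd=NOISE_SD, seed=SEED + i,
        )
        name = f"replicate{i + 1}__HRAS__CRAF-RB.tsv"
        write_titration_tsv(make_titration(spec), OUT / name)
        replicates.append({"ras": "HRAS", "effector": "CRAF-RB", "path": name})

    (OUT / "manifest.json").write_text(
        json.dumps({"titrations": manifest, "replicates": replicates},
                   indent=1, ensure_ascii=False)
    )
    print(f"wrote {len(manifest)} noise-free titrations and "
          f"{len(replicates)} noisy HRAS/CRAF-RB replicates to {OUT}")


if __name__ == "__main__":
    main()
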