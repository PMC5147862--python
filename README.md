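# raseff — RAS–effector interface mapping and affinity fitting

RAS-family GTPases (HRAS, KRAS, NRAS, RRAS1, RRAS2) signal by binding
effector proteins through their RAS-binding (RB) or RAS-association (RA)
domains. Understanding which interface residues drive recognition — and why
RAS and RRAS isoforms bind the same effectors with affinities orders of
magnitude apart — requires two kinds of evidence analyzed on a common frame:
many crystal/NMR structures of RAS–effector complexes, and equilibrium
binding constants measured under one consistent condition set. `raseff`
implements both workflows as a tested Python package for structural
biochemists:

1. **Interface contact mapping.** Each complex structure is parsed (PDB
   format), both chains are synchronized with curated multiple sequence
   alignments, and every intermolecular residue pair with a heavy-atom
   distance ≤ 4.0 Å is counted as a contact. Contacts from all structures
   are aggregated into an **interaction matrix** — rows indexed by RAS
   positions in HRAS numbering, columns by effector positions in CRAF
   numbering — and each contact is decomposed into the four
   main-chain/side-chain atom-pair categories (mm, ms, sm, ss), because
   backbone-mediated contacts (the intermolecular β-sheet of the central
   recognition site) carry different information than side-chain ones.
   Dense blocks of the matrix are detected as **hotspot regions** by
   thresholding and connected-component grouping.

2. **Dissociation constants from fluorescence polarization.** A fixed
   1 μM concentration of fluorescently labeled, GppNHp-loaded RAS is
   titrated with 0.05–100 μM effector domain. Because the receptor
   concentration is comparable to the K_d of tight binders, the fit uses
   the exact tight-binding (quadratic) solution of 1:1 mass action:

   the bound-complex concentration `x` solves
   `x² − (R_t + E_t + K_d)·x + R_t·E_t = 0`, so

   ```
   x = [(R_t + E_t + K_d) − √((R_t + E_t + K_d)² − 4·R_t·E_t)] / 2
   P(E_t) = P_free + (P_bound − P_free) · x / R_t
   ```

   and `fit_titration` estimates (K_d, P_free, P_bound) by least squares
   with K_d kept positive through a log parameterization.

A synthetic-data module generates every fixture the pipeline needs — toy
two-chain PDB complexes with planted contacts at exact distances, simulated
titrations with known K_d, and planted-block matrices — each with
machine-checkable ground truth, so the whole pipeline is testable without
downloading structures or running an instrument.

## Worked example

Fit a simulated titration of the tightest benchmark pair:

```python
from raseff import fit_titration
from raseff.synthetic_data import TitrationSpec, make_titration

curve = make_titration(TitrationSpec(kd_true=0.094))   # HRAS / CRAF-RB, μM
fit = fit_titration(curve)
print(f"K_d = {fit.kd:.4f} μM, converged={fit.converged}")
# K_d = 0.0940 μM, converged=True
```

The numbered drivers under `analysis/` run the two full workflows:

```sh
python analysis/01_simulate_titrations.py   # 25 titrations + replicates
python analysis/02_fit_affinities.py        # fitted K_d grid (μM)
python analysis/03_interface_hotspots.py    # interaction matrix + regions
```

`02_fit_affinities.py` prints the fitted effector × RAS grid, e.g.

```
           HRAS  KRAS  NRAS  RRAS1  RRAS2
CRAF-RB   0.094 0.142 0.048   2.29   4.09
...
worst relative recovery error over 25 pairs: 6.51e-10
HRAS/CRAF-RB noisy replicates: K_d = 0.089 ± 0.003 μM (generating value 0.094 μM)
```

— every K_d of the 25-pair benchmark grid is recovered from its noise-free
synthetic curve, and noisy replicates agree within the standard error.
`03_interface_hotspots.py` aggregates three toy complexes, detects one
region at RAS rows 37–39 × effector columns 66–68 with main-chain/main-chain
contacts dominating rows 37 and 38, and confirms it lies inside the
annotated span of the central recognition region R1 (rows 37–39, columns
66–69). All tables land under `results/`.

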