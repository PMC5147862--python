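# Methods

## Contact definition and categories

Two residues — one on the RAS chain, one on the effector chain — are in
contact when any pair of their heavy atoms lies within 4.0 Å (Euclidean,
boundary inclusive; the cutoff is the `cutoff` field of `RunConfig`).
Hydrogens are dropped at parse time: the criterion is a plain heavy-atom
distance, crystal structures mostly lack hydrogens anyway, and no
van-der-Waals correction is applied. Atoms named N, CA, C, O or OXT are
backbone ("main chain"); everything from CB outward is side chain, so each
atom pair falls into one of four categories (mm, ms, sm, ss; RAS side
first). A backbone N···O pair at ≤ 3.5 Å additionally marks the contact as
hydrogen-bond-like — a geometric proxy, not an energetic model, used only to
annotate records. The production search uses a k-d tree over effector atoms;
a brute-force all-pairs scan is kept in the package as the reference
implementation and the two are asserted identical in tests.

Parsing policies (all deterministic): one conformer per atom — highest
occupancy, ties to the lexicographically smallest altloc; waters, ions,
nucleotides and other non-amino-acid heteroatoms removed; modified amino
acids (e.g. selenomethionine) kept under their parent one-letter code;
multi-model files use a single selected model (default the first) since no
model-averaging convention is defined for contact counting; author residue
numbering and insertion codes preserved throughout. Crystals with several
complexes per asymmetric unit are expanded through
`enumerate_chain_pairs`, which assigns chains to the RAS or effector side
by sequence (exact substring or ≥ 95% identity over the shorter length) and
pairs them either via a user-curated pairing list (the default, since
biological pairs are a curation decision) or, advisorily, as all
combinations flagged for review.

## Alignment frame

The interaction matrix lives on alignment columns, not on any single
structure. The two alignments (RAS side, effector side) are inputs, assumed
already synchronized with the structures by the curator; the package never
re-aligns. A chain is placed on its alignment row by exact ungapped
substring match (left-most placement on ambiguity, with a warning); failing
that, the best sliding-overlap placement is accepted at ≥ 95% identity,
point mismatches map with a warning, and overhanging residues such as
expression tags are dropped. Columns are numbered from the reference row
(HRAS for rows, CRAF for columns; start number configurable, default the
author numbering of the reference construct), gap columns carrying
insertion-suffix labels ("31A"). Columns are 0-based internally and 1-based
in written reports. Residues that cannot be mapped are excluded and
itemized in a skip report — they never create matrix rows.

## Matrix aggregation and region detection

The default counting mode is **per-structure presence**: a cell gains +1
for every complex with at least one atom pair there, which is robust to
redundant crystal forms; **atom-pairs** mode sums atom pairs instead and is
used for category-resolved depth. The four category sub-matrices are
aggregated in the same mode and, in atom-pairs mode, sum cell-wise to the
total matrix (an asserted invariant, along with conservation of input atom
pairs and invariance under permutation of structure order).

Regions are detected by thresholding cells at `min_count` (default 2),
connecting cells within Chebyshev distance `1 + bridge` (default bridge 1,
so blocks may jump one sparse row/column; bridge 0 is plain
8-connectivity), discarding components smaller than `min_cells` (default
3), and ranking the rest by total count with a deterministic (min row, min
col) tie-break. The defaults were chosen so that planted rectangular blocks
with counts ≥ 2 and separation ≥ 3 cells are recovered exactly; since the
historical regions R1–R5 were originally called by eye on a heatmap, all
three parameters are configurable, and the literature spans shipped in
`reference_data.REFERENCE_REGIONS` are used strictly for labeling and
comparison, never as algorithm input. Whether row 39 of the recognition
block is backbone-dominated like rows 37–38 is reported, not asserted.

## Quadratic binding isotherm and fitting

With total receptor R_t (the labeled RAS·mGppNHp species, fixed at 1 μM in
the assay design), total ligand E_t and dissociation constant K_d, the
bound-complex concentration is the physical (smaller) root of
x² − (R_t+E_t+K_d)x + R_t·E_t = 0. The discriminant is clamped at zero to
absorb floating-point negatives where the roots coalesce (K_d → 0,
E_t ≈ R_t). The measured polarization is assumed linear in the bound
fraction x/R_t. All concentrations are μM end to end.

`fit_titration` minimizes unit-weight squared residuals over
(log K_d, P_free, P_bound) with Levenberg–Marquardt, initialized at
P_free = first signal, P_bound = last signal, and K_d = the interpolated
half-signal concentration. The log parameterization enforces K_d > 0; the
standard error of K_d comes from the Jacobian at the optimum via the delta
method. Fits need ≥ 5 points and a non-constant signal; replicate curves
are summarized as mean ± standard error of the mean. Not modeled, by
design: errors in concentrations, fusion-tag effects, polarization vs
anisotropy distinctions, kinetics, competition formats and global
multi-curve fitting — the assay is treated as a single 1:1 isotherm per
curve.

## Synthetic data: what it emulates, and what it does not

`make_toy_complex` plants chosen residue pairs at exact inter-atom
distances (±10⁻³ Å) between atoms of chosen backbone/side-chain classes
while guaranteeing every other inter-chain atom pair sits beyond 8 Å
(twice the cutoff, so float jitter cannot create accidental contacts).
Residues use a minimal five-atom template (N, CA, C, O, CB) clustered
within 1 Å of a center, with the designated contact atom extended on an
arm toward its partner; geometry is deliberately unphysical — no rotamers,
no realistic backbone — because the contract under test is metric, not
chemical. `make_titration` adds i.i.d. Gaussian noise (σ as a fraction of
the signal span, seeded NumPy generator) as a stand-in for instrument
error; real titrations also carry concentration errors and drift that the
generator does not emulate. `make_planted_matrix` builds disjoint
rectangular blocks with known cell sets. Passing tests therefore
demonstrate algorithmic correctness on the stated contracts (exact contact
recovery, parameter identifiability under the stated noise, exact planted
block recovery) — not performance on real crystallographic coordinates,
where disorder, alternate conformations and alignment curation dominate.

Simulation sizes: the noise-robustness study uses 200 seeded replicates
per K_d at σ = 2% of span over the 24-point design; contact-engine
equivalence uses 50 random 8+8-residue complexes at three cutoffs. These
sizes make the full suite run in seconds while keeping the Monte-Carlo
medians stable to well under the 10% acceptance band.

## Known discrepancy in the benchmark constants

The benchmark grid lists the HRAS / CRAF-RB affinity as 0.094 μM, while
the accompanying replicate-reproducibility statement quotes
"0.94 ± 0.014 μM" — a likely decimal-point typo. The grid value is treated
as canonical throughout; the discrepancy is flagged here rather than
resolved.

## Design notes

- The package is organized as an analysis project: computation lives in
  `src/raseff/`, and the numbered scripts under `analysis/` are thin
  narrative drivers. There is no console entry point; the drivers plus the
  library functions (`raseff.pipeline.run_matrix_pipeline`,
  `run_affinity_pipeline`) are the interface, and both accept a single
  `RunConfig` so batch runs are reproducible from one object.
- One effector alignment is accepted per run; whether RB and RA
  sub-families should be aligned jointly or separately is a curation
  question left to the user, who supplies the alignment.
- Outputs (TSV matrices, JSON bundles with sorted keys, no timestamps) are
  byte-identical across reruns on identical inputs.
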