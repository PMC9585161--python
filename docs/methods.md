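# Methods

## Model and scores

The working object is a sample × feature expression matrix `A` (assumed
already log-transformed; no normalisation is applied here). For a
sub-matrix `B_k = (S_k, F_k)` the residue of an entry is
`r_ij = a_ij − μ_i(r) − μ_j(c) + μ_k` and the mean squared residue (MSR)
is `H_k = Σ r_ij² / (|S_k||F_k|)`. The MSR is invariant under adding a
constant to any row or column, scales as `c²` under scalar multiplication
`c·A`, equals the equally weighted mean of the per-row (or per-column)
scores, and is zero exactly on additive blocks `b + p_i + q_j` — which is
why the additive model is both the search target and the implant model of
the synthetic generator. A sub-matrix with `H_k ≤ δ` is a δ-bicluster.
The unnormalised variance `Σ (a_ij − μ_k)²` is exposed for completeness
and powers an optional post-filter against near-constant (trivial)
biclusters; the search itself never uses it.

`msr`/`axis_msr` are defined for real data only and reject complex input
explicitly, so the split between magnitude-form and real-part scores on
shielded data is visible in the API rather than silently absorbed.

## Shielding

A discovered footprint is shielded entrywise:
`a ← (1 + φ·ρ[Im(a)=0]·j)·a + φ·ρ(a)·j` with shielding factor `φ ≥ 1`
(default 10) and `ρ` the discrete unit impulse (1 within `zero_tol` of
zero, default 1e-12). The first impulse detector makes shielding
idempotent; the second rescues exact zeros to `φj` so no entry escapes.
Real parts are preserved exactly — the basis for every "reported quality
is about the raw data" guarantee.

Scores over complex data: deletion phases use the magnitude forms
`(1/|F_k|)·|Σ_j r_ij²|` (row), `(1/|S_k|)·|Σ_i r_ij²|` (column) and
`|Σ r_ij²|/(|S_k||F_k|)` (whole region; the magnitude generalisation is
ours, chosen for consistency with the row/column forms). On a fully
shielded zero-free block every magnitude score is exactly `(1 + φ²)` times
its real counterpart (for φ = 10: ×101); on real data the squared residues
are nonnegative reals, so the magnitude scores are *bit-identical* to the
classical ones. The addition phase scores `real(r_ij)²` only, which by
linearity of the residue equals the score of the unshielded data.

`φ = 10` by default: the inflation only needs to push shielded
rows/columns past the deletion threshold, and ×101 does so for any
realistic δ while keeping double-precision arithmetic comfortable.

## The search

Both methods share one inner engine per discovery iteration:

1. **Collective deletion**: repeatedly delete every row, then every
   column, with score `> α·H` (α default 1.2, the customary fast-deletion
   multiplier), stopping at `H ≤ δ` or a clean pass.
2. **Single-node deletion**: remove the worst-scoring row or column
   (ties: row before column, lowest index) until `H ≤ δ`; hitting the
   minimum dimensions (default 2×2) first makes the iteration degenerate.
3. **Addition**: repeatedly add every column, then every row, whose
   real-part score against the current region is within the admission
   threshold, to a fixed point. A final real-part trim enforces the
   reporting contract `msr ≤ δ` (rarely needed).

The baseline then overwrites the footprint with Uniform draws over the
observed range; the shielded variant shields it. Degenerate iterations are
skipped (not recorded) but their footprint is still shielded/masked so the
state advances; the shielded loop also skips exact re-derivations of an
already reported (rows, cols) pair and terminates as exhausted when a
skipped endpoint is already fully shielded, since re-shielding is a no-op.
All of this makes a run a pure function of (matrix, parameters, seed).

Two engine choices deserve explanation:

* **Admission threshold.** The printed addition rule compares a
  candidate's score to the region's current MSR. After greedy deletion on
  high-contrast data, however, the crossing of δ happens when the last
  incoherent member is removed, so the surviving region is typically far
  *more* coherent than δ requires; the strict rule then rejects
  rows/columns that plainly satisfy the δ-bicluster condition and freezes
  the bicluster at a fragment. The default rule therefore admits a
  candidate whose score is within `max(current MSR, δ)` — everything
  coherent at the level the user already accepts. In the regime the search
  was designed for (deletion stops with `H ≈ δ`, as on real microarray
  data) the two rules coincide; `addition_rule="msr"` restores the strict
  form.
* **Collective-phase gating.** On clean data the collective α-deletion is
  active only for axes with more than 100 entries (with few entries on the
  opposite axis, scores scatter ~`√(2/m)` and repeated tail-truncation at
  `α·H` can cascade the whole matrix away). While the region contains
  shielded entries the phase is active regardless of size: expelling
  shielded rows/columns wholesale is its purpose, their magnitude scores
  dwarf `α·H`, and leaving them in place lets complex column means leak
  imaginary components into the residues of *unshielded* rows, scrambling
  the deletion order.

## Synthetic data

`make_background` draws i.i.d. noise (default Uniform(0, 800), the dynamic
range of the classic yeast benchmark); `implant` writes additive blocks
`b + p_i + q_j + N(0, σ²)` with recorded ground truth (overlapping
implants are last-writer-wins). `overlapping_pair_dataset` builds the
benchmark used throughout: a 15×8 and a 12×6 implant sharing a 4×3
overlap, with the second implant inheriting the first's base and shared
effects so both footprints are genuinely additive despite the shared
cells. Effect scales (base U(300, 500), row/column effects U(−200, 200),
σ = 5) keep implant values inside the data's dynamic range. The expected
MSR of a noisy implant is `σ²(|S|−1)(|F|−1)/(|S||F|)` (≈ 20 at σ = 5), so
recovery experiments use δ = 2σ² = 50, twice the within-implant noise
variance. What the generator does *not* emulate: heavy-tailed or
platform-specific microarray noise, correlated backgrounds,
multiplicative coherence, missing-value patterns — so passing tests show
the machinery works as specified, not that real-data performance is
guaranteed.

## Operating regime and known limitations

The greedy descent acquires a preference for implant members only once the
candidate region is substantially implant-dominated; before that, an
implant row's score advantage is roughly `(|F_k|/m)·(1 − σ²_implant/σ²_bg)`
— of the order of 10% — which is below the per-step score noise when the
implant occupies a small fraction of the matrix. Measured on the benchmark
geometry: implants at ≈ 10% of cells (60×20 matrix) are recovered reliably
(and the masking baseline's second-implant Jaccard is capped near 0.67,
the signature of the destroyed overlap, while the shielded search reaches
1.0); the same implants at ≈ 1% of cells (200×50) are recovered
unreliably by *both* methods, because the first-implant discovery itself
fails — a limitation of the whole greedy-MSR family, not of shielding.
The comparison harness and the acceptance script therefore report both
scales. Further iterations help the shielded search (every discovery,
including noise fragments, is shielded and thereafter expelled, shrinking
the effective search pool), which is why recovery runs request many more
biclusters than implanted structures.

Numerical notes: zero-tolerance 1e-12 in the impulse detectors; per-phase
step caps (`n·m` deletions, `n+m` addition passes) guard against
floating-point tie cycling; missing entries (sentinel −1 by the yeast
convention) are imputed Uniform(min, max) over the observed range from a
dedicated stream of the run's seed before searching; degenerate iterations
do not consume a slot in K, with a total attempts cap of `2K` by default.

Out of scope: inverted-row ("mirror image") addition, probabilistic or
simultaneous multi-bicluster moves, multiplicative coherence models,
statistical significance of biclusters, and any biological interpretation
of the discovered gene sets.
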