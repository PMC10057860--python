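# Methods

This note documents the model behind `formulanet`, the choices made
where the design was genuinely open, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Model and assumptions

The core object is a molecular formula over {C, H, N, O, P, S} — the
element set that covers the overwhelming majority of small endogenous
metabolites. The method assumes:

- **Singly charged positive adducts.** Ions are [M+H]⁺, [M+Na]⁺ or
  [M+K]⁺. Ion m/z = neutral monoisotopic mass + adduct mass − electron
  mass. The electron mass (0.549 mDa) is subtracted because leaving it
  in biases theoretical m/z by more than 2 ppm above m/z ≈ 270 — the
  working tolerance would otherwise be structurally violated.
- **Metabolomes are reaction-dense.** A genuine metabolite formula is
  almost always reachable from other metabolite formulas by common
  biochemical transformations (oxidation, methylation, phosphorylation,
  glycosylation, amino-acid residue transfer, …). A random formula that
  merely matches a mass is not. The degree of a candidate in the seeded
  reaction network is therefore used as an evidence count.
- **Mass error is ppm-scale and centered.** Modern Orbitrap data after
  calibration shows errors clustered near zero within ~2 ppm; the
  score treats the 2 ppm tolerance as the natural unit of mass error.

Isotope masses and abundances are pinned in `formulanet/isotopes.py`
(AME2020 masses, IUPAC-CIAAW 2021 abundances) so results do not drift
with third-party library versions.

## Isotope patterns

Predicted envelopes are aggregated into nominal shells (M, M+1, M+2)
by exact convolution of per-element isotope distributions — equivalent
to expanding the abundance multinomials — with the shell m/z taken as
the abundance-weighted mean isotopologue mass. Shell aggregation (not
resolved fine structure) is deliberate: the isotope score compares one
experimental (m/z, intensity) pair per shell, which is what a
centroided spectrum provides at the M+1 scale. For [M+H]⁺ the extra
proton's hydrogen is included in the envelope; Na and K only shift the
m/z axis at the M+1 shell (⁴¹K first appears at M+2, which the score
does not use).

## Scoring

Score = W_degree·S_degree − W_m/z·S_mz + W_iso·S_iso, defaults
(0.5, 0.3, 0.2).

- **S_mz** = |ppm error| / tol_ppm: 0 at a perfect match, 1 at the
  tolerance boundary, entering with a minus sign as a pure penalty.
  This normalization makes the mass term commensurate with the other
  two unit-interval terms; a raw doubled-ppm variant
  (`mz_mode="doubled_ppm"`) is available for comparison.
- **S_iso** = 0.5·(1 − ppm error/tol_ppm) + 0.5·(1 − relative-intensity
  deviation / 5.0) on the M+1 shell, each part floored at 0. The 500%
  intensity tolerance is deliberately loose: DI intensities of weak
  M+1 peaks are noisy, and the term is meant to veto grossly wrong
  carbon counts, not to fine-rank. A feature with no detected M+1
  scores 0 — absence of evidence, applied equally to all candidates of
  that feature.
- **S_degree** = degree / (max degree among the feature's candidates),
  so it ranks candidates *within* a feature; a lone candidate scores 1.
  No normalization across features is attempted because degrees are
  only ever compared within one feature.

Ties at the top score (within 1e−12) defer the feature — conservatism
over arbitrary choice; the feature is re-scored in later rounds when
the grown network may break the tie.

## Degree filter semantics

The cut-off is inclusive: a candidate survives with degree ≥ cutoff
(default 3). An exclusive reading (> cutoff) is available via
`inclusive_cutoff=False`. A candidate whose formula already *is* a
network node always survives the filter regardless of its degree:
known metabolites must not be penalized for sitting in a sparse corner
of the seed network. Candidate-to-candidate edges (between two
unassigned hypotheses) never count toward degree — evidence comes from
the vetted network only.

## Iterative rounds

After each round the newly unique formulas are added as nodes with
their reaction edges and all unresolved features are re-evaluated.
Both unassigned features *and* ambiguous ties are re-scored by default
(`rescore_ambiguous=False` restricts re-evaluation to unconnected
features); assignments are never revoked, so the unique set grows
monotonically and the loop terminates in at most one round per
feature (in practice 2–7 rounds).

## Preprocessing choices

- Window overlaps are split at the overlap midpoint — deterministic,
  symmetric, and it keeps peaks away from window edges where mass
  accuracy degrades.
- The S/N filter is strict (S/N > 10).
- Alignment is greedy single-linkage in ascending m/z against the
  cluster's running intensity-weighted mean at 5 ppm — deterministic
  and standard for direct-infusion data, where there is no retention
  time to disambiguate.
- Blank reduction keeps features with mean sample intensity ≥ 3× the
  mean blank intensity (configurable).
- The QC RSD filter uses the sample standard deviation and drops
  features absent from QC (they cannot demonstrate repeatability).
- De-isotoping: a feature is non-monoisotopic when another feature one
  ¹³C–¹²C spacing (1.003355 Da) below it, within 2 ppm, has an
  intensity ratio consistent with an M+1 isotopologue. "Consistent"
  means at most 1.5× the largest M+1 fraction any CHNOPS formula at
  that mass could show (≈1.1% per carbon plus a small heteroatom
  allowance). The matched M+1 peak is attached to its parent and feeds
  the isotope score.

## Candidate enumeration

Enumeration is complete over the integer lattice: heteroatoms (P, S,
N, O, heaviest first) and carbon are expanded as staged numpy arrays
pruned by cumulative mass, and hydrogen is solved inside the residual
window, which is narrower than one hydrogen mass for any ppm-scale
tolerance. Per-element upper bounds are mass-derived
(count ≤ target/element mass), guaranteeing completeness without
heuristics; the test suite checks exact set equality against a naive
scalar nested-loop oracle. The H/C rule applies only when C > 0 (the
ratio is undefined for carbon-free formulas such as H₃PO₄-like
candidates, which pass). An optional RDBE window exists but is off by
default, since plain element-ratio rules cover the intended space.

## Reaction table

The package ships a default table of 58 named biochemical formula
differences (small-group transfers, condensations, conjugations, and
the 19 distinct amino-acid residue masses) as an editable CSV; every
network operation is parameterized by whatever table is supplied, so a
lab-specific table is a drop-in replacement. Matching is undirected
(a difference and its negation are the same edge species), duplicate
differences are rejected at load time, and between any two formulas at
most one reaction can match (the pairwise difference is unique).

## Synthetic data: what it emulates, what it does not

The generator emulates the structure of a spectral-stitching DI serum
acquisition: a seed universe whose reaction network has a requested
mean degree (default 3); truth metabolites drawn one reaction step
from the universe; three adduct types; Gaussian ppm mass error
(default sd 0.7 ppm, matching near-zero-centered sub-2-ppm residuals);
M+1/M+2 peaks with 20% multiplicative intensity error; log-uniform
intensities; uniform chemical noise partly below the S/N threshold and
partly irreproducible across QC injections; blank contaminants; and
overlap-duplicated acquisition windows.

Universe growth applies a biased random walk: most growth steps use a
small set of common transformations, producing homologous lattice-like
clusters the way real metabolomes do. The mapping from requested mean
degree d to the growth probability, p = (ln d + 1.74)/3.92 (capped at
0.95), was fitted once on simulated universes across n = 100–2000 and
holds the induced mean degree within ±30% of the request.

Novel truths (absent from the universe) are required to reach ≥ 3
network neighbors by default — the generator's claim is that genuine
metabolites sit in dense reaction neighborhoods, which is exactly the
assumption the method exploits. Decoys are random rule-passing
formulas absent from the universe, mass-matched to it by sampling each
decoy's target mass from a universe member.

Not modeled: ionization-efficiency and matrix effects (intensities
carry no chemistry), profile peak shapes and centroiding, mass-axis
drift within a run, in-source fragmentation, multiply charged ions,
and correlated adduct patterns (each truth is emitted under one
adduct). Passing tests therefore demonstrate the correctness of the
algorithmic chain and its statistical behavior under calibrated noise
— not performance on real serum, where candidate density, isotope
interference and adduct correlation are harsher.

## Parameters

| Parameter | Default | Unit | Why |
| --- | --- | --- | --- |
| `tol_ppm` | 2 | ppm | working mass tolerance of the instrument class |
| `align_ppm` | 5 | ppm | cross-sample alignment window |
| `snr_min` | 10 | — | strict noise floor |
| `blank_ratio` | 3 | fold | sample-over-blank retention threshold |
| `rsd_max` | 30 | % | QC repeatability cut |
| `cutoff` | 3 | neighbors | degree evidence threshold |
| `weights` | (0.5, 0.3, 0.2) | — | degree / mass / isotope weighting |
| `tol_int` | 5.0 | fraction | 500% M+1 intensity tolerance |
| `mass_range` | 50–800 | Da | neutral mass domain of the seed network |
| `hc_ratio` | 0.4–5.1 | — | elemental plausibility window |
| `max_rounds` | 20 | — | safety bound; the loop self-terminates |

## Problem sizes in the test and acceptance runs

The shipped acceptance runs use a 2000-formula universe with 200 truth
ions and 500 noise peaks per sample (3 samples, 1 blank, 2 QC), with
truth recovery averaged over five RNG seeds; the target-decoy
experiment uses nested universes of 500/2000/8000 formulas with 200
known and 200 decoy probes. These sizes exercise every pipeline branch
at roughly the feature density of a real stitched serum spectrum while
keeping a full run in tens of seconds.

## Known limitations

- Positive mode only; no negative-mode adducts or charge states > 1.
- The isotope score uses only the M+1 shell; M+2 information (notably
  sulfur's strong ³⁴S signature) is predicted but not scored.
- Degree evidence is only as good as the seed list: for poorly
  characterized organisms the network filter under-assigns (the
  false-negative mode), and an incomplete reaction table has the same
  effect.
- No MS/MS, retention or collision-cross-section evidence: output is
  formula-level, never structure-level.
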