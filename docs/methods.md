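# Methods

## Model and procedure

`mutsphere` tests whether somatic missense mutations concentrate spatially
on a protein structure more than expected if every residue were equally
likely to mutate. The unit of spatial information is the residue α-carbon;
a hotspot is the closed Euclidean ball of radius *r* Å around a residue's
Cα. The analysis of one structure proceeds in four steps.

**1. Ingest and filter mutations.** The mutation table is per-sample:
gene, sample id, 1-based canonical protein position, wild-type and mutant
residues, mutation type, somatic status, screen type (documented TSV
contract; see `mutmap.TABLE_COLUMNS`). The inclusion filter keeps missense
substitutions whose somatic status is "confirmed somatic variant" or
"reported in another cancer sample as somatic" (matched case-insensitively
after trimming) and that come from whole-gene or whole-genome screens —
targeted screens would bias the uniformity null. Exact duplicates on
(gene, sample, position, wt, mut) are removed keeping the first, so a cell
line reported by several studies is counted once. Counting is sample-level:
two samples mutating the same residue contribute two occurrences.

**2. Reconcile numbering.** Canonical (database) positions rarely match the
author numbering in coordinate files. Two modes are provided:
`structure_numbering` trusts the author residue numbers; `alignment`
(default) globally aligns the canonical sequence to the structure-derived
sequence (BLOSUM62, gap open 10 / extend 0.5 — standard protein-alignment
defaults, configurable) and maps positions through aligned non-gap columns.
An alignment identity below a floor (default 0.90) raises an error rather
than returning a plausible-but-wrong mapping. Mutations at residues without
coordinates are dropped and counted. A structure with fewer than two mapped
occurrences is *blank* — no clustering is assessable — and is excluded
before the study-level test count k is formed.

**3. Optimal sphere cover.** For each cell of the (s, r) grid
(s ∈ {1,2,3}, r ∈ {1..10} Å by default) the package finds the s spheres
maximizing the number of covered mutation occurrences subject to pairwise
center distance ≥ 2r. Candidate centers are all residues, not only mutated
ones: a sphere centered between two mutated sites can cover both. Centers
are sorted by individual coverage (ties broken by ascending residue index)
and the strictly-decreasing index lattice is traversed best-first: the
element (i₁ > … > iₛ) has priority Σ c[iⱼ], successors increment one
coordinate, and a max-heap (ties: lexicographically smallest tuple) yields
elements in non-increasing priority. Since the priority is an upper bound
on union coverage — exact for admissible configurations apart from exact
boundary tangencies — the first admissible element popped is a global
optimum, and the reported `covered` is always the recomputed union count,
never the priority. Infeasibility (no s centers pairwise ≥ 2r apart) is a
property of the geometry alone; such cells are flagged and excluded. A
brute-force enumerator over all C(N, s) subsets, guarded to N ≤ 50, serves
as an independent oracle in the tests.

**4. Simulate and standardize.** T (default 1000) null datasets place the
observed total number of occurrences i.i.d. uniformly over the N residues
(multinomial; sample structure is irrelevant because the statistic depends
only on aggregated counts). Every dataset row — observed and simulated —
is reduced to Z = max over included grid cells of (X − μ)/σ, with μ and σ
taken cell-wise over the simulation rows only (population SD, ddof = 0; at
T = 1000 the distinction from the sample SD is negligible). Cells with
σ = 0 carry no ordering information and are excluded from every row's
maximum, not just the observed one, so the max stays comparable across
rows. The p-value is the tail fraction #{Zᵢ ≥ Z₀}/T; ties count against
significance. When the count is zero the result is reported as a floor,
"<1/T". The reported hotspot configuration is the one at the included cell
with the largest observed standardized coverage (ties → smaller s, then
smaller r); one p-value covers all its spheres jointly.

**Study level.** Across k analyzed (non-blank, non-failed) structures the
significance cutoff is the rough FDR α(k+1)/(2k), a good approximation to
standard FDR control for many positively correlated or independent tests;
it decreases from α at k = 1 toward α/2. The applied threshold is rounded
*down* at a configurable precision (default 3 decimals) to stay
conservative. Floor p-values compare as 1/(2T) for thresholding — strictly
below any achievable non-floor value. Per-structure sub-seeds are derived
by hashing (master seed, structure id), so study results are independent
of manifest row order. One protein may contribute several structures;
the per-gene summary reports the minimum p-value over a gene's structures
and is labelled as such — per-structure rows remain authoritative.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| radii | 1..10 Å | sphere radius grid; 3.8 Å is one backbone step, so the grid spans single-residue to multi-turn neighborhoods |
| max_spheres | 3 | largest sphere count s; larger values are accepted but cost O(Nˢ) worst case |
| simulations (T) | 1000 | Monte-Carlo resolution; the smallest reportable p is 1/T |
| alpha | 0.05 | nominal level entering the rFDR cutoff |
| identity_floor | 0.90 | minimum alignment identity for reconciliation |
| seed | 0 | master seed; every random stream derives from it |

## Synthetic data

The `synthetic` module generates desk-scale ground-truth fixtures: ideal
backbones (straight chain at 3.8 Å spacing; α-helix with 1.5 Å rise, 100°
turn, 2.3 Å radius, giving ≈3.8 Å consecutive Cα distances; self-avoiding
random coil with a 4 Å exclusion radius) written as minimal valid PDB text,
plus mutation tables with planted hotspots (uniform within a short span)
over a uniform background, spread round-robin across sample ids. Generated
tables pass the inclusion filter unchanged by construction, and with zero
hotspots the generator draws from exactly the null law of the simulation
engine — the basis of the calibration test. What the fixtures do *not*
emulate: real folds and contact topology, heterogeneous per-residue
mutability (CpG context, tissue composition), isoform mismatches, missing
loops. Passing tests demonstrate correctness of the machinery and
calibration under the stated null, not robustness to those real-data
features.

## Numerical and design choices

* **Closed balls, boundary tangency.** "Within the sphere" means distance
  ≤ r, and center pairs at exactly 2r are admissible; both choices keep
  results monotone in r and make mutation-to-sphere assignment unambiguous
  except on measure-zero tangencies.
* **Determinism.** All tie-breaks are fixed (ascending residue index,
  lexicographic tuples, s-then-r cell order); identical inputs and seed
  give byte-identical result JSON.
* **Altloc / chain / model selection.** First chain bearing Cα residues
  (or an explicit id), first conformation by default, lowest altloc id
  for alternate locations; chemically modified residues (MSE etc.) are
  excluded unless requested.
* **Degenerate inputs.** Single-residue structures make every cell
  constant (σ = 0): all cells are excluded and p is reported as 1. A
  blank tally is rejected before simulation.
* **Non-uniform null hook.** `simulate_null` accepts per-residue weights,
  but only the uniform null is supported, tested behavior.

## Problem sizes used in the checks

The statistical test fixtures are deliberately desk-scale: the calibration
study uses a 30-residue self-avoiding coil with 25 uniform mutations,
radii {2, 4, 6} Å (kept proportional to the coil's ~25 Å extent, as in real
use where optimal radii are small relative to the protein), s ∈ {1,2,3},
T = 200 and 500 replicates; planted-hotspot recovery uses a 200-residue
chain with 50 mutations in a 3-residue span plus 10 background at T = 1000;
optimizer/oracle agreement uses 200 random instances with N ≤ 30. Under
exchangeability the Monte-Carlo p at T = 200 satisfies
P(p ≤ 0.05) = 11/201 ≈ 0.055 for continuous Z, so the calibration check
allows ±0.03 around 0.05.

## Known limitations

* The uniform null ignores sequence-context mutability; prior per-residue
  rates can be injected through the weights hook but are not a supported
  workflow.
* Maximal coverage is not in general monotone in s: when every admissible
  extension of the (s−1)-optimum is blocked, adding a sphere can lower the
  achievable union (the monotonicity test therefore uses an extended chain
  with r far below its extent, where an admissible extension always
  exists).
* Worst-case search cost is the full C(N, s) lattice (compact structures
  with r near half the diameter); real radii grids sit far from this
  regime, and infeasible cells are detected once per cell, not per
  simulation.
* One chain, one conformation at a time; no side-chain atoms, no mmCIF.
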