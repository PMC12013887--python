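# Methods

## Model and assumptions

The package treats a protein structural unit as a cloud of effective atoms,
one per residue at the unweighted mean of the residue's heavy-atom
positions.  Hydrogens are excluded so results do not depend on whether a
file includes them; alternate locations keep the first conformer; waters
and ligands are dropped; selenomethionine is read as methionine.  Each
effective atom carries an intrinsic hydrophobicity from a residue scale
normalized to [0, 1].

Four per-residue probability distributions are compared over the unit
(each normalized to sum 1):

* **T** — a 3D Gaussian "oil drop" evaluated at the effective atoms.  The
  envelope is fitted with: center = coordinate mean; axes = principal
  components of the centered cloud (decreasing variance, right-handed
  frame); σ per axis = maximal |projection| / 3, so the ±3σ box spans the
  molecule.  The underlying idealization is that water drives folding
  toward a centric hydrophobic core with hydrophobicity decaying smoothly
  to zero at the surface.
* **O** — pairwise hydrophobic interactions through Levitt's contact
  polynomial with cutoff c = 9 Å.  The self term (j = i) is included by
  default (flag `include_self`), so an isolated residue still reports its
  own hydrophobicity; a floor of 1e-12 is added to every raw value before
  normalization so that all-polar neighborhoods cannot produce zeros.
* **R** — uniform 1/N, the no-core reference that anchors the RD ratio.
* **M** — normalize(T + K·(Tmax − T)).  At K = 0 this is T; as K → ∞ it
  tends to the normalized complement (Tmax − T), the membrane-like field
  with hydrophobic surface and polar interior.  For every residue with
  Ti < Tmax, Mi is monotone in K toward that limit (the derivative's sign,
  di·S − D·ti with di = Tmax − Ti, does not depend on K), which makes the
  one-dimensional K search well behaved.

**RD** = DKL(O|T) / (DKL(O|T) + DKL(O|R)) with divergences in bits
(base-2 logs).  **K** is the argmin of DKL(O | M(T, K)).  Fragment status
**RD(FR)** slices the unit-level T/O/R on the fragment, renormalizes each
slice to sum 1 and recomputes RD; the Gaussian envelope is *not* refitted
to the fragment — the fragment is judged against the field of its parent
unit.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Levitt cutoff `cutoff_c` | 9 | Å | the standard contact range of the interaction function |
| `include_self` | true | — | keeps O strictly positive; removable by flag |
| `sigma_divisor` | 3 | — | three-sigma rule: the envelope spans the molecule; exposed in config since only "adjusted to size and shape" is canonical |
| K search `k_max` | 10 | — | observed proteins fall well under K ≈ 3; 10 leaves headroom, and a boundary minimum is flagged with a warning |
| K coarse step | 0.01 | — | brackets the minimum before golden-section refinement to 1e-4 |
| ε floor | 1e-12 | — | applied to any divisor/log argument; well below profile resolution |
| RD threshold | 0.5 | — | hydrophobic core present iff RD < 0.5; pairs exactly at the threshold classify as mixed (class C) since the class rules use strict inequalities |
| pruning threshold | 0.7 | — | iterative largest-|OLS-residual| removal until r exceeds it |

Numerical conventions: divergences are clipped at 0 against float-error
negatives; the K tie-break prefers smaller K (the "more aqueous"
explanation); estimates below 1e-6 snap to exactly 0 when K = 0 achieves
the same objective value.

The default hydrophobicity scale is the Kyte–Doolittle hydropathy index
min-max rescaled to [0, 1].  The model accepts any [0, 1] scale
(`load_scale`), and published RD/K values for specific proteins can depend
noticeably on the scale and on the σ convention; both are therefore
configurable rather than hard-coded.

## Synthetic data: what it emulates and what it does not

`make_cloud` places n residues uniformly in a ball and assigns
hydrophobicity as a linear function of distance from the center: decreasing
("micelle", conforming to the aqueous ideal), increasing ("inverted", the
membrane-like anti-pattern) or constant ("uniform").  Sequence letters are
chosen as the residue whose scale value is nearest the assigned target, so
the letters and the Hir values stay mutually consistent.  Defaults — 150
residues, 15 Å radius, contrast 1.0 — give a residue density comparable to
a small globular protein, so the 9 Å interaction cutoff captures a
realistic neighborhood.

These clouds are statistical objects, not polymers: there is no chain
connectivity, no excluded volume, no secondary structure, and the
hydrophobicity gradient is exact rather than the noisy, sequence-driven
gradient of real proteins.  Passing the discrimination test (micelle
clouds RD < 0.5, inverted clouds RD > 0.5 for ≥95% of seeds) shows the
statistics read geometry correctly, not that any real protein family
behaves a particular way.  Micelle clouds occasionally land near RD = 0.5:
with random placement the core can be under-sampled, and O is smoothed
over 9 Å neighborhoods while T is pointwise — a genuine property of the
statistic, not a generator defect.

`make_k_fixture` draws a random T, applies the M transform at a known K
and adds optional multiplicative log-normal noise (log-normal keeps
positivity before renormalization).  `make_pair_population` draws each
pair's (higher, lower) fragment-RD from a bivariate normal with the
requested correlation, centered in disjoint bands (0.75 / 0.35, sd 0.08,
truncated to [0, 1]).  The bands are disjoint so that the per-pair
max/min ordering used by the scatter never swaps coordinates — otherwise
the ordering itself would inflate the measured correlation above the
generating ρ.  Unit RDs are drawn on opposite sides of 0.5, so every pair
is class C by construction.

## Design choices where the design was open

* The modified-field formula is read as plain K·(Tmax − Ti) followed by
  whole-profile normalization; this is the unique reading under which the
  K = 0 and K → ∞ limits reduce exactly to the aqueous and complement
  fields.
* Tmax is the maximum of the unit's normalized T profile.
* The outlier rule is max-|residual| from an OLS fit, one point at a time,
  with the full removal trace logged — the simplest reproducible reading of
  "eliminate outliers until r > 0.7"; alternative rules can be compared
  against the trace.
* Domain boundaries (e.g. CATH) are caller input in author numbering,
  inclusive; internally everything is 0-based half-open.
* Core computations use no randomness; all generators take explicit seeds.

## Problem sizes

Tests and the acceptance script run at desk scale: 150-residue clouds
(discrimination over 100 seeds per geometry), 50-point profiles for K
recovery (100 noisy replicates), 100 random instances for the
estimator-vs-grid oracle, and a 298-pair population for the correlation
workflow — the population size mirrors a realistic class-C chameleon-pair
collection.

## Limitations

* RD and K describe hydrophobicity topology only; they carry no energetics
  and no secondary-structure information.
* Published per-protein RD/K values are reproducible only up to the
  intrinsic-hydrophobicity scale and σ convention used to produce them;
  with a different scale the threshold-crossing behavior of borderline
  units (RD ≈ 0.5) can flip.
* The fragment statistic assumes the parent unit's envelope is meaningful
  for the fragment; very short fragments (< 2 residues) are rejected, and
  fragments of 2–5 residues give noisy RD(FR).
* The pipeline does not fetch structures, expand biological assemblies or
  assign secondary structure; those are caller responsibilities.
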