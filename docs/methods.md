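# Methods

`lcpkit` analyses conformational ensembles of intrinsically disordered
proteins (IDPs) through one central statistic — the local compaction plot —
plus a set of companion analyses (segment end-to-end distributions against
polymer reference models, sliding-window sequence property scans, and
secondary-structure occupancy maps) and a synthetic ensemble generator that
makes every analysis testable without molecular dynamics data.

## The local compaction plot

For an ensemble of `T` frames over a contiguous chain of `N` residues, fix a
window span `W` (default 75). For every window start `i` and every frame `t`,
measure the Euclidean Cα–Cα distance between residues `i` and `i + W − 1`
(inclusive span: `W = 75` pairs the residues at window positions 1 and 75).
Sliding the window one residue at a time gives a `T × (N − W + 1)` distance
matrix — a fixed-separation diagonal slice of the full intramolecular distance
matrix.

The statistic separates folding regimes cleanly at the default span:

* a rigid folded domain cannot hold two residues further apart than its own
  diameter, so all windows inside it give short (tens of Å), frame-invariant
  distances;
* a flexible but extended linker pushes the same 75-residue separation out to
  50–150 Å with large frame-to-frame scatter;
* a collinear chain with Cα spacing `b` gives exactly `(W − 1) · b`
  (281.2 Å at `W = 75`, `b = 3.8` Å) — the geometric ceiling, and a useful
  closed-form check.

Rendering draws every (window, distance) point with partial opacity so point
density maps to darkness: dominant conformations form dark traces, rare ones
remain visible as lighter shadows. A 2-D histogram mode is available when the
point count makes overplotting impractical. The x-position convention
(window start by default, center optionally) is recorded in the output
metadata because the choice is not canonical.

### Compact/extended classification

Each window is summarised across frames by its median distance (robust to the
bimodal linker conformations IDP ensembles produce; the mean is available as
an option) and thresholded: `< 50 Å` → compact, `≥ 50 Å` → extended, with an
intermediate band when the two thresholds are separated. Residues take the
majority label of the windows covering them; ties go to intermediate. The
50 Å default is the empirical boundary between folded-domain and extended-
linker window distances at `W = 75`; the upper end of the observed linker
range (~150 Å) is descriptive and is deliberately not a classifier bound.

Distances are always Cα–Cα. The measuring atom is a modelling choice, and the
Cα proxy makes results independent of side-chain atom sets; analyses reject
ensembles with numbering gaps rather than bridging them, and frames with
missing residues are rejected rather than imputed, since silent imputation
would corrupt the distance statistics.

## End-to-end distances and reference chain models

`end_to_end` records the per-frame Cα distance between two residues. To ask
whether a segment is *intrinsically* extended, its distribution is compared
against flexible reference chains of the same length:

* **Freely jointed chain (FJC)** — `n − 1` independent virtual bonds of
  length `b = 3.8` Å (the trans-peptide Cα–Cα spacing) with uniformly random
  orientations; `⟨R²⟩ = (n − 1) b²` exactly, which anchors the sampler tests.
* **Self-avoiding walk (SAW)** — the same step proposal with rejection of any
  bead within an excluded-volume radius (default 4.0 Å) of a non-bonded
  predecessor; chains are regrown on dead ends (error past a retry cap).
  Excluded volume swells the coil, giving a second, stiffer null model.

These samplers are analytic stand-ins for explicit control simulations of
highly flexible homopolymer peptides (poly-G, poly-G/S); the package documents
them as stand-ins, not as equivalents, since they carry no solvation or
sequence physics. Comparison uses the two-sample Kolmogorov–Smirnov test —
chosen as the distribution-level "indistinguishability" criterion because it
is assumption-free on distribution shape — reported with mean/median/IQR
deltas. The KS null calibration (two independent same-model draws should give
p > 0.01 almost always) is part of the acceptance checks.

## Sequence property scans

Windows of 25 residues (sliding by one, plotted at the window center — for
even spans the lower-median position) are scored as standalone peptides:

* **Local isoelectric point.** Net charge at pH `x` sums Henderson–Hasselbalch
  terms, `+1/(1 + 10^(x−pKa))` per basic group (K, R, H, free N-terminus) and
  `−1/(1 + 10^(pKa−x))` per acidic group (D, E, C, Y, free C-terminus). The
  charge is strictly decreasing in pH and spans +/− across (0, 14), so the pI
  is the unique root, found by bisection to 0.002 pH. Treating each window as
  a free peptide (termini included) matches the behaviour of the standard
  protein-parameter calculators this analysis mirrors. The pKa constants are
  an explicit YAML table (EMBOSS flat constants by default) and overridable;
  absolute pI values shift with the chosen table, while the profile *shape* —
  which regions are acidic vs. basic — is the scientifically meaningful
  output.
* **Local aromaticity.** The fraction of F/W/Y in the window; a box-filter
  count, bounded in [0, 1].

## Secondary-structure maps

Per-frame assignments come from external tools (DSSP, cpptraj's secstruct);
the package ingests three dialects — a native long TSV (frame, residue,
code), a wide one-letter table, and a wide cpptraj integer table (0 none,
1/2 β, 3 3₁₀, 4 α, 5 π, 6 turn, 7 bend) — onto an eight-class alphabet
(H, G, I, E, B, T, S, C). Unknown or blank cells coerce to coil with a counted
warning rather than failing, because long IDP trajectories routinely contain
unassigned residues. Occupancy is the per-residue fraction of frames in each
class (rows sum to 1 by construction, and are frame-order invariant); helical
propensity is the H + G + I sum. Rasters render residues × time with the
conventional palette (pink α, red 3₁₀, dark blue π, yellow extended, cyan
turn, white coil; bends/bridges default to light grey as legends conventionally
omit them) and concatenate multiple trajectories with separators.

## Synthetic ensemble generator

The generator emulates the geometry that matters to the analyses — rigid
folded domains connected by flexible linkers of tunable extension — without
any physics (no energies, no electrostatics, no acceptance criterion):

* **Rigid domains**: one self-avoiding compact cluster per spec (bead spacing
  exactly `b`, every bead within the bounding radius of the first, hard-core
  clearance 2 Å), grown once and rigid-body re-oriented each frame. All
  intra-domain distances are bounded by the sphere diameter and are
  frame-invariant to 1e-9 Å.
* **Flexible linkers**: grown bead-by-bead with spacing `b`; each step repeats
  the previous direction with probability ε, else draws a fresh uniform unit
  vector. ε = 0 is a freely jointed chain, ε = 1 a straight line, and mean
  extension is monotone in ε in between. Linker extension is modelled by this
  direction-persistence mixture rather than by explicit charge repulsion: the
  mechanism behind extension in any particular protein is a finding about that
  system, not part of the compaction-plot method, and the fixture only needs
  tunable extension with exact ground truth. A charged-bead repulsion fixture
  would be a possible extension.
* Segments concatenate head-to-tail with a junction bond of exactly `b`
  (junctions inherit the following linker's step rule); every residue carries
  a ground-truth label (compact/extended), enabling exact scoring of the
  classifier. Generation is bit-reproducible from the spec (architecture +
  seed), and fixtures round-trip through multi-model PDB to the format's
  1e-3 Å precision.

The default test architecture is an 81-residue domain (radius 20 Å), a
60-residue linker at ε = 0.9, and a second 81-residue domain, over 200
frames — a domain–linker–domain caricature of a folded DNA-binding domain
flanked by extended linkers. With `W = 75`, only residues near the chain
termini have *all* their covering windows inside a single segment (no
75-window fits inside a 60-residue linker), and classification must recover
≥ 95 % of those residues' ground-truth labels.

What the generator does **not** emulate: real bond-angle and dihedral
statistics, side chains, sequence-dependent behaviour, solvation, and the
actual conformational free-energy landscape of any protein. Passing tests
therefore demonstrate that the analyses measure what they claim on ensembles
of known geometry — not that any particular biological conclusion holds.

A single-frame variant (`folded_domain_standin`) provides a synthetic
folded-domain structure spanning an arbitrary author-numbering range (default
157–237, radius 20 Å — the size class of an ~80-residue winged-helix
DNA-binding domain) for checks that need a crystal-structure-like compact
input without downloading one.

## Numerical choices and problem sizes

* Distances in Å throughout; Cα virtual bond 3.8 Å everywhere a bond length
  is needed.
* pI bisection tolerance 0.002 pH; the test oracle is an independent 1e-4
  grid scan, agreement required to 0.005 pH.
* LCP correctness is asserted against a naive double-loop oracle at 1e-9 Å;
  rigid-body invariance at 1e-9 Å; PDB round-trips at 1e-3 Å (format
  precision).
* Acceptance-scale experiments use 10-frame × 300-residue oracle ensembles,
  200-frame recovery fixtures, 1e5-sample FJC draws, and 100-repetition KS
  calibrations — sizes chosen so the full sweep completes in seconds while
  estimator noise stays an order of magnitude below every threshold tested.
* All stochastic components (generator, samplers, experiments) take explicit
  seeds; identical inputs give bit-identical outputs.

## Known limitations

* Cα-only: no side-chain or all-atom distances, no solvent, no
  periodic-boundary handling (inputs are assumed whole-molecule).
* The SAW sampler is a simple rejection/regrowth scheme; it is adequate for
  the short segments used as references but would be inefficient for chains
  of hundreds of residues at large excluded radii.
* Window-position conventions differ across published compaction plots;
  outputs record the convention used, but cross-tool comparisons must align
  them manually.
* The KS test treats frames as independent samples; for strongly
  autocorrelated trajectories the effective sample size is smaller than the
  frame count, making the test anti-conservative.
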