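# lcpkit

Ensemble compaction analysis for intrinsically disordered proteins (IDPs).

Intrinsically disordered proteins do not fold into a single structure; they
sample broad conformational ensembles in which rigid folded domains coexist
with flexible linkers that may be collapsed, coil-like, or held in extended
conformations. `lcpkit` is a toolkit for asking *where along the chain* an
ensemble is compact and where it is extended, and whether a segment's
extension exceeds what a featureless flexible chain would produce. It is
aimed at people analysing MD trajectories or other multi-conformer models of
IDPs.

The core statistic is the **local compaction plot (LCP)**: for a window of
fixed span *W* (default 75 residues) slid along the chain one residue at a
time, the Cα–Cα distance *d(i, i+W−1)* is measured in every frame of the
ensemble and every point is plotted with partial transparency, so frequent
distances accumulate into dark traces while rare conformations stay visible
as lighter ones. Folded domains appear as short (< 50 Å), frame-invariant
dense lines; extended flexible linkers show long (50–150 Å), diffuse bands.
A median-over-frames threshold rule turns the same matrix into per-residue
compact/extended labels.

Around the LCP the package provides:

* **ensemble I/O** — multi-model PDB (Biopython) and MD topology+trajectory
  pairs (mdtraj), reduced to Cα ensembles that keep author residue numbering;
* **end-to-end analysis** — segment end-to-end distance distributions
  compared against freely jointed chain (⟨R²⟩ = (n−1)b², b = 3.8 Å) and
  self-avoiding walk references with a two-sample Kolmogorov–Smirnov test;
* **sequence scans** — sliding-window isoelectric point (explicit pKa table,
  Henderson–Hasselbalch bisection) and aromaticity (F/W/Y fraction);
* **secondary-structure maps** — occupancy and helical propensity from
  DSSP- or cpptraj-style per-frame assignment tables, with raster timelines;
* **a synthetic generator** — domain/linker architectures with exact
  ground-truth labels, so every analysis is testable without MD data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Generate a 222-residue domain–linker–domain ensemble (an 81-residue rigid
domain, a 60-residue extended linker, another 81-residue domain; 200 frames),
compute its LCP, classify regions, and compare the linker with a freely
jointed chain of the same length:

```python
import numpy as np
from lcpkit import compute_lcp, classify_regions
from lcpkit.synthetic import EnsembleSpec, Segment, build_ensemble
from lcpkit.e2e import (ChainModelParams, end_to_end,
                        sample_reference_chain, compare_distributions)

spec = EnsembleSpec(
    segments=(
        Segment("rigid_domain", 81, radius=20.0),
        Segment("flexible_linker", 60, extension=0.9),
        Segment("rigid_domain", 81, radius=20.0),
    ),
    n_frames=200,
    seed=1,
)
ens, truth = build_ensemble(spec)

res = compute_lcp(ens, window=75)
print("windows:", res.n_windows, "frames:", res.n_frames)
print("median distance, window starting at residue 1:  %.1f Å"
      % np.median(res.distances[:, 0]))
print("median distance, window starting at residue 74: %.1f Å"
      % np.median(res.distances[:, 73]))

cls = classify_regions(res)
labels = list(cls.residue_labels.values())
print("compact residues:", labels.count("compact"),
      "extended:", labels.count("extended"))

seg = end_to_end(ens, 82, 141)          # the linker
fjc = sample_reference_chain(ChainModelParams(n_residues=60,
                                              n_samples=10_000, seed=2))
rep = compare_distributions(seg, fjc)
print("linker end-to-end mean: %.1f Å   FJC mean: %.1f Å"
      % (seg.values.mean(), fjc.values.mean()))
print("KS statistic: %.3f   p-value: %.2e"
      % (rep["ks_statistic"], rep["p_value"]))
```

Output:

```
windows: 148 frames: 200
median distance, window starting at residue 1:  11.0 Å
median distance, window starting at residue 74: 108.6 Å
compact residues: 92 extended: 128
linker end-to-end mean: 109.5 Å   FJC mean: 26.7 Å
KS statistic: 0.891   p-value: 5.44e-186
```

Reading the numbers: the window that sits entirely inside the first rigid
domain measures 11 Å — far below the 50 Å compactness bound and identical in
every frame — while the window spanning the linker stretches to ~109 Å. The
classifier labels the domain residues compact and the linker (plus the
domain flanks whose windows reach into it) extended. The linker's end-to-end
distance (109.5 Å on average, ε = 0.9 persistence) is four times the freely
jointed chain's 26.7 Å, and the KS test rejects indistinguishability
outright — this linker is extended far beyond what chain flexibility alone
produces. Dropping ε toward 0 makes the same test unable to tell the two
apart.

The same pipeline runs from the shell:

```sh
lcpkit simulate --frames 200 --seed 1 --out sim/
lcpkit lcp sim/ensemble.pdb --out lcp_out/          # matrix, labels, plot
lcpkit e2e sim/ensemble.pdb --first 82 --last 141 --out e2e_out/
lcpkit seqscan protein.fasta --out scan_out/        # pI + aromaticity
lcpkit ssmap assignments.tsv --out ss_out/          # occupancy + raster
```

Every subcommand writes its tables (TSV), reports (JSON), plots (PNG/SVG) and
a `run_metadata.json` that records version, options and seed, so any run can
be reproduced from its outputs alone.

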