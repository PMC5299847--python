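# osmotrace

Single-cell proteomic dynamics of the budding-yeast osmotic stress
response, from time-lapse fluorescence microscopy of microfluidic
chambers.

When *S. cerevisiae* is exposed to osmotic stress (KCl), over a hundred
proteins downstream of the HOG pathway change their expression over
minutes to hours. GFP-fusion strains imaged every 5 minutes in
microfluidic observation chambers give per-cell fluorescence
trajectories — but chambers start with only 20–50 cells, cells are
washed out during growth, signal photobleaches, and population
averaging can erase genuinely single-cell dynamics such as
asynchronous Hsp12-like expression bursts.

`osmotrace` implements the full analysis chain for this kind of
experiment, aimed at groups doing quantitative time-lapse reporter
microscopy in yeast (or any adherent single-cell system):

- **Quantification** — per-cell readout from image + labeled-mask
  stacks: whole-cell mean intensity for uniformly distributed,
  membrane and mitochondrial proteins; mean of the brightest 10% of
  pixels for nuclear proteins. Greedy nearest-centroid tracking keeps
  cell identities across frames; background is the per-frame median of
  non-cell pixels.
- **Correction & normalization** — mono-exponential photobleach
  correction fitted on a non-responding control; per-time population
  mean S̄ₜ over valid cells; log₂ normalization to the 30-min
  pre-stimulus baseline.
- **Protein screen** — keep strains with SNR > 7 and fold change > 1.2
  (fold change is direction-agnostic, so down-regulated proteins pass).
- **Representative single cell (M1/M2)** — instead of averaging,
  choose the cell most similar to all others:

  ```
  M1ᵢ = (1/(N−1)) Σ_{j≠i} √[ (1/T) Σₜ ((Sₜⁱ − Sₜʲ)/S̄ₜ)² ]
  M2  = √[ (1/T) Σₜ ((Srₜ − S̄ₜ)/S̄ₜ)² ]
  ```

  The representative cell minimizes M1; M2 measures how far its
  trajectory Srₜ sits from the population mean. A high M2 flags
  dynamics (post-peak bursts) that population averaging hides.
- **Dynamics-based clustering** — hierarchical clustering (Euclidean,
  average linkage) of the protein × time log₂ matrix, cut at the
  silhouette-selected number of modules; on the osmotic panel this
  yields four modules: rapidly-up-then-adapting, down-regulated,
  slowly-up-then-adapting, and late-up-non-adapting.
- **Synthetic chip experiment** — a fully ground-truthed generator
  (archetype fold curves, per-cell variability, asynchronous bursts,
  washout truncation, photobleaching, background, noise, and optional
  rendered TIFF image/mask stacks) so the entire pipeline is testable
  without any experimental data.

## Worked example

Run the whole pipeline on a small synthetic panel (8 strains, two per
dynamic archetype, one strain with asynchronous bursts):

```python
from osmotrace import RunConfig, run_pipeline

cfg = RunConfig(outdir="demo", seed=11, n_per_archetype=2,
                bursty_strains=("RAPID_UP_ADAPT_0",))
run_pipeline(cfg, "all")
```

or equivalently from the shell: `osmotrace all --outdir demo --seed 11`.

`demo/representative_summary.csv` ranks strains by M2 (head):

```
          strain  rep_cell_id       m2  n_cells  n_timepoints
RAPID_UP_ADAPT_0           15 0.083019       20            91
DOWN_REGULATED_0            7 0.047740       16            91
RAPID_UP_ADAPT_1           22 0.047091       17            91
DOWN_REGULATED_1           37 0.041109       31            91
```

The bursty strain tops the ranking: its representative cell (cell 15,
picked as the argmin of M1 over 20 full-length trajectories of 91 time
points) keeps its bursts, while the population mean smooths them away,
inflating M2 to 0.083 against ~0.04–0.05 for burst-free strains.

`demo/module_summary.csv` describes the silhouette-selected modules:

```
 module  n_members  peak_time_min                label
      1          2          355.0                 down
      2          2          360.0 up-late-non-adapting
      3          2          130.0     up-slow-adapting
      4          2           30.0     up-fast-adapting
```

All four planted response archetypes are recovered, with peak times
(minutes after stimulus) matching their dynamics. The run also writes
the tidy trajectory table, the log₂ heat-map matrices, per-cell M1
scores, a Newick dendrogram, a clustered heat-map figure and a JSON
run manifest; every CSV carries the seed and config hash in its
header.

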