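# smfretglue

Single-molecule FRET trace analysis and membrane nanocluster statistics for
GPCR conformational studies — the analysis chain behind experiments in which
a dimerizing ("molecular glue") allosteric modulator shifts a receptor's
conformational equilibrium and enlarges its membrane nanoclusters.

The package covers two measurement branches end to end, plus the synthetic
ground truth needed to validate both without raw recordings:

1. **smFRET branch** — two-channel TIRF movies of surface-immobilized,
   donor/acceptor-labeled receptors are turned into per-molecule intensity
   traces (channel registration, spot detection and pairing, aperture
   extraction with local-median background from a 35-px region), corrected
   (7% donor-leakage subtraction, per-molecule γ from the intensity changes
   at acceptor photobleaching), filtered by the five standard selection
   criteria (SNR ≥ 5; single-step acceptor bleach before donor; γ ∈ [0.5, 2.5];
   anticorrelated donor/acceptor fluctuations; single-step donor bleach if
   present; plus direct-excitation acceptor-identity confirmation), and
   summarized as ensemble FRET histograms with two-Gaussian state populations:

   E = Iₐ / (Iₐ + γ·I_d) per frame, binned into 30 intervals over
   [−0.25, 1.25], normalized per molecule, averaged across molecules, and fit
   with A_low·N(μ_low, σ_low) + A_high·N(μ_high, σ_high); state fractions are
   the normalized Gaussian areas, with molecule-bootstrap SEMs. A two-state
   hidden-Markov idealizer supplies state paths and dwell times.

2. **Nanocluster branch** — immunogold particle coordinates on unroofed
   membranes are grouped into clusters by single-linkage (particles within a
   linkage radius belong together), and per-cluster particle counts are
   compared across conditions with cumulative-probability curves and a
   two-sided Mann–Whitney U test.

The **simulator** generates traces, rendered movies, and point patterns from
a fully specified photophysical model (two-state Markov dynamics, per-pair γ,
single-step exponential bleaching, Poisson shot + Gaussian read noise,
donor-only / acceptor-only / aggregate contaminants, clustered vs dispersed
point patterns), so every downstream stage is tested against known truth.

## Worked example

Run the numbered analysis drivers (raw per-frame data goes to `scratch/`,
tables and figures to `results/`):

```
python analysis/01_simulate_dataset.py
python analysis/02_extract_from_movie.py
python analysis/03_correct_and_qc.py
python analysis/04_fret_populations.py
python analysis/05_nanoclusters.py
```

`01` creates two 300-molecule trace conditions whose true active-state
(low-FRET) occupancies are 26.5% ("apo") and 11.2% ("modulator"), plus
vehicle/treated gold-particle patterns. `03` prints the QC funnel — e.g. for
the apo condition 175/300 molecules are accepted, with rejections dominated
by bleach-timing (no usable acceptor bleach inside the 80-s window) rather
than by any FRET-state bias. `04` then prints:

```
apo: n=175 molecules, active state 27.5 +- 0.7% (peaks at E = 0.50 / 0.89)
modulator: n=138 molecules, active state 12.6 +- 0.5% (peaks at E = 0.50 / 0.89)
```

i.e. the fitted two-Gaussian populations recover the simulated 26.5% → 11.2%
active-state suppression to within ~1 percentage point, with the state peaks
at the true efficiencies (0.5 and 0.9). `05` prints the cluster comparison:

```
treated: 571 clusters over 8 images, mean size 2.62
vehicle: 587 clusters over 8 images, mean size 1.67
vehicle vs treated: Mann-Whitney U = 146542, p = 7.89e-06 (***)
```

— the treated condition's larger nanoclusters are detected as a highly
significant shift in the cluster-size distribution.

A `smfretglue` command-line interface wraps the same library for ad-hoc use:
`smfretglue run|simulate|extract|qc|analyze|clusters --help`.

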