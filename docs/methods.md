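# Methods

## Signal model

A labeled molecule in conformational state *s* with FRET efficiency
E_s transfers a fraction E_s of its excitations to the acceptor. With a
per-molecule detection/quantum-yield imbalance γ, the expected
background-free intensities are

    Ia = E_s · I_tot                (acceptor channel, before leakage)
    Id = (1 − E_s) · I_tot / γ      (donor channel)

This convention has three exact consequences the tests rely on: the corrected
estimator Ia/(Ia + γ·Id) returns E_s; the γ-weighted total γ·Id + Ia equals
I_tot through both state transitions *and* acceptor photobleaching (it drops
only when the donor dies); and the standard bleach-step estimator
γ = ΔIa/ΔId at the acceptor bleach is exact on noise-free traces. Donor
leakage adds α·Id (default α = 0.07) to the raw acceptor channel and is
subtracted, after background, before anything else.

Conformational dynamics are a continuous-time Markov chain sampled at the
frame period (100 ms). By default two states at E = 0.5 (active, the larger
helix separation) and E = 0.9 (inactive) exchange with rate constants
k_ij = k_ex·π_j, which makes the stationary distribution exactly the
configured occupancies. The default exchange rate k_ex = 4 s⁻¹ (dwells of
roughly 0.3 s active / 1 s inactive at 25/75 occupancy) is the regime in
which anticorrelated donor/acceptor fluctuations are actually resolvable at
the configured signal-to-noise: slower exchange produces too few transitions
per trace for the differenced-series correlation to rise above shot noise,
which would make the anticorrelation selection criterion vacuous. Slower
regimes (0.5 s⁻¹ each way) are exercised explicitly by the dwell-time
recovery tests.

Photobleaching is single-step exponential per fluorophore. The acceptor's
bleach clock runs only while it is excited (via FRET, i.e. while the donor
lives); defaults are 30 s (acceptor) and 120 s (donor) against an 80-s
donor-excitation window followed by 1 s of direct acceptor excitation. Noise
is Poisson on expected counts plus additive Gaussian read noise; the default
read noise (σ = 75 counts on a 1000-count molecule over a 100-count
background) puts the median trace SNR near 8. Contaminant classes: donor-only
(no acceptor, direct-excitation dark), acceptor-only (dark during donor
excitation, bright under direct excitation), and aggregates (2–3 independent
donor–acceptor pairs superimposed, producing multi-step bleaching).

Movie rendering places molecules as σ = 1.2 px Gaussian spots with a minimum
separation, maps acceptor positions through a known donor→acceptor affine
(so registration is testable against truth), renders the direct-excitation
segment as acceptor-survival intensity, and adds per-pixel Poisson noise plus
camera read noise (10 counts/px by default — a pixel-scale quantity distinct
from the trace-scale read noise). Noise-free registration images with every
spot bright accompany each movie.

## Imaging

Spots are strict local maxima within a 5×5 px window above
background + 5 robust spreads (median/MAD); on noise-free images a small
fraction of the dynamic range substitutes for the spread. Sub-pixel positions
come from log-parabolic interpolation through the 3×3 peak neighborhood
(exact for a sampled Gaussian), falling back to a windowed centroid. The
detection image averages the first 100 donor-excitation frames: donor spots
of high-FRET, high-γ molecules peak at only a few counts, and shorter
averages would miss them selectively — a FRET-state-dependent selection bias
the QC invariants forbid. Registration seeds nearest-neighbor fiducial
matching with a phase-correlation shift and fits the acceptor→donor affine by
least squares (≥ 3 non-collinear matches required). Pairing is greedy
nearest-neighbor within 2 px in the donor frame; unmatched donor spots are
flagged donor-only and excluded. Traces are aperture sums (7 px diameter
default) with per-frame background = median of the 35-px-diameter local
region outside the aperture (pixels near other detected spots excluded),
scaled to the aperture area; molecules whose background region leaves the
image are skipped as "edge", molecules with a neighbor inside one aperture
diameter as "crowded".

## Corrections and bleach annotation

Change points of each channel are found by penalized least-squares
segmentation (optimal partitioning with PELT pruning; penalty
3·σ²·log n, σ from median absolute frame differences /√2; minimum counted
step 3σ). The acceptor bleach frame is the last downward step whose terminal
level is consistent with zero.

Counting *bleach steps* in the presence of FRET dynamics needs an
operational rule, since a high→low transition immediately before the terminal
bleach is, in hindsight, never reversed. A downward step counts as a bleach
rung when it is large, permanent (the pre-step level is never regained), and
either (a) terminal — all later levels stay at the post-step level, (b) set
in a monotone context with no earlier upward step (a clean staircase), or
(c) followed by further upward transitions at a permanently reduced ceiling —
the signature of losing one fluorophore of several while the rest keep
switching. For the donor channel, steps after the acceptor bleach lie outside
the dynamics regime, so permanence alone suffices there. This rule counts 1
for intact molecules regardless of dynamics, ≥ 2 for multi-fluorophore
staircases, and 0 for reversible transitions.

γ is estimated as ΔIa/ΔId across the acceptor bleach, with 50-frame windows
on each side excluding ±3 frames around the step; it is undefined (and the
molecule rejected) when the windows do not fit or the donor shows no
recovery. SNR is the mean pre-bleach total intensity divided by the standard
deviation of its high-frequency residual after subtracting a 5-frame running
median (noise-free traces report a large capped sentinel). Anticorrelation is
the Pearson correlation of the frame-differenced channels over the pre-bleach
segment.

## Selection criteria

Evaluated in order (first failure recorded as the reject reason; boundary
values pass inclusively): (1) SNR ≥ 5; (2) exactly one acceptor bleach rung,
strictly before any donor bleach (or no donor bleach); (3) 0.5 ≤ γ ≤ 2.5;
(4) r ≤ −0.3 on differenced traces for dynamic molecules — traces locked in
one state show no anticorrelated fluctuations and are judged instead by
opposite-sign intensity steps at the acceptor bleach; (5) at most one donor
bleach rung, applied only if the donor bleaches; and acceptor-identity
confirmation. Since the direct-excitation segment follows the 80-s donor
segment, a molecule whose acceptor bleached mid-movie cannot show direct
signal; an observed acceptor bleach therefore satisfies the identity check
(recorded not-applicable), and the direct-excitation threshold
(mean > background + 3σ) applies only when no bleach was seen.

Under these physics roughly 40% of intact molecules are rejected for bleach
*timing* alone — the acceptor must bleach between 5 s and 75 s with the donor
surviving 5 s longer for γ to be measurable — which is a property of
single-exponential photobleaching, not of the classifier; among molecules
with compatible timing, acceptance exceeds 95% and is unbiased across FRET
states, while contaminants are rejected at ≈ 99%.

## Histograms and populations

E is computed per pre-acceptor-bleach frame (frames within ±3 of the bleach
excluded; post-bleach E is undefined and never used). Values are binned into
30 half-open bins over [−0.25, 1.25] (last bin closed), normalized by each
molecule's in-range count, and averaged across molecules with equal weight;
per-bin SEM is the across-molecule SD/√n. The two-Gaussian model is fit by
bounded nonlinear least squares at bin centers with multi-start
initialization; components are ordered by mean and fractions are area shares.
Component widths are bounded at σ ≤ 0.2 by default: a conformational state's
peak width is set by shot noise (σ_E ≈ 0.05–0.1) plus modest heterogeneity,
and once σ is allowed to span half the physical E range the wide component
stops being a state and becomes a tail-correction — on simulated data such a
solution attains a *lower* residual while absorbing minority states, so the
bound is what makes small populations identifiable. When the two fitted
means are closer than half the larger width the split is not identifiable and
the fit collapses to a single component (second area reported as zero).
Fraction uncertainties come from a molecule-level bootstrap (resample
molecules, re-average, refit warm-started; default 200 replicates, seeded).
Idealization fits a two-state Gaussian-emission hidden Markov model
(hmmlearn) and takes the most probable path; a state split whose means are
closer than three times the frame noise is collapsed to a single static
state. Edge dwells are censored and excluded from dwell-time summaries. A
midpoint-threshold idealizer is available as a fallback mode.

## Nanoclusters

Clusters are single-linkage connected components at a configurable linkage
radius (default 100 nm ≈ 3× a nominal gold-label diameter; the radius is a
required, logged parameter and a sensitivity sweep is provided since no
unique operational definition of "cluster" exists). Sizes are pooled across
images within a condition, with per-image breakdowns retained; conditions are
compared by a two-sided Mann–Whitney U test on pooled sizes (exact null for
small tie-free samples, tie-corrected normal approximation otherwise;
Kolmogorov–Smirnov optional; per-image means available as a
pseudoreplication-safe alternative). Under the null the test rejects at the
nominal 5% rate on the simulated size distributions.

## Reproducibility and problem sizes

A single global seed fans out to per-stage sub-seeds by stable hashing of
stage names, and per-molecule generator sub-streams make outputs independent
of generation order; no output file carries a timestamp, so a rerun of a
serialized configuration is byte-identical. The shipped analyses use 300
molecules per trace condition, 50-molecule movies on 256×256 px fields, and
8 images per point-pattern condition — sizes at which the recovered
quantities sit well inside their statistical tolerances while the full chain
runs in minutes on one core.

## Limitations

The generator emulates the photophysics the selection criteria assume —
single-step bleaching, a single leakage term, linear camera response,
stationary dynamics — and real recordings violate some of these (triplet
blinking, drift, acceptor direct excitation during donor excitation,
non-uniform illumination, diffusing background). Passing tests therefore
demonstrate that the analysis recovers truth *under its stated model*, not
that the model exhausts real data. No drift correction, 3D localization,
ALEX-style β/δ corrections, kinetic rate inference beyond dwell summaries, or
spatial statistics beyond single-linkage counts are attempted. The
bleach-rung rule cannot, even in principle, distinguish an aggregate's
intermediate acceptor loss from a state transition when the remainder of the
trace carries no further dynamics; such aggregates are caught, if at all, by
the other criteria.
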