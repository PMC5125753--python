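# mrnatrack

Quantitative analyses for live- and fixed-imaging studies of mRNA
localisation in the *Drosophila* oocyte — built around the question of
how *bicoid*-class transcripts reach and stay at the anterior cortex:
by continuous directed transport, or by weakly biased random motor
transport followed by anchoring.

The package is aimed at quantitative cell biologists and image-analysis
scientists who have particle tracks, ROI photobleaching/photo-conversion
time courses, or super-resolution spot images, and want the published
analysis chain as tested, scriptable Python rather than a collection of
Fiji plugins and spreadsheets. Every estimator comes with a seeded
synthetic-data generator and ground truth, so the whole pipeline can be
validated end to end without any microscope.

## What it computes

**Track statistics** (`mrnatrack.tracks`). Per-track mean speed
(mean of frame-to-frame velocities), path length, direction from the
initial→final vector, distance from the anterior cortex, and the net
anterior displacement rate. Population level: anterior/posterior counts
overall and by distance bin (0–5, 5–10, >10 μm), angular windcharts, an
exact one-tailed binomial test of the anterior fraction against 50%, a
one-sample Wilcoxon test of net displacement, mobile fractions per 5 s
window, sustained-reversal frequencies, and speed comparisons by
Wilcoxon rank-sum or a mixed-effects model with oocyte/movie random
intercepts.

**Recovery kinetics** (`mrnatrack.kinetics`). FRAP and photo-conversion
curves are corrected for acquisition photobleaching calibrated on fixed
samples, I(t) = I₀·e^(−pt), then fitted to a bi-exponential with the
nonspecific half-time τ_NS held at its nurse-cell calibration
(2.0 min FRAP, 3.2 min photo-conversion):

    NI(t) = F_IM + C_NS·e^(−ln2·t/τ_NS) + C_RNA·e^(−ln2·t/τ_RNA)   (photo-conversion)
    NI(t) = 1 − F_IM − C_NS·e^(−ln2·t/τ_NS) − C_RNA·e^(−ln2·t/τ_RNA)   (FRAP)

The nonspecific component is removed, the RNA-only signal refitted to a
single exponential (immobile fraction and fluorescence half-time), and
photo-conversion data are compensated for MCP–MS2 dissociation
(k_off = 0.0017 min⁻¹, a 9% loss over 55 min). Curves are compared with
the extra-sum-of-squares F-test.

**Particle profiling** (`mrnatrack.profiler`). Intensity maxima are
detected with a prominence-style noise tolerance, X/Y line profiles are
fitted with Lorentzians B + A/(1 + ((x−x₀)/γ)²) — the effective STED
point-spread profile — and particle diameter is reported as the mean of
the two FWHMs (2γ·pixel size). Filters reject fits with r² < 0.8, axis
ratios above 2, edge contact and high local density; the accepted spots
feed summed-fluorescence quantification (background-subtracted sum over
the FWHM ellipse), nearest-neighbour statistics and mixed-model
size/intensity-versus-distance analyses.

**Colocalisation** (`mrnatrack.coloc`). Rolling-ball background
subtraction, the van Steensel cross-correlation function (Pearson r
versus integer pixel shift along an axis) and Costes block-randomisation
significance.

**Statistics** (`mrnatrack.stats`) and **synthetic data**
(`mrnatrack.simulate`) round out the toolkit, including 2^(−ΔΔCT) qPCR
fold changes.

## Worked example

`examples/01_track_directionality.py` simulates the wild-type tracking
condition (1181 tracks, 52.6% anterior bias) and tests the bias:

```
tracks analysed:        1181
mean speed:             0.79 ± 0.01 μm/s (mean ± SEM)
anterior-directed:      619 (52.4%)
one-tailed binomial p:  0.052
net displacement p:     0.025 (one-sample Wilcoxon)
```

The realised anterior excess in this random draw (52.4%) sits at the
detection threshold — exactly the regime the real data occupy: a bias
this weak cannot by itself concentrate the RNA anteriorly, which is the
quantitative argument for an anchoring step. The other examples cover
the kinetics pipeline (`02`), spot sizing (`03`), colocalisation (`04`)
and qPCR fold changes (`05`); each prints its numbers with a short
interpretation.

A thin CLI mirrors the library for shell use:

```
mrnatrack simulate tracks --seed 1 --out out/
mrnatrack track-stats --tracks out/tracks.csv --out stats/
mrnatrack profile-spots --image img.tif --pixel-nm 14.6 --out spots/
```

Every run writes a `manifest.json` (config, seed, versions) sufficient
to reproduce its outputs.

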