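# miisr

Quantitative analysis of molecular interactions and clustering in
single-molecule localization microscopy (SMLM) data.

Super-resolution techniques such as PALM, STORM and ground-state
depletion microscopy localize individual fluorophores with ~20 nm
precision, producing *molecular position tables* rather than conventional
images. Pixel-based colocalization and morphology tools fail on such
data: interacting molecules resolve into neighbouring pixels, and the
stochastic imaging process simultaneously misses fluorophores
(undersampling) and detects the same fluorophore repeatedly
(oversampling). `miisr` provides the spatial-statistics toolbox that
works directly on the position tables — for cell biologists asking
whether two labelled proteins interact, whether they form higher-order
assemblies, and where individual clusters are.

## What it computes

**Spatial association analysis (SAA).** For each molecule of channel A,
the Euclidean distance to its nearest neighbour in channel B. Molecules
closer than the *colocalization distance criterion*

&nbsp;&nbsp;&nbsp;&nbsp;CDC = m·σ_RMS + I_reg,&nbsp;&nbsp;
σ_RMS = √(Σᵢ σ_cᵢ²)

are potentially interacting, where σ_cᵢ is the mean localization
precision of channel *i*, I_reg the channel registration error, and
m ∈ {1.65, 2} a 90%/95% probability cutoff (typical two-colour CDC:
23–28 nm). The measured sub-CDC fraction is compared against *simulated
random positions* (SRP) — Monte-Carlo controls with one channel
uniformly randomized over the same region — so chance juxtaposition is
factored out. SAA is directional: A→B and B→A generally differ, which
itself carries stoichiometric information.

**Co-clustering statistics.** The cross-channel radial distribution
function G(r) (pair correlation; 1 under complete spatial randomness)
and cross-Ripley's K(r) with its variance-stabilized transform
H(r) = √(K/π) − r. The H peak radius r_max yields a mean cluster radius
via Lagache's r_max/1.3 or Kiskowski's half-the-radius where H′(r)
reaches −1.

**Cluster segmentation.** DBSCAN (core/edge/noise roles), OPTICS with
reachability-distance (RD) plot extraction — static RD threshold for
homogeneous densities, recursive hierarchical RD segmentation for mixed
densities and nested structures (e.g. intraluminal vesicles inside
multivesicular bodies) — plus Ripley-map thresholding (`h_segment`) and
convex-hull quantification of cross-channel cluster composition.

**Synthetic ground truth.** Generators for pair fields at exact
separations, clustered fields, over-/under-sampling artefacts, and a
frame-wise acquisition simulator with an autocorrelation-based
reconstruction stop-point — so every analysis can be validated against
known truth without microscope data.

## Worked example

`python examples/saa_pair_field.py` builds 5,000 molecule pairs 10.2 nm
apart (emulating annealed Cy3/Cy5-labelled 30-bp DNA duplexes), with 50%
excess unpaired B molecules and 20 nm-precision jitter on both channels:

```
CDC = 46.67 nm (1.65 x sqrt(20^2 + 20^2))
A -> B: fraction below CDC = 1.000, SRP (random) = 0.510, histogram mode = 11.0 nm
B -> A: fraction below CDC = 0.793, SRP (random) = 0.375, histogram mode = 11.0 nm
```

Every A molecule has a partner, so A→B association is total and far
above the 0.51 expected by chance; B→A is diluted by the unpaired excess
— the directional asymmetry quantifies the unannealed fraction. The
histogram mode (2 nm bins) recovers the true 10.2 nm separation to
within one bin. The other example scripts cover co-clustering statistics
(`clustering_statistics.py`), nested-cluster segmentation
(`optics_segmentation.py`), the reconstruction stop-point
(`acquisition_stop_point.py`) and file conversion plus batch queues
(`convert_and_batch.py`).

A thin CLI mirrors the batch workflow:

```bash
miisr convert raw.txt --dialect leica_gsd --px-nm 100
miisr saa A.tsv B.tsv --cutoff 1.65 --randomizations 20 --seed 1
miisr cluster A.tsv --algo optics --min-size 20
miisr run queue.yaml
```

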