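# Methods

This note documents the measurement models, the defaults and why they were
chosen, the synthetic-data generators and their limits, and the numerical
decisions made where the procedures left room.

## Image quantification (`puncta`)

**Thresholding.** Each channel of a field is binarized at its whole-image
mean plus standard deviation, with strict `>` for mask membership. The SD is
the population flavor (divide by n), matching histogram-based image
statistics; a sample-SD switch exists (`sample_sd=True`). The statistics are
computed over the full field — one neuron per field — rather than within the
neuron mask; with a bright cell fill and dense marker staining the two
readings give nearly identical masks, and the whole-field reading needs no
prior segmentation.

**Triple colocalization.** Connected components (8-connectivity by default,
4 available) of the pixelwise AND of the cell-fill, presynaptic and
postsynaptic masks; every component of at least one pixel counts once.
Because mean and SD both scale linearly, multiplying all channels by a
constant leaves the masks — and therefore the counts — unchanged.

**Soma segmentation.** The procedure the counts depend on (cell-fill mask
minus cell body vs. cell body alone) needs a soma outline that manual
workflows draw by hand. The heuristic used here is a morphological opening
with a disc (default radius 5 px), keeping the largest surviving component:
a disc that is wider than any dendrite erases them and preserves the soma.
A supplied soma mask always overrides the heuristic. Discrete opening can
retain one or two pixels of a dendrite root at the soma junction; the tests
treat pixels within 2 px of the soma boundary as junction territory.

**Densities and normalization.** Densities are reported per µm² using the
pixel size (raw pixel areas are also available in the records). Within each
experiment the mean density of every condition is divided by that
experiment's control mean, so the control normalizes to 1 and
experiment-to-experiment staining and culture-density variation cancels.

**Sholl profiles.** Circles (default 11, spaced 10 µm) are rasterized at
1 px line width with pixels ordered by angle, so connected runs of skeleton
pixels along a circle — with circular wrap-around — are its dendrite
crossings. Circles extending past the image are counted over the in-image
arc and flagged.

## Event detection (`ephys`)

**Envelope.** Sliding-window RMS of the mean-subtracted trace, centered,
with edge windows truncated. The envelope operation defaults to a 10 ms
window; UP-state *detection* uses a 50 ms window by default because with a
10 ms window the within-event envelope fluctuates enough (relative SD
≈ 0.7 for 100 Hz-band activity) to fragment epochs below the 100 ms minimum.

**UP-state rules.** Candidate epochs are maximal runs of envelope >
threshold. Runs shorter than 100 ms are discarded first; surviving runs
separated by at most 600 ms are then merged (equivalently, an event ends
only once the envelope stays below threshold for more than 600 ms). The
order — minimum duration before merging — is configurable via the two
duration parameters and is the documented default. Durations convert to
sample counts by rounding half up, and "at least 100 ms" means at least that
many samples. A run still open at the record end is emitted flagged
truncated. Event amplitude is the mean envelope during the event (peak
available). A vectorized run-length implementation is validated exactly
against a per-sample state machine (`synquant.reference`).

**Automatic threshold.** The threshold is median(envelope) + 5 × 1.4826 ×
MAD(envelope). Median/MAD statistics ignore the event epochs as long as
events occupy well under half the record, so the threshold is stable on
event-rich traces; at 5 scaled MADs the false-event rate on baseline noise
is negligible while events of ≥ 3× baseline RMS clear it comfortably. An
earlier candidate — mean + 3 SD of the envelope's lower quartile — sits only
≈ 1 SD above the baseline mean and admits ≈ 100 ms noise runs, so it was
rejected. A flat envelope has no baseline scale and raises instead of
guessing.

**Mini detection.** The trace is oriented so events are positive (inward
events recorded at −70 mV deflect negative and are flipped). The local
baseline is a running median over 500 ms — long relative to a single
transient (≈ 45 ms for the default 1 ms rise / 8 ms decay kinetics), so the
median is not dragged into the event; at a 50 ms window the baseline bias
alone costs ≈ 5% of amplitude. Candidate peaks are local maxima of the
residual smoothed over 2 ms, at least 7 pA high and 5 ms apart; consecutive
candidates with no trough below 50% of the smaller peak between them ride on
one transient (noise ripple on a decay) and are collapsed onto the larger
peak. Amplitude is the raw baseline-subtracted value at the peak — the 2 ms
smoothing shifts the peak location by well under the transient's flat top,
so the raw read is unbiased to < 1% while avoiding the upward max-of-noise
bias of reading a raw local maximum. Onset/offset are the last/first
crossings of 10% of the peak (offset capped at the next event's onset); the
area between them, in pA·ms, must reach 10 pA·ms. The 10% boundary and the
integration rule are this package's choices; only the two thresholds are
inherited from the commercial tool's documented settings.

**Summaries.** UP-state frequency is events/min (the field reports 10-min
records); mini frequency is Hz. Means are reported as absent for empty
records rather than NaN-propagated.

## Gene-set statistics (`genesets`)

RPKM is `1e9 · count / (length_bp · library_size)`. The expression filter
keeps genes whose *group-mean* RPKM exceeds 0.5 in at least one group
(strict `>`); a per-sample variant is available. DEG calls require
|log2FC| > 0.3 and FDR < 0.05, both strict; the differential-expression
engine itself is pluggable input (per-gene log2FC and raw p or FDR), not
re-implemented.

Overlap testing intersects both sets with the explicit background universe
first (genes off-background are dropped and flagged), uses the
over-representation tail only, and BH-adjusts across the family of external
sets tested against one internal set. Both raw and adjusted p-values are
reported. Permutations re-draw the external set from the background or the
internal set from the expressed universe, uniformly without replacement,
with `p = max(m, 1)/B` — a zero-exceedance result reports `1/B`, never 0.
Gene symbols are uppercased and de-duplicated; no ortholog mapping is
attempted (mixing species symbol conventions is the caller's
responsibility).

## Synthetic data (`synthgen`)

**Images** (default 256×256 px at 0.5 µm/px): a neuron as a filled soma disc
(radius 10 px) with 4–6 straight 3 px-wide dendrites, a bright cell fill
(1500 on a 200-count camera baseline), and Gaussian puncta (σ = 1.5 px, peak
500). Colocalized puncta occupy identical coordinates in both marker
channels inside the neuron; single-channel puncta sit on the neuron; 500
distractor puncta per marker channel — synapses of unlabeled neighbors —
are scattered strictly off the cell. The distractors are what give the
marker channels a realistically signal-dominated histogram: a mean+SD
threshold then sits ≈ 3.5 noise SDs above background, as it does in real
stained fields, rather than ≈ 1 noise SD as it would over pure noise. The
default noise SD of interest is 50, i.e. 10% of the puncta peak. On-cell
puncta keep a pairwise spacing of 8 px; impossible packings raise rather
than silently overlap. Intensities are quantized to the 16-bit integer
grid. A separate `geometry_seed` lets paired conditions share one neuron
shape so that planted density ratios are exact by construction.

Not emulated: z-stacks (fields are already projections), uneven
illumination, shot-noise scaling with intensity, realistic dendrite
morphology or spines, antibody background gradients. Passing tests
demonstrate that the measurement rules recover known truth under controlled
conditions, not that they are robust to every real-world artifact.

**Extracellular records** (2.5 kHz): epochs of white noise low-pass filtered
at 100 Hz and rescaled to the requested RMS amplitude, added on broadband
baseline noise; epochs placed with at least 2 s gaps (or given explicitly).
Default study condition: five 1 s epochs at amplitude 5× the noise SD in a
60 s record.

**Voltage-clamp records** (10 kHz): biexponential transients (unit peak,
1 ms rise / 8 ms decay) at homogeneous-Poisson times, amplitudes from a
constant, truncated-normal or lognormal law, inward polarity by default.
Default study condition: 1 Hz events at 20 ± 3 pA with 4 pA noise (SNR 5).

**Gene universes**: at enrichment factor exactly 1 the external set is a
uniform draw from the background (a true hypergeometric null); otherwise
`factor × nK/N` overlap genes (stochastically rounded) are planted, erroring
when the request exceeds the smaller set. **Count matrices**: negative
binomial with mean proportional to gene length and variance
`μ + φμ²`; dispersion below 1e-8 falls back to Poisson.

## Pipeline and formats

Configs are plain YAML validated against an explicit schema — unknown keys
are rejected by name — and every seed is explicit. Outputs are tab-delimited
UTF-8 with '.' decimals and fixed column order; floats are written at full
precision so that write→read round-trips are lossless and repeated runs are
byte-identical (the run manifest records a sha256 per output and the config
hash; its timestamp is informational). Images travel as multi-page 16-bit
TIFF with channel roles in the description tag; traces as two-column
(time_s, value) text with a JSON sidecar; gene sets as GMT; ground truth as
JSON (masks run-length encoded). Exit codes: 0 success, 2 validation error,
3 stage error.

## Benchmark problem sizes

The validation benchmarks (`synquant.benchmarks`, used by the tests and by
`scripts/acceptance.py`) use: 1000 random envelopes for the detector-vs-
oracle comparison; 120 s noise-free and 300 s SNR-5 voltage-clamp records;
50 noise-free plus 50 noisy image fields; exhaustive enumeration of every
overlap universe with background ≤ 12; 50 permutation seeds at 100/1000/
10000 replicates on a fixed universe; and 10 image fields per condition for
the planted 2.0 density-ratio experiment. These sizes give Monte-Carlo error
comfortably inside the stated tolerances while the whole battery runs in
well under a minute of compute.

## Known limitations

- The soma heuristic assumes a roughly convex soma wider than any dendrite;
  irregular somata should be outlined manually and supplied as a mask.
- Colocalization is 2-D (projection-based); genuinely 3-D appositions can
  merge or split in projection.
- Mini detection does not fit kinetics and deliberately merges transients
  with no intervening trough, so genuinely superposed events within a few
  milliseconds are reported as one compound event.
- The permutation machinery draws sets uniformly; it does not model
  expression-matched or length-matched null sets.
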