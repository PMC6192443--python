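# Methods

## Scope and model

`proglu` infers a residue-level proline→glutamate conversion from
centroided bottom-up LC-MS/MS data. The analysis treats the conversion
as an ordinary dynamic modification of +31.98983 Da on proline (two
oxygen atoms; stored at full precision, displayed as +31.990) and
establishes it in four stages: modification-aware peptide-spectrum
matching with target-decoy FDR control, fragment-level site
localization, co-elution verification of the modified/unmodified
precursor pair, and XIC-based occupancy estimation. All masses are
monoisotopic; charging uses the proton mass (1.007276 Da), which
reproduces the printed two-decimal m/z values of the signature pair
(698.33 / 714.33 at z = 2).

## Modification registry

Shipped entries (Da, monoisotopic): Carbamidomethyl +57.02146 (C,
fixed), Oxidation +15.99491 (M and P by default; restrictable to M),
Deamidation +0.98402 (N, Q), Pro>Glu +31.98983 (P), Arg>Glu −27.05852
(R), Pro>GSA +15.99491 (P), Arg>GSA −43.05343 (R). At most one dynamic
modification per residue position and at most three per peptide (a
common search-engine convention; the cap is configurable). The registry
serializes to a plain-text table with deltas at five decimals.

## Digestion and decoys

Trypsin cleaves C-terminal to K/R except before P. Defaults: up to 2
missed cleavages (a standard bottom-up choice; the underlying protocol
does not state one) and minimum peptide length 5. Protein coordinates
are 1-based inclusive, so a shift at peptide position p maps to protein
residue start + p − 1 (peptide DFTPVCTTELGR at 42–53 puts its proline
at residue 45). Decoys are whole reversed proteins digested afresh,
which preserves cleavage-site statistics better than per-peptide
reversal; accessions carry the `DECOY_` prefix. Initiator methionine is
not specially trimmed.

## Search and FDR

Candidates are indexed by neutral mass; an MS2 scan is scored against
every form within 15 ppm of its declared precursor at its declared
charge (no charge re-guessing). Fragments are singly charged b/y ions;
doubly charged fragments can be enabled for z ≥ 3 precursors. Matching
is greedy nearest-m/z within 0.05 Da, one observed peak per theoretical
ion, ties broken toward the higher-intensity peak. The score is a
hyperscore-style statistic, ln(b!) + ln(y!) + ln(1 + matched intensity
sum); it is deliberately not a SEQUEST XCorr re-implementation —
nothing downstream depends on the score's absolute value, only on its
ranking, which the target-decoy calibration absorbs. Rank-1 PSMs per
scan get q-values by the standard recipe (sort by score, running FDR =
decoys/targets with 0/0 → 0, cumulative minimum from the bottom), and
targets with q ≤ 0.01 survive. FDR is controlled at PSM level; the
report states this and the tests verify the empirical false proportion
among survivors stays ≤ 3% on ground-truth runs.

## Site localization

For a PSM carrying exactly one dynamic mass shift, every placement on a
same-target residue is evaluated. Site-determining ions are the b/y
ions whose m/z differs between placements (for a sole target residue,
every ion containing it). The stated site is *localized* when (a) at
least one matched site-determining ion lies on each flank that has one
— b-series on the N-terminal side, y-series on the C-terminal side; a
site so close to a terminus that one series cannot cover it is decided
by the existing flank — and (b) its total matched site-determining
evidence strictly exceeds every rival placement's. Rivals are compared
by strict dominance rather than required to have zero matches, because
within a 0.05 Da tolerance a rival placement occasionally picks up a
coincidental cross-series match (e.g. an unshifted b7 falling within
tolerance of an observed y6); such coincidences must not veto a fully
bracketed site. Ties are always reported as ambiguous, never broken
silently. The minimum per-flank evidence (default 1) is configurable.

This is deliberate evidence counting rather than a probabilistic
A-score: the scientific argument the pipeline reproduces is exactly
this ion-ladder bracketing. Every site report carries the mandatory
isobaric caveat that +31.990 Da at proline cannot distinguish glutamate
conversion from dihydroxyproline.

## Co-elution and occupancy

XICs sum MS1 intensity within ±15 ppm of the target m/z per scan,
within a ±1.5 min window around the identifying PSM. The apex is the
maximum after 3-point moving-average smoothing (stabilizes the apex
under shot noise without biasing symmetric peaks); the area is the
trapezoid over the trace. The pair passes QC when the apex shift is
below 0.2 min; an undefined apex fails with the reason recorded.
Occupancy is 100·A_mod/(A_mod + A_unmod) from MS1 areas — "ion
intensity" is read as MS1 signal, and an apex-intensity ratio is
available as a config switch. One charge state (the identified one) is
quantified per pair by default. Replicate aggregation reports the
arithmetic mean and sample (n−1) SD over QC-passing runs, with QC
failures counted in the summary.

The method's core assumption is equal ionization: converted and
unconverted peptides are taken to respond identically, so the XIC area
ratio equals the molecular ratio. Occupancy is reported per run; both
areas zero yields an explicitly flagged undefined estimate.

## The simulator

The generator emulates the acquisition the pipeline is designed for: a
60-min gradient, MS1 scans over m/z 300–2000 every 2 s, top-15
data-dependent selection among multiply charged (z ≥ 2) signal
precursors above an intensity floor, and 20 s dynamic exclusion
(re-selection of the same m/z within the window is suppressed; the test
suite asserts this). Peptides from a tryptic digest get a uniform
random apex within the gradient's central 76% and a log-uniform
abundance (2×10⁶–2×10⁷ area units); elution is Gaussian with 12 s FWHM,
integrating analytically to the abundance. A site-bearing peptide's
abundance is split between unconverted and converted forms by the
stated occupancy with an exactly shared apex. MS1 peaks are
monoisotopic only, with 3 ppm m/z jitter, 15% multiplicative intensity
CV (shot noise), and ~50 uniform noise peaks per scan; MS2 spectra are
b/y ladders with 0.01 Da jitter (≤ tolerance/3), 10% per-ion dropout
and ~10 noise peaks. Every draw comes from one seed; identical configs
give byte-identical manifests and peak lists.

What it does **not** emulate: isotope envelopes (the pipeline
quantifies monoisotopic XICs), peak tailing, chimeric spectra,
retention-time dependence on sequence, charge-state distributions, or
ionization suppression. Passing tests therefore demonstrate the
*inference machinery* — identification, localization, co-elution QC and
occupancy arithmetic recover planted truth under realistic tolerances
and noise — not robustness to every artefact of real instrument data.
In particular the equal-ionization assumption is true by construction
in simulation and only approximately true in reality.

The bundled demo protein is synthetic: 224 deterministic pseudo-random
residues with DFTPVCTTELGR placed at 42–53 so that the proline-45
coordinate arithmetic is exercised. It is not the real Prx6 sequence
(substitute UniProt P30041 for real-data work).

## Numerical choices

- Fragment/peak coincidences closer than 1e-9 m/z are merged
  (intensity-summed) to keep centroid lists strictly increasing.
- Deterministic tie-breaks everywhere a ranking exists: PSM selection
  prefers higher score, then more matched fragments, then smaller
  |ppm|, then target over decoy, then lexicographic identity; scoring
  is invariant to peak and scan order.
- FDR running estimate uses 0/0 → 0; empty inputs give empty outputs
  rather than errors.
- XIC of an absent target: area 0, apex NaN, flagged downstream.
- Degenerate aggregation (N=1) reports SD as NaN, never 0.

## Problem sizes

The test suite and acceptance script run entirely on simulated data:
six-replicate occupancy recovery on full 60-min runs of the one-protein
demo database (~1800 MS1 scans per run), 200-trial localization
ensembles, and a 550-spectrum FDR ensemble over a 12-protein random
database with decoys. These sizes give stable statistics for the
properties checked while keeping the whole suite fast on a single CPU.

## Known limitations

- PSM-level (not peptide-level) FDR; protein inference is out of scope.
- No open/wide-window search, no retention-time prediction, no
  machine-learned rescoring.
- Single-charge-state quantification by default; no isotope-envelope
  deconvolution.
- Localization cannot, by construction, distinguish Pro→Glu from
  dihydroxyproline; orthogonal chemistry is required.
- The mzML writer emits the minimal standards-conformant subset the
  reader and third-party readers need (64-bit arrays, no compression);
  it is not a general-purpose mzML library.
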