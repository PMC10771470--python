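# Methods

## Scope and data model

The package analyses centroided MS/MS spectra from a strain × activator ×
media fermentation screen. A `Spectrum` carries precursor m/z, retention
time (minutes), and peaks sorted by ascending m/z; duplicate m/z values are
kept distinct. Each spectrum references an extract, and extract metadata
(strain, activator or WT, medium, clone, origin) travels in a separate CSV
keyed by `extract_id`. Total ion current (TIC), the sum of fragment
intensities, is the yield proxy throughout.

## Spectral filtering

Background correction removes fragment peaks below 1000 intensity counts;
the comparison is `>=` so a peak at exactly the threshold survives, and
spectra emptied by the filter are dropped and counted. Two further filters
run before any similarity scoring, in fixed order: (1) all peaks within
±17 Da of the precursor are deleted (inclusive boundary), removing residual
precursor signal; (2) a peak is kept only if it ranks among the 6 most
intense within ±50 Da *of its own m/z*. The window is anchored on the peak
being judged — the anchor is a genuine convention choice, and the
self-anchored form is the one that makes the filter idempotent and
order-free. Ties in the intensity ranking break toward lower m/z, so output
is deterministic. Note the self-anchored rule guarantees each survivor is
outranked by fewer than k peaks in its own window; it does *not* bound the
number of survivors inside an arbitrary ±50 Da interval, since two survivors
100 Da apart can flank a third.

## Modified cosine

Candidate peak pairs are those within 0.02 Da directly, plus — when the
precursor mass difference Δ exceeds the tolerance — pairs with
|mzA − mzB − Δ| ≤ 0.02 Da ("shifted", which is what lets homologous analogs
score highly). Intensities are weighted by the 0.5 power (the classical
networking convention; the exponent is a parameter, and at 1.0 the score
matches `matchms.ModifiedCosine` to machine precision, which serves as an
independent cross-check in the tests). A one-to-one matching is selected
greedily by descending weighted-intensity product with ties broken by lower
m/z; arguments are first put in a canonical order so the score is exactly
symmetric. The score is the matched product sum over the product of
Euclidean norms of the weighted intensity vectors, so self-similarity is
exactly 1. Greedy selection can in principle be suboptimal;
`exact_cosine_score` solves the same matching as a maximum-weight linear
assignment (SciPy LAP) and the test suite and acceptance script verify
≥ 99% exact agreement on random small-spectrum suites. Zero-norm spectra
score 0 with a warning rather than raising.

## Networking and scaffolds

All node pairs with cosine ≥ 0.7 **and** ≥ 6 matched peaks are candidate
edges; an edge is kept only if each endpoint is among the other's top-10
candidates (ranking by cosine, then matched count, then node id). Thresholds
are inclusive: the screen's own definition of unique scaffolds as having
"< 0.7 and < 6" similarity to each other is the complement of the inclusive
edge rule, and the library-match rule ("at least 6") uses it explicitly.
Molecular-family size is unbounded. Networking runs on consolidated unique
metabolites, one representative spectrum each (highest TIC), rather than on
raw per-extract spectra — consolidation plays the role of the hosted
workflow's unstated spectral-clustering stage. Connected components of ≥ 2
nodes are clusters, singletons are orphans, and clusters + orphans are the
unique scaffolds.

## Consolidation and yields

Spectra are merged into unique metabolites by greedy centroid clustering:
processed in descending TIC (ties by id), each spectrum joins the
earliest-founded metabolite whose running mean precursor and RT are within
0.02 Da and 0.4 min, else founds a new one; means update incrementally.
The greedy TIC-ordered seed rule is a determinism choice — the tolerance
rule alone does not define a unique partition, and TIC ordering makes the
result invariant to input order. The yield matrix takes the highest member
TIC per (metabolite, extract), zero when absent. Group yields (wild-type vs
mutant) take the max over media within strain then over strains, which
equals the flat max over group extracts (property-tested identity).

## Provenance, fold change, perturbation flags

Detection defaults to any nonzero consolidated yield (background filtering
already applied); an MS1-style stricter predicate (e.g. ≥ 10⁵) is available
via `detection_threshold`. Metabolites split into native-only,
activated-only, and both; fold change = mutant max / wild-type max is
defined only on "both" (zero wild-type yield raises — such metabolites
belong in activated-only). The distribution uses unit-width bins `<1, [1,2),
[2,3), [3,4), ≥4`; only the outer bins are fixed by the screen's reporting
convention, interior bins are a configurable choice. A mutant extract counts
as perturbed when it shows any metabolite undetected in the parent extract
of the same medium, or any shared metabolite with yield ratio strictly > 1
(ratio exactly 1 is unperturbed); with replicate parents the comparison uses
their elementwise max profile.

## Coverage curves

For 1–8 conditions (media or regulators), all C(n, k) subsets are
enumerated; a subset's coverage is the size of the union of its item sets
over the global union, ×100. Mean and **population** SD (ddof = 0) are
reported per k, since every subset is enumerated — a census, not a sample.
Curves are monotone in the mean and end at exactly 100%.

## Bioactivity differences

Six assays (A549 cytotoxicity; SA, EA, PA, ACB antibacterial; AF
antifungal), % inhibition, values outside [0, 100] allowed. Per
activator-strain combination: Difference = max over clones × media of mutant
inhibition − max over media of native inhibition. The palette interpolates
linearly in RGB between dark grey (0.3, 0.3, 0.3) at −100, white at 0 and a
named assay colour (brown/red/purple/blue/green/orange) at +100, clamping
outside ±100. Linear RGB with named set-points is a rendering choice; the
set-points themselves are the screen's convention.

## Mass calculation

Monoisotopic masses are summed from an embedded IUPAC table (≥ 6 decimals).
[M−H]⁻ subtracts a proton, not a hydrogen atom — the electron stays with
the anion — matching high-resolution "calcd" values at 4-decimal precision
(round-trip identity property-tested to 1e−6 Da). [M+H]⁺ and [M+Na]⁺ are
provided through the same adduct table.

## Synthetic study generator

The generator emulates the screen's structure, not its chemistry. Choices
that matter:

* **Spectra.** Each scaffold has 10 backbone fragments with a shared
  intensity profile (5×10⁴–5×10⁵ counts, per-analog log-normal variation
  σ = 0.15); each analog shifts the high-mass half of the backbone by its
  offset (multiples of 14.05 Da, a grid-aligned CH₂-homolog step) and adds 3
  analog-specific fragments at 2×10³–2×10⁴ counts. All m/z values sit on a
  0.05 Da grid so the 0.02 Da tolerance can never produce ambiguous
  half-matches; within-scaffold backbone spacing is ≥ 17.05 Da and the
  shifted set is a mass-ordered suffix, which keeps every inter-peak gap
  ≥ 17.05 Da — so any ±50 Da window holds at most 6 backbone peaks and the
  top-6 window filter provably never deletes a backbone fragment
  (analog-specific peaks are strictly less intense). Analog pairs therefore
  share all 10 backbone fragments (direct + shifted matches) while distinct
  scaffolds share none, and default networking recovers the scaffold
  partition exactly at zero noise.
* **Study design.** Defaults: 26 scaffolds × 4 analogs = 104 metabolites
  programmed as 50 shared / 5 native-only / 49 activation-only, i.e. an
  activated/native expansion ratio of 99/55 = 1.8; 6 strains × 3 activators
  × 3 media, 2 mutant clones plus one parent replicate per (strain, medium)
  — 126 extracts, ~1,700 scans, chosen to keep a full pipeline run in
  seconds. Each metabolite is produced by 2 strains in a random 1–3-media
  subset with probability 0.9 per eligible extract; activation-only
  metabolites are tied to one trigger activator, native-only metabolites are
  suppressed in all mutants; shared metabolites get a per
  (metabolite, strain, activator) log-normal upregulation factor (median 2,
  σ = 0.8).
* **Noise.** Spectrum-level log-normal intensity noise at CV 0.1; RT and
  precursor jitter are truncated normals with SD 0.1 min / 0.005 Da clipped
  at twice the SD, i.e. at half the consolidation tolerances, which
  guarantees the true partition stays recoverable. Bioactivity: baseline
  uniform 0–15% inhibition, plus a 40–90-point potency in one assay for each
  of 10 designated activation-gained metabolites.
* **Determinism.** One `numpy` Generator seeded from `seed` drives every
  draw in a fixed order; the emitted `ground_truth.json` records all
  programmed answers, so any run is replayable.

What the generator does **not** emulate: real fragmentation chemistry,
chromatographic peak shapes, co-elution/chimeric spectra, ionisation
suppression, media-blank contaminants, or the hosted workflow's internal
spectral clustering. Passing the recovery tests therefore shows the
statistics are implemented correctly and are robust to the modelled noise —
not that real screens will be recovered this cleanly; in real data
consolidation drift and chimeric spectra are the dominant failure modes.
With the default design every scaffold appears in every medium, so
scaffold-level coverage curves sit at 100% from k = 1; the metabolite-level
curves carry the media structure.

## Problem sizes and tolerances

The validation suite runs the full study at its default size (three seeds
for recovery claims), 1,000-pair similarity-oracle suites, and exhaustive
enumeration oracles on ≤ 6-peak spectra and ≤ 8-condition coverage
instances. Score agreement with the assignment oracle is asserted at 1e−9;
consolidation and provenance recovery are asserted exactly at zero noise;
fold-change recovery at noise CV 0.1 is asserted at < 15% median absolute
relative error and expansion-ratio recovery within ±10% (observed: ~8% and
~1–3% respectively).

## Known limitations

* Greedy matching is not globally optimal (bounded, not eliminated, by the
  assignment oracle).
* Consolidation is order-dependent by design (deterministic via TIC
  seeding) and, like any centroid-drift rule, can split slowly drifting
  features — the likely source of the small re-identification losses such
  workflows report on real data.
* The mutual top-k rule is evaluated on thresholded candidates only, so
  `top_k ≥ n` reduces exactly to the thresholded graph.
* Coverage enumeration is exact and intentionally capped at 8 conditions.
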