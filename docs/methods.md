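# Methods

## The measurement model

A blue-native gel lane separates intact protein complexes by size; cutting
it into S slices (default S = 60, slice 1 = gel top = largest complexes)
and identifying peptides per slice by LC-MS/MS yields, for every protein,
a vector of identification evidence along the size axis. We quantify that
evidence with the exponentially modified protein abundance index,

    emPAI(s) = 10^(N_obs(s) / N_observable) − 1,

with two deliberate conventions:

* **The denominator is a whole-protein property.** `N_observable` counts
  distinct fully cleaved (0 missed cleavages) tryptic peptides whose m/z at
  some allowed charge (1+–3+) lies in the scan range m/z 450–1800, with
  cysteines carbamidomethylated (+57.021464 Da, the usual fixed
  modification). Variable methionine oxidation is ignored for
  observability. The missed-cleavage convention for the denominator is
  exposed (`DigestionParams.missed_cleavages_observable`) because search
  engines tolerate up to two missed cleavages in the *numerator* while the
  original emPAI validation used fully cleaved peptides in the
  denominator; per-slice ratios above 1 (emPAI > 9) are therefore possible
  and harmless for profile shape.
* **The numerator is per slice** and counts distinct peptide *sequences*
  (charge states and scores do not multiply evidence).

emPAI(n, n) = 9 exactly; emPAI is strictly increasing in the numerator and
decreasing in the denominator. A protein with identifications but zero
observable peptides is contradictory under the configured instrument
window; `compute_empai` raises, and the table builder can instead drop the
protein with a warning (`strict=False`) so one stray row cannot abort a
run.

Molar percentages divide each protein's summed-over-slices emPAI by the
dataset total (×100); they sum to 100 by construction and are invariant
under rescaling all emPAI values.

## Digestion

Trypsin cleaves after K or R, not before proline (the proline rule is on
by default and toggleable, matching the common search-engine definition).
Peptides carry exact parent coordinates and spanned-site counts; with k
fully cleaved fragments, the number of products with at most m missed
cleavages is Σ_{j=0..min(m,k−1)} (k−j), which the test suite checks
against an independent substring-enumeration oracle. Monoisotopic residue
masses, water, the proton mass and the Kyte–Doolittle hydropathy table are
frozen in `constants.py` (version-tagged, logged with every export).
Nonstandard residue letters (B, J, O, U, X, Z) are retained in sequences —
accessions stay addressable — but any peptide containing one has undefined
mass and is excluded from observability.

## Peak detection

Profiles are plateau-merged local-maximum scans with a *topographic
prominence* threshold: a maximum qualifies when its height above the
higher of the two minima separating it from the nearest taller part of the
profile reaches `max(min_value, rel_height · max(profile))`. For an
isolated peak prominence equals height, so the rule reduces to a relative
height threshold on clean profiles; its value is in suppressing
count-noise bumps on the flank of a dominant peak (which a raw height
threshold admits, flooding downstream grouping with artifacts) while
keeping genuine minor oligomer peaks, whose valleys return near zero — the
CF1-beside-CF0F1 pattern. A side of the scan that reaches the gel edge
without meeting a taller value contributes base 0, so boundary-truncated
bands keep full prominence and slices 1 and S are eligible apexes.
Plateaus report their topmost (leftmost) slice, breaking ties toward the
larger complex. Defaults `rel_height = 0.1`, `min_value = 0.01` emPAI
suppress one-peptide trailing noise while retaining minor peaks; both are
CLI flags. Peak intervals extend along strictly descending flanks while
values stay ≥ half the apex, stopping before a shared local minimum, which
keeps intervals disjoint.

Mass calibration fits `log10(mass kDa) = a·slice + b` by least squares on
≥ 2 markers (slices are cut at regular intervals, so slice number is a
linear distance proxy); the slope must be negative, residuals are
reported, and estimates outside the marker range are flagged as
extrapolated.

## Co-migration inference

Two partner notions are exposed, because both are in routine use:
same-slice detection (every protein with evidence in a queried slice) and
peak-apex grouping. Grouping scans every slice s and collects proteins
with an apex within ±tolerance (default 0 — "the same gel slice"; the
benchmark uses 1); singleton groups are dropped, duplicate member sets are
merged onto the anchor with the smallest apex spread, and a group whose
member set is a strict subset of a nearby group's (anchors within
2·tolerance) is discarded as a windowing artifact of the same apex
cluster. Subset groups anchored far away are *kept* — a genuine
sub-complex lower in the gel (CF1 vs CF0F1) is exactly that pattern.
Scanning all slices rather than only occupied apex slices matters when
member apexes straddle an unoccupied centre slice (e.g. apexes at s−1 and
s+1 only); tolerance 0 behaves identically either way. Profile similarity
is plain Pearson correlation (undefined for constant profiles); ranked
partner lists default to a 0.8 report threshold.

Report percentages round half-up to integers; full precision is retained
in JSON outputs.

## The synthetic benchmark

The generator emulates the data-generating process the analysis assumes,
not raw spectra. Complexes migrate as Gaussian bands: complex c with apex
slice μ, width σ (slices) and abundance scale A contributes
`a(c,s) = A·exp(−(s−μ)²/2σ²)`. Each member protein (stoichiometry q) emits
each of its candidate peptides (≤ 2 missed cleavages, in scan range)
independently with probability

    p = (1 − exp(−k·q·a(c,s))) · (1 − penalty · h(peptide)),

where h is the peptide's Kyte–Doolittle hydropathy rescaled to [0, 1].
The saturating form makes emPAI grow with log-abundance, as in the
index's validation; a linear-clamp model was rejected because it destroys
rank correlation at high abundance. The hydrophobicity factor reproduces
the familiar depression of emPAI for very hydrophobic subunits (the
PsaA/PsbA pattern): raising the penalty strictly lowers a hydrophobic
protein's mean emPAI (tested). Slices where the band falls below
`detection_floor` (default 1 %) of its apex abundance emit nothing,
emulating the instrument's minimum-signal threshold for triggering MS/MS;
without such a floor the mathematical Gaussian emits isolated
single-peptide rows arbitrarily far from the band — behaviour no
ion-trap shows — and those rows co-locate across members of a complex,
creating spurious distant "co-migration". Background noise adds
Poisson-distributed spurious (but sequence-true) tryptic peptide rows per
slice. All randomness flows from one seed through per-operation
substreams.

Defaults, chosen once as the simulated study conditions: k = 5 (near
saturation at band apex, as expected for an abundant complex), abundance
scale 0.6 and σ = 1.0 slice for the benchmark complexes (bands a few
slices wide whose apex slice is decisively resolved — larger A·k values
saturate detection over several slices and the apex becomes a coin flip
among them, which no peak detector can undo), hydrophobicity penalty 0.3,
background 1 row/slice (0 in the recovery benchmark). The benchmark
plants five complexes of 3–6 members, apexes 10 slices apart, in a
30-protein proteome (lengths 80–300), amino-acid composition with ~11 %
K/R so tryptic peptide lengths are realistic.

What passing the benchmark does and does not show: the generator draws
peptides independently per slice with known band shapes and no
co-eluting-complex overlap, retention-time effects, shared peptides across
paralogs, or protein-inference ambiguity. Recovery of planted complexes
therefore validates the pipeline's bookkeeping and peak/grouping logic,
not its robustness to the protein-inference problems a real search-engine
export carries.

Quantification fidelity is measured as the Spearman correlation between
computed emPAI profiles and the *instrument-visible* truth (the
stoichiometry-weighted band abundance, zeroed below the detection floor);
against the un-floored Gaussian the correlation is structurally diluted
by ties between truth-tail values and emPAI zeros regardless of
quantification quality. Median correlation under default noise is ~0.89.

## Design choices where the design was open

* **Paralog aggregation is opt-in** (`aggregate_group` sums member
  profiles under a new label, the PsaD1+PsaD2 pattern); nothing is merged
  automatically because which paralogs share a subunit role is an
  annotation judgement.
* **Shared peptides** are counted for exactly the accession the input
  table asserts; protein grouping/parsimony is the search engine's job
  and is out of scope.
* **Rows are never silently dropped** on ingest: strict mode raises on
  the first bad row with its row number, accounting mode returns accepted
  rows plus rejected row numbers.
* **Unknown localization strings** map to "unknown" with a warning rather
  than an error, so annotations from a differently-scoped study remain
  usable.
* **Exports are pure functions** of inputs and parameters: entries are
  sorted, JSON keys are sorted, and the manifest carries a SHA-256
  checksum, so re-runs are byte-identical and diffable.

## Problem sizes

The test suite simulates 30-protein proteomes; the digestion oracle
compares 200 random proteins (lengths 10–500) peptide-by-peptide; peak
detection is checked against an exhaustive scan on 1,000 random 60-slice
profiles; the recovery benchmark sweeps 20 seeds. The acceptance script
re-runs the recovery benchmark on 20 fresh datasets and the correlation
benchmark on 5, all derived from its `--seed`.

## Known limitations

* emPAI is semi-quantitative; its exponential form distorts peak *shape*,
  so Pearson similarity between subunits of one complex can dip below the
  0.8 report threshold even when apexes coincide (the benchmark shows
  values from ~0.68 upward for true co-members). Apex-based grouping is
  the primary inference; similarity is a secondary ranking.
* Overlapping bands are not deconvolved; a protein shared between two
  complexes closer than ~2σ yields one merged peak.
* The mass calibration assumes log-linear migration over the whole lane;
  gradient gels deviate at the extremes, and extrapolated estimates are
  flagged but not corrected.
* No statistical significance is attached to co-migration (no permutation
  null); groups are candidates for orthogonal validation, not calls.
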