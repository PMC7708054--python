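# Methods

## Motif scanning with exact p-value thresholds

Motifs are position probability matrices (PPMs) over ACGT, width 1–30, read
from MEME minimal format. Before scoring, a pseudocount of 1e-3 is added to
every cell and columns renormalized, so log-odds scores stay finite; the
magnitude is small enough not to move consensus calls. Scores are log2
odds against a 0-order background (default uniform 0.25 per base; a
sequence-derived or file-based background can be substituted — the scan was
specified only as "FIMO at p = 1e-4", so the background is configurable and
recorded in outputs).

To threshold at a target p-value, log-odds entries are rounded to a lattice
of 1/1000 bit and the exact distribution of the integer window score under
the background is obtained by convolving the per-position score
distributions (positions are independent under a 0-order background). The
threshold is the smallest lattice score `t` with `P(score >= t) <= p`; it
and every hit's p-value are exact with respect to the discretized matrix.
The lattice granularity trades table size against fidelity to the continuous
scores; at 1/1000 bit the rounding error per window is below 0.015 bits for
the widest admissible motif. Two consequences worth knowing:

* `t` need not be an attained word score — it is the smallest integer that
  admits the right tail. Tests compare against exhaustive enumeration over
  all 4^W words at widths ≤ 6.
* For short motifs a stringent p-value can be unattainable: under a uniform
  background the best width-6 word already has p-value 4^-6 ≈ 2.4e-4 > 1e-4.
  The threshold is then set one lattice step above the maximum (the scan
  returns nothing) and a warning is logged.

Scanning covers both strands; minus-strand hits are reported in
forward-strand coordinates (0-based, half-open). Windows containing N are
skipped rather than scored with ambiguity conventions. Overlapping hits are
all reported — candidate maps are not greedily masked; the dissection layer
merges strictly overlapping same-motif hits into candidate CRE regions.

## CRE pool

Candidate CREs are excised promoter regions labelled GENERIC, C_CRE_TGA or
C_CRE_NON_TGA. The two C-CRE classes correspond to the common element found
across pathogen-derived constitutive promoters, split by whether direct
TGA/bZIP binding is predicted. Native flanking sequence (default 10 bp per
side, configurable — the capture length is a package choice) travels with
each record for native-context variant building. The shipped fixture pool is
synthetic but mirrors the study composition: 2 TGA C-CREs (TGACG core), 1
non-TGA C-CRE, 12 generics, each the consensus of one fixture motif.

## Promoter dissection variants

Deletion excises a region cleanly. Relocation conserves length and re-places
a region so its 3' edge sits at a slot-defined gap upstream of the TATA box:
proximal = 10 bp (configurable), mid = half the available upstream span,
distal = the whole span (region at the 5' end). The exact coordinates used
for the original deletion/relocation constructs were not published; these
slot definitions are the package's own, chosen to span the range the
experiments probed.

## Library generation

Defaults are the study conditions: N ~ U[3,10] CREs per design, sampled
uniformly without replacement; one fresh random spacer of length U[5,30] nt
per CRE; a 19 nt random prefix; TATATAA; a 43 nt core containing the TSS;
1000 designs per library. Design choices where the source description was
ambiguous:

* *Spacer arity.* "A random sequence of 5–30 bases" could mean one block per
  design or one per CRE. One spacer per CRE iteration was chosen: it yields
  variable-region lengths that actually vary with N, consistent with the
  architecture's "region of variable length".
* *Segment order.* Each spacer precedes its CRE, so the final CRE abuts the
  TATA box — the configuration where C-CRE activity is maximal. The gap
  penalty therefore never fires on generated designs; it applies to manual
  constructions that insert sequence before the TATA box.
* *Prefix.* Re-randomized per design (configurable); whether the original
  library fixed it per run is not stated.
* *Core.* The literal 43 nt core was not published; `DEFAULT_CORE` is a
  fixed synthetic stand-in and should be replaced by a core of known
  provenance for wet-lab use.
* *Orientation.* CREs are inserted forward-strand only.
* Random segments use i.i.d. bases at a configurable GC fraction (default
  0.5).

The orthogonal builder tiles k copies of one synthetic-TF binding site with
fixed 5 bp spacers in the same frame; k = 0 gives the no-site control.

## Strength model

Let `d` be the distance (bases) from a C-CRE's 3' edge to the first TATA
base, 0 = abutting. The proximity weight is

```
w(d) = 1                         d <= plateau(class)
     = 1 - (d - plateau)/70      plateau < d < plateau + 70
     = 0                         otherwise
```

with plateau 60 bp for C_CRE_TGA and 130 bp for C_CRE_NON_TGA — the two
measured breakpoints. Per-base scores: 0 by default, `s_generic = 1` inside
generic CREs, `s_ccre * w(d) = 2 w(d)` inside C-CREs. With ≥ 2 C-CREs, every
base strictly between the outermost pair additionally receives
`s_between * w(d_mid) = 0.5 w(d_mid)`, where `d_mid` is the distance of the
between-region midpoint to the TATA box on the TGA schedule ("outermost
pair" is a package decision; the arity was not specified). If the most
TATA-proximal CRE sits more than 50 bp from the TATA box, the summed score
is multiplied by the same linear decay (1 → 0 over 70 bp past the limit).
The raw score is the adjusted sum divided by total length — so padding a
design with inert sequence dilutes it, and adding a CRE raises the score
only if its per-base contribution beats the current mean.

The numeric magnitudes (1, 2, 0.5) and the linear decay with a 70 bp span
are declared model constants: the original per-base values were never
published, only the three breakpoints. All are configurable; the package's
tests pin the breakpoints and the structural properties (monotonicity in
distance, sum/length semantics, right-skew of library strengths), not the
unpublished magnitudes.

Calibration fits the single scalar `k = Σxy / Σx²` (least squares through
the origin) mapping raw score to measured normalized expression — one
"numerator", no intercept, matching how the prediction was defined.
Diagnostics report R² of `k·x` against `y` about the mean of `y` (can be
negative for a poor fit). At least 2 points with non-zero raw-score variance
are required. The published predicted-vs-measured R² (0.7076) depends on the
unpublished score constants and the unpublished measured-strength table, so
it is not a reproduction target; the package instead verifies parameter
recovery on synthetic data (fitted k unbiased within Monte-Carlo error
across 200 replicates) and the structural properties above.

## Junction audit

Assembled designs are rescanned with the full motif library at the same
exact threshold. A hit is *intended* only if it lies wholly inside one CRE
segment **and** matches a motif listed for that CRE; everything else is
unintended, and unintended hits straddling a segment boundary are junction
hits. This is deliberately stricter than "not in the pool": a TGA motif
landing inside a generic CRE is exactly the kind of unplanned activity the
audit exists to catch. No multiple-testing correction is applied across the
scan, matching single-threshold FIMO usage. A design is flagged on the first
unintended hit; the CLI exits 2 when any audited design is flagged.

## Synthetic fixtures: what they emulate and what they do not

`generate_fixtures` produces sharp PWMs (consensus probability 0.97 —
near-deterministic binding preferences), promoters with planted consensus
instances at recorded coordinates, the 2+1+12 pool, and a measured-strength
table `y = k_true·raw + N(0, σ)` with k_true = 2.5 and σ = 0.12, emulating
ratiometric dual-luciferase protoplast measurements with assay noise. Motif
widths default to 8–12 so a planted consensus clears p = 1e-4 (a width-w
consensus has exact p-value 4^-w). Everything derives from one seed;
identical specs give byte-identical files.

These fixtures deliberately omit features of real data: soft/degenerate
PWMs with overlapping specificities, correlated motif co-occurrence,
repressive CREs, promoter GC structure, and measurement noise that scales
with expression. Passing tests therefore demonstrate the machinery is
correct under known ground truth, not that predictions transfer to any
particular genome's promoters.

## Numerical conventions

* Coordinates 0-based half-open internally; GFF3 output 1-based inclusive.
* Score lattice 1/1000 bit; thresholds and p-values exact on the lattice.
* Library generation consumes a single `numpy.random.default_rng(seed)`
  stream; (pool, config) reproduces a library byte for byte.
* Hit ordering is (sequence_id, start, motif_id, strand); ties in region
  merging are broken by coordinate then id.
* Acceptance-script problem sizes: proximity weights on a 0–300 bp grid,
  gap probe with 0–200 bp insertions — both chosen to bracket every
  breakpoint with margin.

## Known limitations

* The strength model is linear and additive per base; it cannot express
  saturation, repression, or CRE–CRE synergy beyond the between-C-CRE term.
* The audit reports unintended sites but does not predict their effect on
  expression (activator vs repressor annotation for plant TFs is too sparse
  to justify a sign).
* Only 0-order backgrounds are supported for scanning; no q-value/FDR across
  hits.
* The generator does not exclude designs that fail the audit; auditing is a
  separate, explicit step.
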