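# Methods

## Charge model

All non-learning methods share one physical model: a denatured,
unstructured chain whose ionizable groups titrate independently. The net
charge at a given pH is the Henderson–Hasselbalch sum

Z(pH) = Σ_bases 1/(1 + 10^(pH − pKa)) − Σ_acids 1/(1 + 10^(pKa − pH)),

with bases = {K, R, H sidechains, free alpha-amino terminus} and acids =
{D, E, C, Y sidechains, alpha-carboxyl terminus, phosphosite groups}. Every
pKa is required to lie in the open interval (0, 14); under that constraint
Z is continuous and strictly decreasing whenever at least one group exists,
so the pI is the unique root of Z. No temperature, ionic-strength or
structural (e.g. disulfide) effects are modelled. Residue indexing is
1-based; the terminal groups attach to positions 1 and len(seq).

Degenerate codes (B, Z, X, U, O) are accepted in input and treated as
non-ionizable, as is any residue missing from the active basis set: a basis
without a C entry simply never titrates cysteine. This "missing entry means
non-ionizable" rule is a deliberate totality choice — the alternative
(refusing sequences that contain residues without pKas) would make the
coarse historical basis sets unusable.

## Root solving

Bisection on [0, 14], stopping when the bracket is narrower than the
configured tolerance (default 1e-4 pH; the returned midpoint is then within
5e-5 of the root). Bisection is chosen over Newton-type schemes because Z
is monotone, so convergence is guaranteed, bit-for-bit reproducible, and
more than fast enough at desk scale (~18 iterations per solve). Sequences
whose groups all share one polarity (e.g. an N-terminally acetylated
peptide containing only acids) have no root; they raise
`NoIsoelectricPointError` rather than returning a clamped 0/14, because a
clamped value would silently distort downstream benchmark statistics. pI
values are kept at full precision internally and rounded to 2 decimals only
at serialization.

## pKa bases as data

All pKa constants live in per-set YAML files under `ampholyte/data/`, each
carrying its literature citation, validated on load. This is the package's
central design commitment: the accuracy of pI prediction is highly
sensitive to the basis set, so sets must be swappable without code changes.
Users can register custom sets at runtime or from files in the same
format. The Bjellqvist terminal variants additionally embed their base set,
so a variant with empty positional tables reduces exactly to the plain
enumeration — the property the test suite uses to pin the lookup logic.

The four Bjellqvist variants (default, expasy, calibrated, skoog) follow
their cited sources; whether the original "calibrated" recalibration also
touched sidechain pKas is not documented in our sources, so the shipped
file alters terminal tables only (the file format permits both).

## Cofactor and Branca corrections

Cofactor adds fixed ΔpKa terms, read from a window of ±3 residues, to the
acidic carboxyl groups only (D/E sidechains and the C-terminus); all other
groups pass through unchanged. Offsets are signed so a table may
distinguish N-side from C-side neighbors; the shipped table is symmetric.

Branca weights each neighbor's ΔpKa entry (window ±6) by that neighbor's
*charged fraction* — the absolute value of its fractional charge, the only
reading that yields a multiplier in [0, 1] — at the current pH estimate,
and adds a global term keyed by the (count of D, count of E) pattern to the
D/E pKas. Because the corrected pKas depend on the pI being solved for, the
scheme is a fixed point: seed with the uncorrected iterative pI, correct,
re-solve, repeat until the estimate moves less than the solver tolerance,
damping steps by 0.5 when their sign alternates. The corrections are small
relative to the charge curve's slope, so the iteration contracts strongly
(typically 2–4 passes). Correction *sources* are sidechain and modification
groups; terminal groups receive corrections but do not emit them, since a
terminal group shares its residue letter with a sidechain and re-keying it
would double-count. The carboxyl-count term is applied additively on the
D/E sidechain pKas (not on the final pI); the primary sources are ambiguous
on this point and the choice is flagged in the table files. Branca refuses
sequences without a K/R C-terminus (`NotApplicableError`, distinct from
numerical failure): the method is defined for tryptic peptides only.

The shipped numeric ΔpKa constants for both methods are **synthetic
stand-ins** (files named `*_synthetic.yaml`): plausible signs and
magnitudes — basic neighbors stabilize carboxylate anions and lower acid
pKas, acidic neighbors raise them, effects decay with distance — standing
in for the fitted constants of the primary publications, which are not
bundled. Every algorithmic test therefore uses zero, single-entry or random
synthetic tables, so correctness of the *algorithms* is independent of
constant provenance; users wanting faithful Cofactor/Branca numbers should
transcribe the published constants into the same file format.

## Modifications

A phosphosite contributes two acidic groups with default pKas 1.2 and 6.5
(data-file overridable), equivalent under the HH model to one diprotic
phosphate monoester; at high pH each site carries −2. The defaults are
stated for phospho-S/T; phospho-Y reuses them, an explicit totality choice.
N-terminal acetylation omits the alpha-amino group entirely. Both
modifications can only lower the pI; the suite checks this direction across
random peptides and every non-SVM method. Annotations travel in dataset
tables as a strict `phospho@3;acetyl@nterm` dialect.

## SVM predictor

The learning method is a retrainable pipeline, not a frozen model: features
are residue composition (20, normalized over standard residues), length,
a physics-based seed pI (iterative method over a named basis, default the
Bjellqvist sidechain set — the most widely used default basis), the
sequence means of bundled AAindex-style property scales (Kyte–Doolittle
hydropathy and monoisotopic residue mass), and two modification counts.
Feature order is fixed and versioned; serialized models embed their
feature spec and refuse to load across format versions.

Training fits `StandardScaler + SVR(rbf)` on a seeded 80/20
train/validation split, scanning a fixed grid (gamma ∈ {0.002, 0.01,
scale} × C ∈ {1, 10, 100} × ε ∈ {0.01, 0.1}) and keeping the
validation-best model; the stored held-out RMSD is measured on the 20%
split. Small gamma values are in the grid because the response is nearly
linear in the standardized features (the seed pI dominates), and a broad
RBF at the sklearn default bandwidth underfits it. Training refuses fewer
than 50 records: learning-based pI prediction degrades sharply on small
data. Everything is deterministic given (dataset order, seed).

## Benchmarking

"R²" is reported as the squared Pearson correlation, alongside the signed
r, because a squared statistic hides anti-correlation. Failed predictions
are excluded pairwise per combination (not listwise across methods) and
counted in `n_failed`, so Branca's applicability limit shows up as
accounting, not a crash. The outlier rule flags |experimental − predicted|
≥ the sample (n−1) SD of the *predicted* vector; when that SD is zero only
strictly positive residuals flag. Users wanting a residual-SD threshold can
compute it from the per-record residual table every report carries.
Per-fraction summaries report n, mean and SD of predicted pI, and RMSD,
ordered by each fraction's experimental midpoint; single-record fractions
report SD 0 with an annotation.

## Synthetic data

`simulate_peptides` emulates an OFF-GEL experiment: uniform-random
sequences (length 7–25, default n = 2000) with a tryptic K/R C-terminus,
ground truth from a configurable generating method (default
Bjellqvist/expasy), optional phospho/acetyl subpopulations, Gaussian
observation noise (default SD 0.2 pH, a realistic per-fraction IEF
uncertainty), and fraction assignment by binning the observed pI into 15
equal-width bins over pH 3–10 (out-of-range values land in the end bins;
an option quantizes observations to fraction midpoints instead).
`simulate_proteins` emulates a literature-collated table: longer chains
(50–400 residues), a configurable share (default 0.5) with 2–5 discordant
measurements at between-lab SD 1.0 pH, and a small subset (default 0.01)
with a forced focalization zone of ≥ 3.5 pH units.

What the generators deliberately do not model: real proteome composition
bias (uniform residue usage by default), MS/MS identification error,
inter-fraction diffusion, chemical derivatization. Passing tests on this
synthetic data therefore demonstrate the pipeline's internal consistency
and sensitivity structure — not field accuracy on any particular
instrument or organism.

## Numerical notes and degenerate inputs

* Corrected pKas are clamped to [1e-3, 14 − 1e-3] so extreme user tables
  cannot push a group out of the valid domain.
* The ± group-count limits of the charge curve hold in the limit sense:
  at pH exactly 0 or 14 a group with a pKa near the boundary (Arg at 12.5,
  phosphate at 1.2) still carries up to ~0.06 fractional charge.
  Verification probes 5 pH units beyond the extreme pKas, where every term
  has decayed below 1e-5.
* A length-1 sequence is treated as n-terminal context in positional
  lookups (tie-break, documented in code).
* Verification problem sizes (200 peptides for grid-scan agreement at
  1e-5 step, 500 for self-benchmarks, 2000/200 for SVM recovery) were
  chosen to make the checks statistically meaningful at interactive
  runtimes.

## Known limitations

* No structure-based pKa calculation; chains are assumed denatured.
* Cofactor/Branca shipped constants are synthetic stand-ins (above).
* Only phosphorylation and N-terminal acetylation are modelled; iTRAQ/TMT
  derivatization, methylation, oxidation etc. are out of scope.
* The SVM ships no pretrained weights: it is a pipeline to be trained on
  the user's own (or simulated) data.
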