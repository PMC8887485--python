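# Methods

`epiquant` implements two quantitative chromatin workflows end to end, each
driven by a synthetic-data generator with known ground truth so that every
stage is testable at desk scale without external downloads.

## Arm 1 — relative quantification of histone H3 PTMs

### Derivatization and mass model

Histones are modelled as chemically derivatized before digestion: free and
monomethylated lysines receive heavy-isotope methyl groups by reductive
dimethylation (¹³CD₂O + NaBD₃CN), and peptide N-termini are propionylated
after digestion. The scheme is a rule table mapping each endogenous lysine
state to the number of installed heavy methyls:

| state | endogenous adduct | heavy methyls | total adduct (Da) |
|-------|-------------------|---------------|-------------------|
| un    | —                 | 2             | 36.0757 |
| me1   | CH₂ (14.0157)     | 1             | 32.0535 |
| me2   | 2×CH₂             | 0             | 28.0313 |
| me3   | 3×CH₂             | 0             | 42.0470 |
| ac    | C₂H₂O (42.0106)   | 0             | 42.0106 |

One heavy methyl adds ¹³CD₃ − H = 18.0378 Da. Because every lysine ends
fully alkylated or acylated, trypsin cleaves only after arginine
(Arg-C-like), never before proline. All masses are monoisotopic; residue
masses come from pyteomics. Histone residue numbering excludes the
initiator methionine (H3 residue 1 is the Ala of ARTK…), so the digest
yields the canonical tail peptides 3–8 (K4), 9–17 (K9/K14), 18–26
(K18/K23) and 27–40 (K27/K36/K37).

The five derivatized states are pairwise mass-distinct, which is what MS1
discrimination requires. Note that the derivatized ladder is deliberately
*non-monotone* (un > me1 > me2 < me3): installing heavy methyls into free
slots means endogenous methylation can *reduce* the derivatized mass. The
narrowest gap is endogenous trimethyl vs. acetyl, 3×CH₂ − C₂H₂O =
0.0364 Da; the MS1 matching tolerance (default 10 ppm) is validated at
configuration time against this gap at the quantified precursor m/z.

### Quantified isoform catalogue

The default catalogue enumerates all five states over the routinely
quantified lysines, holding K37 of the 27–40 peptide unmodified. This is a
deliberate design choice, not a shortcut: with all three lysines of that
peptide variable, exactly isobaric groups of up to six positional
permutations arise in which *no* single fragment ion is unique against all
co-candidates (each b/y cut point only reports a partial sum of adducts),
so proportional unique-ion splitting is undefined. With two variable sites
every isobaric group assigns a distinct state to K27, so the b-ions
N-terminal to K36 always distinguish every member. Full three-site
enumeration remains available through `enumerate_isoforms`.

### Quantification procedure

1. **Match** each XIC peak to all catalogue isoforms whose theoretical m/z
   at the peak's charge lies within the ppm tolerance. Exactly isobaric
   positional isomers are kept together. When *near*-isobaric state
   classes collide at a coarse tolerance, a configurable elution-order
   heuristic (default: dimethyl-class before acetyl-class on C18
   reversed phase) assigns co-matching peaks by retention time; anything
   the ordering cannot resolve is carried forward rather than dropped.
2. **Select** the highest-area charge state per isoform group (ties break
   toward lower charge).
3. **Split** shared isobaric areas by the ratio of summed unique-fragment
   intensities in the peak's MS2 spectrum. The split conserves the shared
   area exactly (the last isoform receives the remainder); an isoform with
   zero detected unique ions is assigned zero with a warning, and an
   all-zero spectrum raises an unresolved-isobars error.
4. **Normalize**: each peptide's isoform areas are expressed as
   percentages of the peptide total (the total is 100 % by definition).
   Marginal per-site state percentages (e.g. "K27me3") are obtained by
   summation over combinations; each site's marginals again total 100 %.
5. **Contrast**: condition B over A as log base-1.5 of the percentage
   ratio, with a pseudocount (default 0.01 percentage points) on both
   sides so undetected states stay finite. At pseudocount 0 the matrix is
   exactly antisymmetric under condition swap. With replicates,
   percentages are computed per run, then averaged before the contrast;
   the standard deviation is reported.

### Synthetic LC-MS/MS runs

The generator emits one XIC peak per resolvable m/z–RT group with area
proportional to the summed true abundances, times a multiplicative
log-normal factor (σ default 0.05 — a typical run-to-run integration
spread). Every precursor gets an MS2 spectrum (DDA-like); co-eluting
isoforms contribute b/y ions proportional to their abundances, plus a
uniform additive floor (default 1 % of the maximum intensity). The default
composition of the 27–40 peptide includes the classic K27me1·K36me2 /
K27me2·K36me1 co-eluting pair and the near-isobaric K27me3 / K27ac pair.
Seeds are mandatory constructor arguments; there is no global random
state, and a fixed seed fixes every output byte.

What the generator does **not** emulate: profile-mode chromatograms, raw
peak integration, isotope envelopes, neutral losses, missed-cleavage
variants, co-isolation chimeras, or retention-time drift between runs.
Passing tests therefore demonstrate the correctness of the quantification
arithmetic downstream of peak integration, not robustness to
identification errors in real data.

## Arm 2 — spike-in-normalized ChIP-Rx domain dynamics

### Rx normalization

Each sample's scaling factor is `scale_constant / spikein_reads` (default
scale 10⁶, i.e. reads-per-spike-in-million). The convention that
additionally divides by primary depth in millions is available behind a
flag. Tracks are binned at 20 bp (0-based half-open coordinates), scaled
bin-wise, flagged as normalized (double normalization is an error), and
replicate-averaged element-wise. Because the spike-in count scales with
sequencing depth while ground-truth occupancy does not, multiplying a
sample's coverage and spike-in count by any k > 0 cancels exactly — the
invariance the spike-in design exists to provide.

Interval means are base-weighted (partial bin overlaps count their
overlapped bases), equal to the mean of the per-base expansion of the
track. Profiles come in two modes: point mode (columns of one bin width
across anchor ± flank, strand-flipped for minus-strand anchors) and scaled
mode (gene body rescaled to `body_bins` columns, default 200, with
native-resolution flanks). Rows whose window runs off a chromosome end
are padded with missing values and excluded from the composite.

### Domain logic

Two peak sets partition into cluster I (A-only), II (shared, recorded from
both sides) and III (B-only); "shared" requires an overlap of at least
`min_overlap` bases, which should be set to the sequencing read length so
sub-tag overlaps do not count. Gene association is overlap-based against
the TSS−2.5 kb .. TES+2.5 kb window; independently each peak is annotated
with its nearest gene by center-to-TSS distance (ties toward the smaller
gene id). A gene is "strong" when its replicate-averaged normalized mean
over that window rises at least two-fold between conditions; the
pseudocount guarding the ratio defaults to 1 % of the genome-wide median
bin value. Two-group comparisons use Welch's unpaired or the paired
Student t-test (two-tailed), per the usual convention for per-gene signal
contrasts.

### Synthetic ChIP experiments

Ground truth is a genome with true enriched domains per condition; bin
counts are Poisson with mean `depth × (background + enrichment inside
domains)`, partial bins weighted by covered bases. "Called" peaks equal
the true domains — peak calling is out of scope, and returning truth
isolates the interval logic under test. The zero-noise switch emits the
expected coverage exactly, making every downstream estimator exact.

The default study design tiles 4 kb gene bodies at 12 kb spacing
(alternating strands) so gene windows never overlap; condition A enriches
20 gene bodies, condition B adds 8 more; enrichment is 2.0 expected
reads/bin above a 0.2 background at unit depth (a ~11-fold in-domain
signal, comfortably above the 2-fold classification threshold yet noisy
enough that Poisson error is visible at bin level); condition B is
sequenced 1.5× deeper with spike-in counts at 5 % of a 4 M-read budget,
exactly the depth imbalance Rx normalization must undo; two replicates
per condition. These sizes keep a full two-condition experiment under a
second while leaving dozens of Poisson counts per gene window, so
recovery statistics are meaningful.

Not emulated: read-level alignment artifacts, duplicate/blacklist
filtering, fragment-length smoothing, peak-caller boundary noise,
input-chromatin subtraction, and copy-number variation. Tests on this
generator validate the normalization and interval arithmetic, not
robustness to peak-calling errors.

## Numerical choices

- Isobaric splits conserve the shared area exactly by assigning the last
  isoform the remainder after proportional allocation.
- Percentages sum to 100 within 1e-6 by construction; all-zero peptides
  are reported as missing, never as zeros.
- Quant-peak ties break toward lower charge; nearest-gene ties toward the
  lexicographically smaller id — both deterministic.
- Edge-of-chromosome profile rows are excluded from composites rather
  than zero-filled, to avoid biasing the flanks downward.
- bedGraph values are written with 6 decimals; round trips are exact at
  that precision.

## Known limitations

- The elution-order heuristic is a coarse partial order over state
  classes; real retention behaviour depends on the full modification
  context. Unresolvable assignments are carried forward, so downstream
  splitting must disambiguate or fail loudly.
- Proportional unique-ion splitting assumes equal fragmentation
  efficiency across positional isomers; a systematic efficiency bias
  would propagate directly into the apportionment.
- The Rx factor uses spike-in counts only; it assumes equal
  immunoprecipitation efficiency across samples, as the spike-in design
  itself does.
- Genome-scale results from the deposited sequencing datasets (tens of
  thousands of peaks) are out of desk-scale reach; the package validates
  the procedures structurally, not those headline counts.
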