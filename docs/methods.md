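# Methods

## The segregation model

The core statistic is deliberately simple: an alignment column *segregates*
two phenotype classes when the residue sets observed in each class are
disjoint, both non-empty, and contain no gap character. This is a
presence/absence partition test, not an association test — with the small
labeled panels typical of a cultivar study (a handful of tolerant and
sensitive accessions) there is no power for anything stronger, and the
biological claim being screened for ("all tolerant accessions carry X, all
sensitive carry Y") is exactly the strict partition.

Consequences of the definition, all enforced and tested:

* a column where any residue appears in both classes (the Ala/Pro mixture
  seen at HKT1;5 position 140) is non-segregating, however suggestive;
* a gap in either class disqualifies the column — an indel is not a
  substitution, and alignment-dependent gap placement should never create a
  "segregating" call;
* monomorphic columns are not reported at all;
* an optional exceptions budget `k` relabels a column
  `candidate_with_exceptions` when removing at most `k` sequences restores
  a strict gap-free partition (default `k = 0`: off). The count is the sum
  over shared residues of the smaller class count carrying that residue,
  plus gap carriers.

Label policy: `moderately_tolerant` and `unknown` sequences are excluded
from the partition test by default. Intermediate phenotypes are a separate
category — folding them into "tolerant" is a modelling decision the caller
must make explicitly (`policy="include_as_tolerant"`, which folds in the
moderates only; unknowns are never counted).

Coordinates are 1-based and inclusive everywhere. Alignment columns are
reported together with the ungapped position in a caller-chosen reference
row; a gap in the reference row yields an explicit gap marker, never a
silently shifted coordinate. The residue → CDS map is
`nt_start = 3(aa−1)+1`, `nt_end = nt_start+2`, with the inverse
`aa = ⌊(nt−1)/3⌋+1`; both directions are property-tested. The well-known
fact that different alignment parameters can shift a residue's *column* (a
332 ↔ 333 drift between tools) is handled by always reporting both the
column and the reference-row position.

## Pairwise alignment

Multiple alignments are consumed, not computed — recomputing a progressive
MSA adds nothing to the scan and would couple results to aligner
parameters. What the package does provide is an exact global (end-to-end)
pairwise aligner with affine gaps (Gotoh three-matrix recursion), because
counting differences between two named alleles must not require an
external tool. Scoring defaults: identity matrix +1/−1, gap open 10,
gap extend 0.5 (a gap of length L costs `open + (L−1)·extend`). The
traceback resolves ties deterministically in the order
diagonal > up > left, so outputs are reproducible to the byte. Scores are
verified in tests against both an exhaustive alignment enumeration (tiny
strings, no dynamic programming) and an independent aligner
(`Bio.Align.PairwiseAligner`) on longer ones.

Substitution counting distinguishes substitution columns (both residues
non-gap and unequal; reported in the first sequence's ungapped frame) from
indel columns (gap in exactly one row), which are listed separately and
never counted as substitutions.

## Trajectory statistics

**Contact probability.** Residues a and b are in contact in a frame when
the minimum distance over all heavy-atom pairs (one atom from each) is
≤ 4.2 Å. The contact probability is the fraction of frames in contact: 0
means the contact never formed, 1 that it persisted throughout. No
persistence smoothing is applied by default — "stable" is read as "present
in the frame" — but a minimum-run-length parameter (`min_run`, default 1)
is exposed for a stricter reading, since a contact that flickers on for
single frames is arguably not stable. Heavy = element ≠ H, taken from the
PDB element column or inferred from the atom-name convention when absent.

Invariants tested: probability ∈ [0,1]; symmetry in (a,b); monotone
non-decreasing in the cutoff; equality with a brute-force all-pairs
all-frames recomputation on small systems; invariance under rigid-body
rotation + translation of every frame.

**Filter dispersion.** For each selectivity-filter residue (the
Ser/Gly/Gly/Gly set at 76, 264, 391, 495 in HKT1;5 numbering; all four sit
on P-loops) the per-frame side-chain heavy-atom center of mass is computed,
mass-weighted by default (standard atomic masses; a geometric mean is
available — the literature rarely states which was used, and the choice
moves a Ser COM by well under an ångström). Glycine has no heavy side-chain
atom, so its Cα stands in (flag-controlled; disabling it makes Gly an
error). The pooled distribution is centered by subtracting the per-axis
grand mean — making plots and spread statistics comparable across systems —
and `spread_stats` then refuses uncentered input so a net offset can never
masquerade as spread. Reported: pooled per-axis SD, *within-residue*
per-axis SD (fluctuation about each residue's own mean — this is the
quantity that recovers an injected isotropic jitter σ, since the pooled SD
also contains the static inter-residue geometry), XY radial RMS, Z range,
and per-residue RMSF.

Equilibration discard and frame stride are exposed
(`Trajectory.sliced(discard_frac, stride)`, CLI `--discard-frac/--stride`)
for the usual "analyse the last third of the run" workflow.

**Limitations, stated loudly:** no periodic-boundary minimum-image
handling — input trajectories must be whole-molecule/unwrapped; only
multi-model PDB and CSV frame tables are read (binary MD formats are out of
scope at desk scale); atoms must appear identically in every frame.

## Relative expression (2^−ΔΔCt)

Technical replicates are averaged within (sample, gene) before anything
else — they estimate pipetting noise, not biology. Then per biological
replicate ΔCt = Ct(target) − Ct(reference gene), ΔΔCt = ΔCt −
mean ΔCt(control group), ratio = 2^−ΔΔCt. The group ratio is the mean of
per-replicate ratios and its dispersion the SEM over biological replicates.
The efficiency-corrected general form
`E_t^−ΔCt_t / E_r^−ΔCt_r` is available (per-gene efficiencies, default
exactly 2.0 which reduces to 2^−ΔΔCt), because real amplification
efficiencies of 90–95% make the ideal-doubling form a slight
overestimate of induction.

Group comparison: one-way ANOVA (scipy) followed by Tukey HSD
(statsmodels), stars \*\*/\*/ns at 0.01/0.05 against each stratum's own
control condition, within genotype × tissue. The fully degenerate case
(zero variance everywhere, equal means) returns omnibus p = 1 rather than
NaN. Unrounded Tukey p-values are used internally (the pretty summary
table rounds to 4 decimals, which breaks p-ordering assertions at small p).

## Ion quantification

Calibration is an OLS line through ≥ 3 distinct positive standards
(default series 10, 8, 6, 4, 2, 1, 0.5 ppm); a non-positive slope is a
hard error (a photometer whose reading does not increase with
concentration is broken), while inverse prediction outside the standards'
range warns rather than errors — extrapolating a linear photometer a
little beyond the top standard is routine practice, but the analyst should
see it. Tissue content is
`(ppm · dilution) / (equivalent weight · 1000 · dry weight g)` in mmol per
gram dry mass; equivalent weights default to 22.99 (Na) and 39.10 (K)
g/eq — for monovalent ions these equal the atomic weights, which is the
assumption behind using the two terms interchangeably. The Na⁺/K⁺ ratio is
a plain quotient and is invariant to any dilution factor applied to both
ions (property-tested).

## Synthetic data: what it emulates and what it does not

The generators produce inputs whose ground truth is known exactly, which
is what makes recall/precision and parameter-recovery claims testable
offline.

* **Panels** (`PanelSpec`): a random base protein; planted sites replace
  one residue per class (tolerant/sensitive); confounded sites cycle an
  A/P-style pool within *every* class, guaranteeing a shared residue and
  hence a non-segregating verdict; background substitutions hit a
  per-position rate outside the planted/confounded columns.
  Moderately-tolerant sequences carry the sensitive-type residue at
  planted sites, so the default exclusion policy keeps the site strict and
  the inclusion policy breaks it — exercising exactly the decision the
  policy flag encodes. Background rates above 0.3 are rejected: at that
  density random hits start destroying the guarantee that planted sites
  are the only strict columns. CDS ground truth comes from a fixed
  most-common-codon back-translation table (D→GAC, H→CAC, V→GTC, L→CTC,
  matching the codon pairs at the real SNP positions), with a TAA stop.
  Defaults (4 tolerant, 4 sensitive, length 120) mirror the scale of a
  cultivar panel, not its phylogenetic structure: generated sequences are
  i.i.d. around one base sequence, so the generator does not emulate
  lineage correlation, and a clean scan result here does not preclude
  phylogenetic confounding in real panels.
* **Trajectories** (`TrajectorySpec`): single-heavy-atom residues on a
  widely spaced grid; each contact pair toggles its partner between 3.0 Å
  (in contact) and 10.0 Å (apart) from its anchor — deterministic mode
  realises exactly `round(f·n)` contact frames, random mode draws
  Bernoulli(f) per frame; filter residues jitter isotropically,
  N(0, σ²) per axis per frame, about fixed homes. Specs whose geometry
  cannot encode the occupancy (contact distance ≥ cutoff ≥ apart distance)
  are rejected. This emulates occupancy and dispersion, not protein
  structure: there are no bonded constraints, no solvent, no membrane.
* **Ct tables** (`CtSpec`): target Ct = baseline − log₂(fold) + ε,
  reference Ct = baseline + ε, ε ~ N(0, sd) per well. Default design —
  three genotypes (a sensitive and a tolerant glycophyte plus a halophyte),
  0/100/200 mM conditions, six biological × three technical replicates,
  noise sd 0.1 cycles, fold defaults 2.4 (both glycophytes at 100 mM), 1.2
  (tolerant glycophyte at 200 mM) and 7.5 (halophyte at 200 mM, with 3.0
  at 100 mM as the intermediate of its gradual rise) — mirrors the
  experimental design this pipeline targets. The generator draws technical
  noise i.i.d. per well; it does not emulate shared biological-replicate
  effects or plate effects.
* **Photometer** (`PhotometerSpec`): readings = slope·ppm + intercept +
  N(0, sd) over the standard series above.

All generators are pure functions of their spec (seed included):
reproduction is byte-identical. The CLI writes each generator's ground
truth as a JSON/CSV sidecar next to the data.

A deterministic synthetic stand-in pair (`hkt_standin_pair`) encodes the
documented tolerant/sensitive allele relationship — identical sequences of
HKT1;5-like length except at positions 140 (P/A), 184 (H/R), 332 (D/H) and
395 (V/L) — so pairwise-difference analyses can be exercised without
fetching database records. They are labelled synthetic and are not the
database sequences.

## Numerical and testing conventions

* Problem sizes in the test suite are chosen for sub-second unit tests:
  brute-force contact comparisons at ≤ 10 residues × ≤ 50 frames,
  alignment enumeration at ≤ 5-mers, jitter recovery at 2000 frames,
  ANOVA calibration at 1000 simulated null datasets.
* Randomised tests fix seeds (numpy `default_rng`) or use derandomised
  hypothesis profiles; the label-permutation null uses 200 draws.
* Centering is exact to float round-off; the acceptance threshold used in
  tests (1e-9 Å) is far above the observed ~1e-13 residual that comes from
  summing coordinates of grid-scale magnitude.
* Tie-breaks: alignment traceback diagonal > up > left; longest-ORF
  selection prefers the 5′-most hit on the + strand; reverse-strand ORFs
  are reported on the reverse complement's own 1-based axis with a strand
  flag, keeping the codon map strand-agnostic.
* Ambiguous codons translate to X (tolerant of database ambiguity codes);
  internal stops render as `*` without truncating.
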