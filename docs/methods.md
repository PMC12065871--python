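# Methods

## Statistical model

Peptide intensities are analyzed on the log2 scale; input tables are linear
scale and are log2-transformed on entry. Median normalization shifts each
sample by a constant so that its median equals the median of all per-sample
medians. It presupposes that most peptides are unchanged between conditions;
with a planted or real signal affecting a large fraction of the measured
peptides the median itself absorbs part of the effect (see *Synthetic data*
below for how the generator reflects this).

Differential abundance per peptide uses an equal-variance two-sample t-test
with empirical-Bayes variance moderation. With per-peptide pooled variance
s² on d = nT + nR − 2 degrees of freedom and prior (d₀, s₀²),

    s²_post = (d₀·s₀² + d·s²) / (d₀ + d),
    t = log2FC / (s_post · sqrt(1/nT + 1/nR)),  df = d₀ + d.

(d₀ = 0 recovers the ordinary pooled t-test; d₀ = ∞ a z-test on s₀².) The
hyperparameters are estimated by closed-form moment matching of log s² to a
scaled log-F distribution (digamma/trigamma inversion, Newton iteration);
when the excess spread of log s² is non-positive the prior degrees of
freedom are infinite. Missing intensities are omitted, never imputed; a
peptide is tested only with ≥ 2 quantified replicates per side. Equal
variance (not Welch) was chosen as the canonical moderated-test form.

Benjamini–Hochberg adjustment is applied once per (assay channel, contrast)
across all tested peptides of all proteins, mirroring proteome-wide
analysis. The peptide score is s = −log10(q)·|log2FC| (dimensionless, ≥ 0;
0 iff q = 1 or log2FC = 0). p-values are floored at 1e−300 so q and the
score stay finite.

## Trypsin-only control normalization

For each (protein, peptide, sample) present in both channels the adjusted
LiP intensity is `lip − tc + median_over_samples(tc)`, with the per-peptide
median taken across **all** samples of the control channel (an alternative
definition across only reference samples was considered; the all-sample
median is symmetric in the contrast and keeps the adjusted values on the
original intensity scale). Effects present in both channels — covalent
modification, abundance change — cancel exactly; LiP-only (conformational)
effects pass through unchanged. Note the converse: a control-channel-only
decrease appears as a *positive* adjusted fold change (relatively more
protease-accessible signal per unit of unmodified peptide), which is the
arithmetically faithful reading of the subtraction formula. LiP peptides
without a same-sample control partner (in particular all half-tryptic
peptides, which have no trypsin-only counterpart) are dropped from the
adjusted output with a logged count — control normalization is therefore an
option for covalent-effect removal, not a default pipeline step.

Covalent-modification candidates are trypsin-control peptides with
log2FC ≤ −1 and q ≤ 0.05 (decreases only: a covalent adduct mass-shifts the
peptide away from its unmodified precursor; increases are not evidence of
covalent binding). Reports are per protein, "k of n flagged".

## Residue aggregation

Peptides are located on their parent protein by exact substring search; all
occurrences are returned and multi-occurrence peptides are flagged
ambiguous. By default every occurrence contributes to aggregation and the
covered residues are marked ambiguity-tainted; a strict mode drops ambiguous
peptides. Peptides claimed by several proteins contribute to each parent
independently.

The amino-acid score S_i is the arithmetic mean of the scores of all
quantified, tested peptides covering residue i (1-based, inclusive
coordinates throughout). Residues covered by no quantified peptide are *not
detected* — a state distinct from S_i = 0 — and serialize with an empty
score field. Significance is the pure threshold S_i > τ with
τ = −log10(0.05)·|log2(2)| ≈ 1.30103 by default; an optional strict mode
additionally requires a covering peptide with q < 0.05 and |log2FC| > 1.
Maximal runs of significant residues are reported as regions.

Span-mean aggregation has an intrinsic resolution limit: a peptide
straddling a true-effect boundary carries an attenuated but often still
highly significant score across its *entire* span, so a few residues beyond
a region boundary can exceed τ when their coverage is thin (in the default
synthetic experiment, residues 98–102, covered almost solely by one
missed-cleavage straddler, are reproducibly super-threshold). Deep
overlapping coverage — the regime this analysis is designed for — dilutes
such bleed.

## Structure mapping

Minimal inter-residue distances are all-atom (non-hydrogen) pairwise minima
in Å; pockets are residue lists taken from database annotations. Hydrogens,
waters and hetero-compounds are excluded when reading PDB/mmCIF (gemmi);
alternate locations resolve to the highest-occupancy atom. The
score-distance relationship is summarized as the mean minimal pocket
distance of residues with S_i > τ versus that of all residues; with no
super-threshold residues that group mean is undefined (NaN). Sequence
positions are assumed to equal author residue numbering unless an explicit
mapping is supplied. Distances are computed within one selected chain;
inter-protomer contacts of multi-chain assemblies are out of scope. Score
export writes each residue's score into the B-factor column of every atom
(sentinel −1.0 for undetected residues), at the format's 2-decimal
precision.

## ThT kinetics

F(t) = F0 + (Fmax − F0)/(1 + exp(−k(t − t_half))) is fit by least squares
(scipy curve_fit) to ≥ 6 strictly increasing time points. T_End is the mean
of the last three observed points (averaging reduces plate-reader noise at
the endpoint). Curves whose fitted amplitude is below 3× the residual RMS
(or that fail to converge, or are exactly constant) are *flat*:
t_half = ∞, the no-aggregation convention. A fitted t_half outside the
observed time range is flagged extrapolated.

## Enrichment

Per annotation term a 2×2 table over the background universe
(hit∧term, hit∧¬term, ¬hit∧term, ¬hit∧¬term) is tested with Fisher's exact
test (two-sided by default; one-sided "greater" by flag) and BH-adjusted
across terms. The reported odds ratio is the sample odds ratio a·d/(b·c)
(0 when a·d = 0, ∞ when only b·c = 0).

## Synthetic data

The generator is the package's test bed and emulates a two-condition LiP
experiment with known truth:

- **Digestion.** Fully-tryptic peptides are enumerated exhaustively (cut
  after K/R, not before P; length 6–40; ≤ 2 missed cleavages). Half-tryptic
  peptides keep one tryptic terminus; a candidate whose nonspecific cut
  falls inside an accessibility region is accepted with probability 0.30,
  elsewhere 0.15 (proteinase K nicks an accessible chain everywhere, with an
  excess where accessibility differs between conditions). Sampled
  half-tryptics are internally fully cleaved by default
  (`missed_cleavage_penalty = 0`): a proteinase-K fragment is bounded by the
  *nearest* tryptic cuts, and missed-cleavage semi-tryptic forms are minor
  species in real digests.
- **Effects.** An accessibility region (start, end, log2 effect) adds
  effect × (overlap/length) to every overlapping LiP peptide in the
  treatment condition — straddling peptides are attenuated proportionally.
  Covalent sites add their (negative) effect to every peptide containing the
  position in *both* channels; the control channel contains the
  fully-tryptic subset only.
- **Noise.** log2 intensities get i.i.d. normal noise with typical sd
  log2(1 + CV); per-peptide variances are drawn from the scaled
  inverse-chi-square prior s₀²·d₀/χ²_{d₀} with d₀ = 4 — the hierarchical
  model the moderated test assumes, with a prior df in the range typical of
  low-replicate DIA data. Base abundances are N(20, 1.5²) log2 units.
  Intensities are exported linear (2^x).
- **Carrier background.** Eight fixed treatment-insensitive carrier proteins
  (~1.9 kaa total) are co-simulated in both channels. They model the
  background peptide population of a real run (protease autolysis products,
  co-measured proteins) and supply the unchanged majority that median
  normalization and proteome-wide BH adjustment presuppose; without them the
  per-sample median absorbs part of a planted effect on a single small
  protein.
- **Defaults = study conditions.** 140-residue human α-synuclein, one
  region (61, 95, +2.0) — the NAC amyloid core of the monomer-vs-fibril
  comparison — CV 10%, 4 vs 4 replicates. Dose series scale region effects
  by the log-logistic occupancy dose^h/(EC50^h + dose^h). All generators are
  pure functions of (parameters, seed).

What the generator does **not** emulate: intensity-dependent missingness is
off by default (a logistic-dropout flag exists on real data's behalf, but
baseline tests stay exact); no retention-time or ionization effects, no
peptide-level FDR, no shared peptides between the target and carriers, no
correlation of noise across peptides. Passing recovery tests therefore show
the statistical pipeline is correct under its own model assumptions, not
that any given real dataset has the coverage or noise structure required
for residue-level resolution.

## Toy structures

`make_toy_structure` builds an idealized α-helix (rise 1.5 Å, twist 100°,
Cα at 2.3 Å radius plus one pseudo side-chain atom at 3.3 Å, 0.05 Å seeded
jitter), giving consecutive Cα–Cα distances near 3.8 Å — a minimal but
geometrically sane scaffold for distance-report tests.

## Numerical choices and degenerate inputs

- Zero or unparsable input intensities become *missing*, never −∞.
- BH uses stable sorting; tied p-values share the adjusted value of their
  last rank; output is capped at 1.
- Trigamma inversion starts at 0.5 + 1/x and iterates Newton steps to
  1e−10 relative tolerance; extreme arguments use asymptotic starts.
- A peptide score of exactly 0 occurs iff q = 1 or log2FC = 0; scores are
  never negative.
- `estimate_moderation` requires ≥ 10 finite variances and rejects an
  all-zero variance set; zero variances (tied intensities) are excluded from
  moment matching as uninformative on the log scale.
- Residue significance requires detection; undetected residues can never be
  significant or belong to a region.

## Known limitations

- Residue scores inherit peptide-span bleed (see above); reported region
  boundaries are accurate to roughly the local peptide-length scale, not to
  single residues, when coverage is thin.
- The TC normalization drops half-tryptic peptides by construction; covalent
  and conformational effects can only be disentangled where fully-tryptic
  coverage exists.
- Median normalization is unreliable when a majority of measured peptides
  change; for purified-protein runs this is mitigated by background
  peptides, but extreme comparisons (complete unfolding) can still bias
  fold changes.
- Structure distance reports assume the fingerprint's sequence numbering
  matches the model's author numbering unless a mapping is given; no
  alignment is attempted.
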