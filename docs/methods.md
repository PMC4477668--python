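# Methods

## Model

`rbscore` scores each residue of a protein chain for nucleic-acid (NA)
binding in two stages. The **feature score** is a linear combination of 13
per-residue values — solvent-accessible surface area (ASA, Å²), the counts
of the residue's surface sample points in 10 electrostatic-potential bins,
and two alignment-derived conservation values — using 14 weights selected
by residue type (the type-dependent ASA slope `w_aa`, the 10 shared bin
weights, the shared non-negative `w_CE` and `w_width`, and the
type-dependent constant `C_aa`). The **prediction score** adds the averaged,
weighted feature scores of two neighbor layers: direct neighbors, whose
solvent-accessible dot clouds approach within 1 Å, and indirect neighbors,
which share a direct neighbor with the target and lie within 18 Å
Cα–Cα. Each neighbor contributes through a residue-type weight (`u_aa`
direct, `v_aa` indirect, indexed by the *neighbor's* type) and a
neighbor-type weight (`f` direct, `g` indirect) over 6 types: sequence
separation |i−j| ∈ {1, 2–4, >4} crossed with whether the neighbor's feature
score exceeds the target's (ties count as low, for determinism). The
combination is single-pass — neighbor feature scores are not themselves
propagated — and the scores are unbounded, which is what lets binding
funnels appear on the surface instead of saturated classifier outputs.
Altogether 104 weights: 52 in the feature block, 52 in the network block.

Sequence distances use 0-based contiguous chain indices as parsed, so a
crystallographic gap between author numbers still counts as one step; the
|i−j| classes encode bonding topology, and peptide-bond adjacency follows
chain order in the file. Author numbering is preserved for reports only.

## Geometry

The surface is sampled Shrake–Rupley style on the solvent-accessible sphere
(r_atom + 1.4 Å probe) with a deterministic Fibonacci-spiral template,
default 960 points per atom; a point is removed when strictly inside
another atom's expanded sphere. ASA is the surviving fraction times the
expanded sphere area, summed per residue (it matches biotite's independent
Shrake–Rupley to ~1e-7 relative on random atom sets, and the isolated-
carbon sphere analytically). United-atom radii: C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å, configurable via a two-column radii file; hydrogens are
discarded at parse time since the target crystal structures rarely resolve
them and all distances are heavy-atom distances. Per-residue ASA converges
to better than 2% between 960 and 3840 points on the synthetic fixtures.

The 1 Å dot-contact rule and the 960-dot density are a matched pair: a
sparser cloud needs a looser contact distance. Both are exposed as
configuration (`contact_dist`, `density`).

ΔASA for the binding-label gate is computed with the NA chains as the only
extra occluders — protein partner chains are present in both the free and
bound states — so ΔASA isolates the NA footprint and is non-negative up to
sampling tolerance. Binding labels require a heavy-atom distance to NA
below the cutoff (3.5 Å for training; 3.5–6.0 Å ladder for assessment) and,
by default, ΔASA > 0. Dataset filters drop chains shorter than 20 residues,
chains with fewer than 3 binding residues, and Cα-only chains.

## Electrostatics

The built-in potential is a screened Coulomb (Debye–Hückel) sum over formal
charges — Arg/Lys +1 (guanidinium carbon / NZ), Asp/Glu −1 (carboxyl
carbon), His +0.1, chain termini ±1 — with dielectric 4 (protein-surface
regime), Debye length 8 Å (~150 mM monovalent salt), distances floored at
1 Å, expressed in kT/e via the vacuum Bjerrum length (560.4 Å at 298 K).
Only the *shape* of the 10-bin histogram over [−20, 20) kT/e feeds the
score (out-of-range values clamp into the outer bins; this keeps the
row-sum-equals-dot-count invariant), so the model tolerates a crude
potential; a precomputed OpenDX scalar grid (e.g. a Poisson–Boltzmann map)
can be substituted and is interpolated trilinearly at the dot positions.

## Conservation

CE is the information content log₂20 − H of the 20-amino-acid frequency
vector among non-gap symbols of an alignment column, so that high CE means
conserved — the orientation the scoring model assumes. Raw-entropy and
gaps-in-frequencies variants are available as switches
(`information_content`, `count_gaps_in_entropy`). Width is the non-gap
fraction of the column; ambiguous residues (B, Z, X) are excluded from the
frequency vector but count as non-gap for width. Columns gapped in the
query are skipped so the outputs align with the structure's sequence; a
mismatch raises an error naming the first discordant position. Without an
MSA, CE and width are zero and their weights contribute nothing.

## Training

wAUC = Σ AUC(i)·len(i) / Σ len(i) is piecewise constant in the weights, so
the trainer is simulated-annealing Monte Carlo: perturb one uniformly
chosen parameter by Gaussian noise, accept uphill moves always and downhill
moves with probability exp(ΔwAUC/T), reflect `w_CE`/`w_width` proposals at
zero, cool geometrically, return the best-ever vector with a full
(step, T, wAUC) trace. Defaults: T₀ = 0.01, cooling 0.92, 400 proposals per
temperature, T_min = 10⁻⁴, stop after 15 temperatures without a new best.
The initial temperature is set to the observed scale of single-move wAUC
changes (~10⁻³): much hotter and the annealer accepts every downhill move
and degenerates into a random walk; colder and it is greedy hill-climbing.
Proposal step sizes are derived from the starting vector (30% of each
parameter's magnitude with per-block medians and floors) because the
feature-block slopes multiply features spanning tens of units and are
correspondingly small. The starting vector itself is data-driven: pooled
point-biserial correlation of each feature column with the labels, scaled
by the column's spread, with the network block at u = v = 0.5, f = g = 1.

Cross-validation splits at the protein level (never residues) into 5
seeded folds; the selected model is the fold with the highest validation
wAUC, with an optional full-data refit. Per-protein AUC uses the midrank
Mann–Whitney statistic, making the tie convention explicit; proteins with
single-class labels at a given cutoff are skipped (and logged) for
wAUC/mAUC, while tAUC pools all residues.

## Synthetic fixtures

`make_toy_complex` plants a known interface: residues of 5 pseudo-atoms
(N, CA, C, CB, side-chain tip) sit on a smooth curve; interface residues
raise their tip to z = +7 Å and one 3-pseudo-atom nucleotide sits
3.0–3.4 Å above each tip, while every other residue stays below z = +1 and
hence >8 Å from the NA. Labeling at 3.5 Å with the ΔASA gate therefore
recovers exactly the planted set. Interface composition is biased toward
{R, D, G, H, K, T} (default 0.7), mimicking observed NA interfaces.
`make_synthetic_msa` substitutes per column with probability
1 − conservation and gaps with a configurable fraction.
`make_planted_score_dataset` draws heterogeneous features (ASA ~ |N(60,
30²)| Å², multinomial bin counts of 100 dots over Dirichlet(0.5)
compositions, uniform CE/width), builds a sequence-plus-random contact
graph, and labels the top 25% of residues ranked by a known generating
vector plus Gaussian rank noise (default σ = 0.1 standard deviations of the
score) — at σ = 0 the generating model separates perfectly, at large σ
labels are random. Default study sizes: 50 training and 12 held-out
proteins of 40 residues for recovery experiments; 200 points for the
planted funnel at σ = 0.1.

What passing on these fixtures shows — and does not. The fixtures exercise
every pipeline stage with known ground truth, but they are geometrically
idealized (single compact interface, no crevices, pseudo-atoms, charges
aligned with interface bias) and the planted-score datasets are drawn from
the model family itself. Success here validates correctness of the
machinery and recoverability of planted signal, not accuracy on real
protein–NA complexes; the shipped default weights are fitted on these
fixtures and are explicitly non-canonical.

## Numerical choices and degenerate inputs

Dot occlusion uses a 10⁻⁹ Å tolerance on "strictly inside"; dot–dot contact
search uses a KD-tree whose result equals the all-pairs check exactly
(tested). AUC requires both label classes, otherwise the protein is
skipped; funnel correlation requires ≥3 residues within the 20 Å region
(a default — "around the binding region" is not a sharp notion — exposed as
`region_limit`) and non-zero variance. The funnel's Pearson r is reported
signed; with high scores at the interface it is negative, and funnel
strength is |r|. The count estimator regresses the *fraction* of binding
residues on the fraction of {R,D,G,H,K,T} so protein length does not
dominate, and floors predicted counts at zero. Weight files are strict:
missing, unknown, or duplicate keys are errors. Altloc atoms keep the
highest occupancy; multi-model files use model 1; MSE and a fixed list of
modified residues map to their parent amino acid, other HETATM residues are
dropped with a warning; contacts to NA hydrogens or modified nucleotides
are not counted (both are excluded at parse time).

## Known limitations

The Debye–Hückel surface potential is a coarse stand-in for a
Poisson–Boltzmann map (use the OpenDX import for higher fidelity). The
dot-sampled accessible surface is not a re-entrant molecular surface, so
deep crevices are represented only approximately. mmCIF input, redundancy
removal, and homology-model workflows are out of scope. The annealer's
single-coordinate proposals converge slowly from strong starting points;
in practice the data-driven initialization does most of the work on
well-separated data and the annealer refines it.
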