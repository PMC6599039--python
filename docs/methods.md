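# Methods

## Cross-link restraints

DSS couples primary amines; accounting for the two lysine side chains and
backbone flexibility, an identified lysine–lysine link constrains the
Cα–Cα distance to at most ~32 Å. The package fixes the cutoff at exactly
32.0 Å with the boundary counted as satisfied: a sharp convention is what
makes counts reproducible. Restraints anchored on a surrogate residue (see
below) face the same limit by default; `evaluate_restraints` accepts an
optional slack of s Å per surrogate side (default 0) for sensitivity
analysis only.

pLink-style reports are peptide-level; the parser collapses them to unique
residue pairs keeping the best score (pLink scores are E-value-like, so
smaller is better), drops self-links, and sniffs two header dialects: a
flat Protein_1/Position_1/Protein_2/Position_2 table and the pLink2
`Proteins` column encoding `NAME (pos)-NAME (pos)`. FDR control is assumed
done upstream; an optional score threshold is available but off by
default.

**Surrogate anchors.** When a cross-linked residue lies in a disordered,
unmodelled terminus, the restraint is re-anchored on the nearest residue
in sequence that has a Cα — for a terminal tail, the last ordered residue.
Equidistant ties break toward the lower residue number (only reachable for
internal gaps, which the analyses here do not exercise). The operation is
idempotent: an anchor is its own anchor.

**Homo-oligomer ambiguity.** Each subunit of the double ring is present
twice, so a link between protein names maps to several chain pairings.
The default policy keeps the pairing with the smallest Cα–Cα distance —
links are treated as satisfiable constraints, the reading that gives the
assembly the benefit of the doubt. `enumerate` returns every unordered
chain pairing (for a two-copy intra-protein link: both within-copy
pairings and the cross-copy pairing, whose two residue-to-chain
orientations are collapsed to the shorter) for sensitivity analysis.

**Foldedness statistic.** With N linkable lysine pairs in a reference
structure, K of them beyond the limit, and n observed links showing k
violations, the package reports the exact hypergeometric lower tail
P(X ≤ k). A small value means the observed links avoid the violating pairs
more than uniform sampling allows — evidence the cross-linked molecule is
folded like the reference. Hypergeometric rather than permutation: exact,
closed-form, no seed dependence. The background population counts only
lysines with a resolved Cα; the N-terminal amine is not a site.

## Orientation search

The search is an exhaustive scan of a deterministic, near-uniform rotation
grid (super-Fibonacci spiral on the quaternion sphere). The grid size is
chosen so the covering radius stays below the requested step (default
10°); a verification test confirms every random rotation has a grid
neighbour within the step. When a translation box is requested the
substrate centroid additionally scans a cubic 2 Å grid.

Scoring is a squared hinge beyond the cutoff, Σ max(0, d − 32)², so all
fully satisfying poses are equivalent at zero — mirroring the
satisfiability logic of restraint validation — with a raw distance-sum
mode available. Ranking is penalty-first, then number of satisfied
restraints, total restraint distance, and finally quaternion order: a
deterministic total order, byte-for-byte reproducible.

Grid resolution is not the precision limit: the best grid candidates are
polished by continuous local minimisation (Powell over a rotation-vector
perturbation). On synthetic planted-pose problems with exhaustive
noiseless links this brings the recovered orientation to within a few
degrees of truth at a 10° grid.

**Robust mode.** With a trimming fraction f > 0 the worst ⌈f·n⌉
restraints are ignored. The trimmed penalty develops spurious exact zeros
(any pose can sacrifice a different subset), so robust ranking is
consensus-first — most satisfied restraints, then trimmed penalty — the
maximum-consistent-restraints criterion familiar from exhaustive
restraint-based docking. Local polish in this mode is a deterministic
shrinking-ball hill-climb on the same consensus key, since the flat
trimmed objective defeats smooth descent. Stochastic sparse detection
biases pure distance-sum minimisation (the detected subset is
distance-weighted, so the weighted sum is not stationary at the true
pose); recovery benchmarks therefore use the exhaustive detection regime,
where every pair within the linker limit is a restraint.

## Density difference and occupancy

Simulated maps render each atom as a spherical Gaussian with FWHM equal to
the nominal resolution and amplitude proportional to atomic number,
truncated at 5σ (keeps > 99.8% of the mass; the analytic-integral test
allows 1%). Maps are MRC2014/CCP4 via gemmi; only isotropic voxels are
supported (resample first otherwise).

Subtraction is voxelwise a − s·b. s = 1 by default; `lsq` fits the
least-squares scalar ⟨a,b⟩/⟨b,b⟩ for map pairs on arbitrary intensity
scales, optionally over a mask of high-confidence voxels — a whole-map fit
is attenuated when background noise inflates ⟨b,b⟩. Synthetic pairs from
the generator share an absolute scale, so their analyses use s = 1;
occupancy calls under `lsq` are invariant to a common rescaling of both
maps, which is tested.

Each pocket sphere (default radius 6 Å) is scored by its mean difference
density as a z-score against the whole-map voxel distribution
(reference-minus-query: high difference ⇒ nucleotide absent). Classes:
occupied below z = 0.5, empty above z = 1.5, partial between. These
thresholds formalise what is otherwise a visual classification; the
values are the package's convention, exposed on the CLI, and a degenerate
all-zero difference map yields z = 0 everywhere (everything occupied,
nothing empty).

## Surface areas and contacts

Shrake–Rupley with a deterministic Fibonacci-spiral point set (default 960
points, probe 1.4 Å, Bondi radii; unknown elements 1.8 Å with a warning).
The point set is expressed in a molecular frame built from the principal
axes of the coordinates with skewness-fixed signs, which makes areas
exactly equivariant under proper rigid motions — a lab-frame point set
would only be invariant to quadrature error. At 960 points the quadrature
is within 1% of the closed-form sphere area and 0.5% self-consistent
against a 4× denser set.

Burial is 1 − SASA(ligand in complex)/SASA(ligand isolated), both areas
computed in the complex's frame so they differ only through occlusion.
Contacts are heavy-atom distance classes (models carry no hydrogens, so
no angle terms): N/O–N/O within 3.5 Å as hydrogen bonds; phosphate
oxygens (O within 1.8 Å of a ligand P) against Lys/Arg/His side-chain
nitrogens within 4.0 Å as salt bridges; C–C within 4.0 Å as hydrophobic;
each pair reported once with its most specific type.

## Synthetic data

The generator emulates the geometry the analyses depend on, not the
physics: Cα-only pseudo-subunits (27-residue compact bodies) on two
staggered octameric rings (radius 40 Å, inter-ring gap 28 Å), each with a
12-residue disordered N-terminal tail descending toward the inter-ring
midplane at its own azimuth — tails exist in the ground truth but are
withheld from the emitted model, so surrogate-anchor logic runs exactly as
on a real deposition. The substrate is a seven-bladed propeller (70
residues, radius 18 Å) planted at a uniformly random rotation about its
centroid on the midplane. It carries 11 lysines at irregular positions
(one per blade plus a second on alternate blades), about the lysine
density of a real ~330-residue propeller; the irregularity is what makes
the cross-link pattern orientation-identifying.

Cross-link detection: a lysine pair at true distance d ≤ 32 Å is emitted
with probability p·exp(−d/λ), defaults p = 0.4 and λ = 15 Å — chosen once
to give on the order of 150–200 unique links on the default assembly,
the regime of a real chaperonin XL-MS experiment — plus ⌊false_rate·n⌋
uniformly random decoy pairs (default 5%, the upstream FDR level). The
decay constant is recoverable from ≥ 500 simulated links by maximum
likelihood within 20%, which is tested. Setting p = 1, λ = ∞ gives the
deterministic exhaustive regime used by the recovery benchmarks.

Occupancy pairs: a 25-atom pseudo-nucleotide (phosphorus-weighted, ~3.5 Å
footprint — about the size and heavy-atom count of ADP) is planted in all
16 pockets for the reference and a chosen subset for the query; both maps
get i.i.d. Gaussian voxel noise. The noise unit reported in the truth
table is the isolated ligand's peak density.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: side-chain atoms and real secondary
structure, sequence realism, peptide-level detectability (miscleavage,
charge states), non-uniform map resolution, masking/segmentation effects
in difference maps, and model-vs-map registration error. The
deposited-entry reproduction tests exist precisely to cover that gap and
require the published files locally.

## Problem sizes and numerics

Default benchmarks use the full 16-subunit assembly (~500 residues,
~360–430 restraints), a 10° rotation grid (≈ 28 000 orientations,
vectorised scoring), 16 pockets on ~50³ voxel maps at 2 Å, and 20
generator seeds per recovery property. Floating-point conventions:
distances in Å; satisfaction at ≤ cutoff; quaternions normalised with an
error above 1e-6 deviation and a warning above 1e-12; all stochastic
operations take an explicit integer seed and use one `numpy` generator per
call, no global state.
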