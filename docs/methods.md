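# Methods

## The Rg/N^ν classifier

A chain bound in a complex is summarized by its radius of gyration over
α-carbon coordinates. CA-only and unweighted: the mass-weighted definition
reduces to the unweighted one when every point is a CA carbon, and CA
coverage is also what defines the chain length `N` (residues counted in
`N` are exactly those contributing coordinates to Rg, so the statistic is
self-consistent; an all-atom mass-weighted variant is available behind
`ClassifierConfig.mass_weighted` for sensitivity checks).

The decision statistic is `Rg/N^ν` in Å. Defaults:

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.26 Å | decision value; ID iff statistic strictly greater |
| `nu` | 1.0 | scaling exponent of the statistic |
| `min_segment_len` | 20 | candidate chain must have > 20 residues with coordinates |
| `min_partner_len` | 70 | some partner chain must have > 70 residues |

Strict inequality at the threshold assigns exact ties to *structured*,
the conservative choice for a screen whose positives trigger further
analysis. Flory fits (`fit_flory`) are ordinary least squares of ln Rg on
ln N; the slope is ν̂ and exp(intercept) the prefactor R₀. A log-log OLS
weights relative errors uniformly across the length range, which is the
standard way such scaling exponents are read off.

The classifier's physical envelope: collapsed chains follow ν ≈ 0.33–0.35,
random coils ν ≈ 0.5, rods ν = 1. At ν = 1 the statistic of a globule
(R₀ = 2.2 Å, ν = 0.35) is `2.2·N^−0.65`, which falls below 0.26 Å from
N = 27 on; shorter compact chains can exceed the threshold. This is the
known failure mode of the method — short chains (often disulfide-stabilized)
are the dominant false positives — and is why the curation filters exclude
small disulfide-rich domains, coiled coils and transmembrane chains from
negative sets.

## SASA and interfaces

SASA uses the Shrake–Rupley construction: each heavy atom's sphere is
expanded by the probe radius (1.4 Å) and sampled with a deterministic
golden-angle (Fibonacci) spiral of 960 points; a point is accessible if it
lies outside every neighbouring expanded sphere. Determinism makes results
reproducible to the bit and the point count a pure accuracy knob
(isolated-sphere error ≈ 5·10⁻¹⁴ %, two-sphere spherical-cap error
≈ 0.4 % at 960 points; totals move < 0.3 % on doubling the count).
Hydrogens are ignored — crystal structures rarely resolve them — and
heavy-atom radii follow the ProtOr group convention, with CHARMM22 radii
for Zn²⁺ (1.09 Å), Ca²⁺ (1.367 Å) and Na⁺ (1.36375 Å). Neighbor search is
a KD-tree; output is contractually identical to all-pairs enumeration.

Interfaces are defined by burial: three SASA runs under one configuration
(complex, segment alone, partner group alone) give per-residue
`ΔSASA = SASA_free − SASA_bound`; residues with ΔSASA > ε are interface
residues. ε = 0.1 Ų suppresses point-sampling noise on what is nominally
"any positive change". The interface area is the half-sum of buried area
over both sides, which makes it symmetric under exchanging segment and
partner. With more than two chains the partner group is the union of all
other polymer chains, treated as one rigid body.

Relative SASA divides a residue's SASA by that of the same residue type
in an extended (φ = ψ = 180°) Gly-X-Gly tripeptide, built internally with
ideal backbone geometry and heavy-atom side-chain templates from the
chemical component dictionary. Computing the reference with the same
radii, probe and point set as the query keeps the 0.25 rSASA decision
self-consistent; the extended conformer is the conventional
maximum-exposure reference. Region assignment follows the Levy scheme:
rim if rSASA > 0.25 in the complex; core if ≤ 0.25 in the complex but
> 0.25 free; support if buried in both states (support residues are kept
out of core and rim compositions). Composition profiles are fractions over
the 20 types, ordered from order-promoting (W) to disorder-promoting (K)
residues; enrichment is a per-type difference of profiles, and per-complex
averaging (not pooling) is used when aggregating across complexes so that
large interfaces do not dominate.

## Contacts

Salt bridges are counted as *atom pairs*: any side-chain donor nitrogen
(ARG NE/NH1/NH2, LYS NZ, HIS ND1/NE2) and side-chain acceptor oxygen
(ASP OD1/OD2, GLU OE1/OE2) across the interface strictly closer than
4.0 Å, with the N-terminal amine and C-terminal carboxylate included by
default. Histidine is treated as a donor (configurable off) since it is
conventionally grouped with the charged residues. A bidentate
arginine–glutamate pairing therefore contributes up to four bridges;
residue-pair aggregation is a trivial post-processing step on the output.

Hydrogen bonds use geometric criteria: donor–acceptor heavy-atom distance
≤ 3.9 Å, plus an angular test. For backbone amides a hydrogen is placed on
the C(i−1)–N / CA–N bisector at 1.0 Å and the D–H···A angle must be
≥ 90°; for donors whose hydrogens cannot be placed from ideal geometry the
angle at the donor between its bonded heavy atom and the acceptor must be
≥ 90°. Aromatic-ring acceptors are not considered. These are deliberately
simple, documented criteria in the spirit of the HBPlus defaults, not a
re-implementation of that program.

Disulfides are CYS SG–SG pairs within 2.5 Å (canonical bond 2.05 Å plus
coordinate error), matched greedily nearest-first so each SG joins at most
one bond. Contact counts are also reported per 100 Ų of interface area.

## Curation and redundancy

A chain enters classification iff it has > 20 residues with coordinates,
has some partner chain with > 70 residues, is not a short (< 100 residue)
chain with ≥ 2 disulfides, and is not on an external exclusion list
(coiled-coil and transmembrane detection are delegated to external tools;
their output is consumed as `structure_id:chain_id` lists). Rules are
evaluated independently, so a report names every rule a chain fails.

Redundancy removal builds a graph with an edge wherever pairwise percent
identity exceeds the Rost HSSP-curve threshold
`n + 480·L^(−0.32·(1+e^(−L/1000)))` (n = 3, L = alignment length, capped
at 100 %), then keeps one representative per connected component: best
resolution, then longest, then lexicographically first. Identities come
from a global BLOSUM62 alignment with gap penalties 10/0.5 and are
computed as identical columns over alignment length, gaps included. The
curve is steeply decreasing over typical domain lengths and mildly
non-monotone past L ≈ 300 — a property of the published functional form,
kept as-is.

## Evaluation

ROC curves sweep all distinct score thresholds; AUC is trapezoidal and
equals the Mann–Whitney pair-counting statistic with half-credit ties
(asserted to 1e-12 in tests). MCC uses the standard Matthews formula with
the 0-by-convention degenerate case. Threshold selection follows the
resampling protocol: 1000 repetitions, each drawing half of each class
without replacement, MCC evaluated on a threshold grid; the chosen
threshold maximizes the mean MCC (lowest grid point on ties), and FDR and
sensitivity are then re-evaluated on the full data at that threshold. All
resampling is seeded and the seed is recorded in reports. Rank-based group
comparisons use the two-sided Mann–Whitney test, exact for small tie-free
samples and normal-approximated with tie correction otherwise.

## Synthetic data: what it shows and what it does not

The fixture generator produces the geometric classes the classifier is
built to separate: extended CA traces (spacing 3.8 Å, the trans-peptide
virtual bond), ideal α-helices (rise 1.5 Å, radius 2.3 Å, 100°/residue),
fixed-step random walks, and isotropic globules rescaled so Rg = R₀·N^ν
holds exactly (defaults R₀ = 2.2 Å, ν = 0.35, the collapsed-chain
scaling). CA traces are decorated with geometrically placed N/C/O backbone
atoms, and designed toy complexes place full heavy-atom residues with
verified contact distances (±0.01 Å). The synthetic benchmark in
`scripts/acceptance.py` uses 52 positives (short extended/random-walk
segments, N ∈ [21, 120]) against 762 globular negatives (N ∈ [71, 500]) —
the class sizes of the study design — and 500 random walks of N ∈ [50, 500]
for the Flory fit.

These fixtures validate the geometry, the decision rule, the SASA
machinery and the statistics against closed forms and independent
implementations. They do **not** establish real-data performance: real
bound ID segments are neither perfect rods nor ideal walks, real globular
chains scatter around their scaling law, and real interfaces have packed,
chemically heterogeneous cores. Near-perfect AUC/MCC on the synthetic
benchmark reflects the designed separation of the classes, not an expected
error rate on the PDB. Validation against real structures is wired in as
an accession-based test (place PDB entries 1JSU, 1ACB, 1WU9 under
`tests/data/accessions/`) and through the CLI on any local structure file.

## Numerical choices and limitations

* Altlocs resolve to the highest-occupancy conformer (first on ties);
  model 1 is used for multi-model files.
* `N` counts standard residues *with a CA atom*; modified residues with a
  mapped parent (MSE→MET, …) count, unmapped HETATM polymers do not.
* Fixture backbones are geometric, not energy-minimized; SASA and H-bond
  results on fixtures exercise code paths, not stereochemistry.
* No nucleic-acid support, no symmetry expansion, no Lee–Richards
  slicing, no aromatic/cation-π/water-mediated interactions.
* Problem sizes in tests and the acceptance script (960 sphere points,
  500-walk fits, 1000-rep resampling, toy complexes ≤ 500 atoms) were
  chosen so the whole suite runs in well under a minute on one CPU while
  keeping every oracle's tolerance comfortably met.
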