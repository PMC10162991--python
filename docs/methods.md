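# Methods

This note records the models, criteria, parameter choices and numerical
conventions behind `carriermd`, and what the synthetic-data generators
do and do not emulate.

## Units, axes and periodic boundaries

Coordinates and box lengths are in Å, times in ns (trajectory formats
that store picoseconds are converted on read/write). Only orthorhombic
boxes are supported; triclinic input raises an explicit error. The
transmembrane axis is the box z-axis by convention — no axis fitting is
performed — matching the standard setup in which the membrane normal is
aligned with z during system building.

All inter-group distances use the minimum-image convention under the
frame's box (plain Euclidean distances when the box is absent). Whether
published trajectory analyses of this kind used minimum-image or
unwrapped coordinates is generally not stated; minimum image is adopted
here because it is well defined for any wrapped trajectory, and it is
applied uniformly.

XTC output is written with 10⁻⁴ nm coordinate precision so that
write/read round-trips stay within 10⁻³ Å, the package's stated format
tolerance.

## Atom selections

A small expression language (`resid`, `resname`, `name`, `segid`,
ranges, `and`/`or`/`not`, parentheses) is implemented in the package
rather than delegated to a trajectory library, so the selection
semantics are part of this package's contract and independent of any
third-party grammar. Resolution is deterministic; empty selections are
representable and flagged, and analysis entry points reject them with
the offending group named.

## Interaction criteria

* Contact: minimum cross-pair distance < 3.0 Å, strict inequality. All
  atoms participate, including hydrogens; a `heavy_only` flag exists for
  sensitivity checks.
* Hydrogen bond: donor–acceptor distance < 3.3 Å and donor–H–acceptor
  angle > 140°, both strict. Explicit hydrogens are required; the
  criterion is undefined without them and the code says so. Sidechain
  donor/acceptor chemistry for the standard residues is tabulated in
  `data/hbond_chemistry.yaml`; for ligands a generic rule applies
  (N/O/S with an attached hydrogen donates, any N/O accepts), with
  hydrogen attachment resolved from topology bonds when present and
  otherwise from a ≤ 1.25 Å geometric rule on the first analysed frame.
* Pi interaction: at least three atoms of one aromatic protein ring
  (PHE/TYR/HIS rings; TRP's five- and six-membered rings tested
  separately) within 3.8 Å of the pooled nucleotide ring atoms (both
  purine rings, or the pyrimidine ring). The criterion counts atoms
  only; no ring-plane geometry is checked, which is the literal reading
  of the distance-based definition.
* Salt bridge: an ARG/LYS–ASP/GLU pair is bonded in a frame when any
  sidechain donor/acceptor combination satisfies the hydrogen-bond
  criterion.

Contact-time decomposition: per frame a residue–ligand interaction is
classed *hydrogen-bonded* if any H-bond exists, else *pi* if the pi
criterion holds, else *plain contact*. The three classes are mutually
exclusive with H-bond precedence, so the stacked components sum exactly
to the total interaction time. This resolves the overlap ambiguity of
stacked-bar contact figures in a documented direction.

Analysis windows default to \[200 ns, trajectory end\]: the first 200 ns
of a binding trajectory are treated as equilibration and excluded from
all time fractions. Replica SEM is the sample standard deviation over
replicas divided by √n and is reported as absent (NaN), not zero, for a
single replica.

The ligand orientation observable is the cosine of the angle between
the phosphate→base center-of-mass vector and +z; the exact atom content
of the two moieties is resolved by nucleotide atom-name conventions
(phosphate P/O names, primed ribose names, base names), documented in
`chemistry.py`. The protein center is the unweighted mean of a
user-supplied set of Cα atoms — canonically the 18 alpha carbons of the
residue 27–29 triplets (odd helices) and 83–85 triplets (even helices)
of the carrier fold.

## Water permeation

The membrane slab is split into three equal-thickness z-regions. A
crossing starts when a water oxygen enters the slab from outside
(bottom → region 1 for +z, top → region 3 for −z), advances when the
next region in order is reached (temporary regressions do not cancel
progress: the criterion is visiting the three regions in order), and
counts only if the molecule exits on the far side having stayed within
15 Å of the nearest protein atom at every in-slab frame. A per-frame z
displacement larger than half the box height is a periodic-boundary
wrap and resets the crossing, eliminating the classic false positive of
water diffusing across the periodic boundary. The rules are symmetric
in ±z, so time-reversing a trajectory exactly swaps the +z and −z event
counts — a property the tests assert.

Slab bounds default to the mean z of the lower- and upper-leaflet
phosphorus atoms (leaflets split at the median), overridable
explicitly. Water is tracked by its oxygen only.

## Helix splay

At each grid point z (1 Å step by default), each helix's mean Cα (x, y)
over Cα atoms with |z_Cα − z| ≤ 6 Å (half the 12 Å running window) is
computed; R_XY(z) is the root-mean-square distance of those per-helix
means from their average, over the N helices with data at that z.
Helices with no Cα in a window are dropped from N rather than imputed;
grid points with no helix at all are absent (NaN), never zero.
Per-frame profiles are averaged over frames (`mode="mean"`) or taken
from the final frame (`mode="last"`), and replica averaging is provided
separately; both modes exist because published profiles do not always
state which was used.

## Pose clustering

Each frame is fitted to a reference frame by the optimal least-squares
rigid transform (Kabsch, SVD with determinant correction, reflections
excluded) on the transmembrane-helix Cα atoms; the transform is applied
to the ligand atoms and the flattened coordinates form the pose matrix.
Stage 1 cuts a Ward-linkage dendrogram (Euclidean metric) at k
clusters; `k="auto"` maximises the silhouette score over k ∈ \[2, 6\].
Stage 2 runs K-means initialised from the stage-1 centroids (single
initialisation, tolerance 10⁻⁶, ≤ 500 iterations), which is the natural
reading of "agglomerative clustering followed by K-means" and makes the
procedure deterministic given (data, k, seed). The representative
configuration of a cluster is the member frame nearest its K-means
centroid, ties broken toward the lowest frame index. Published
implementations of the two-stage scheme differ in their internal
defaults; this package fixes one documented procedure rather than
emulating any particular tool. A degenerate all-identical pose matrix
yields a single cluster with a warning.

## Triplet mapping and sequence identity

Repeat boundaries are user input (three ordered, non-overlapping
residue intervals), not inferred: the decomposition of a carrier into
its two-helix repeats follows structural assignments that a tool should
consume, not decide — including single-column adjustments made on
structural grounds, which are representable as alternative input
alignments. Each aligned row must degap exactly to its sequence slice
(validated, first discrepancy reported). Fully ungapped columns become
triplets labelled by the three one-letter codes plus the first-repeat
residue number; gapped columns are reported as incomplete. Labels
round-trip through `parse_triplet_label`.

Percent identity divides identical column pairs by the number of
co-ungapped columns by default (alignment length and
shorter-sequence-length denominators are provided for sensitivity,
since published identity figures rarely state the denominator), and is
rounded to integer percent.

The packaged `synthetic_carrier_sequence()` is a SYNTHETIC stand-in for
a rat-UCP1-like repeat decomposition: the residues whose identities and
positions are documented in the carrier literature (A27, I29, K38/K138,
Q83–Q85, R84/R183/R277, F88/I187/W281, Q85/N184/L278, R92/E191, N188)
are placed at their real positions with gap placements reproducing the
real per-block numbering offsets (+100 in the helix-1/2 block, +99/+193
in the binding-site block); all other residues are deterministic
filler. It exists so the triplet machinery is testable offline; it must
not be used for identity comparisons against real sequences, and the
test asserting published UCP-family identities (58%/20%) requires the
real sequences to be supplied.

## Respirometry

Flux is the negative time derivative of the O₂ concentration (central
differences, optional moving-average smoothing), consumption positive.
Phase fluxes average the flux over \[t_inj + lag, t_inj + lag + 60 s\];
the lag defaults to 0 s and is exposed because protocols differ on
whether the window starts at the injection or after visual
stabilisation. Windows overrunning the next injection are truncated and
flagged. Metrics: RCR = F_ADP/F_oligomycin; activation fraction
(F_FA − F_NADH)/(F_CCCP − F_NADH) — the NADH baseline is subtracted
from numerator and denominator alike, the symmetric reading of
"normalised by the CCCP flux after removing NADH", and flagged here as
an interpretation; inhibition rate 1 − (F_nuc − F_NADH)/(F_FA − F_NADH).
All three are ratios of flux differences and invariant to uniform flux
rescaling (asserted to 10⁻¹²). Replicate summaries use
linear-interpolation (type-7) quartiles — boxplot statistics depend on
the quartile method, hence the documentation — and 1.5·IQR whiskers
clipped to the data range. Inferential statistics (ANOVA, post-tests)
are deliberately out of scope; the package emits tidy per-replicate
tables for external tools.

## Synthetic data: what it emulates, and what it does not

The generators produce geometry that is *decidable*, not physical:
there is no force field, no dynamics, no lipids beyond
phosphorus-plane markers, and no solvent beyond scripted single-atom
"waters". Scheduled pocket geometry places every atom at least 0.2 Å
inside or outside each detection threshold (hydrogen bonds at 2.85 Å
donor–acceptor with a collinear hydrogen; plain contacts via an apolar
Cβ at 2.5 Å with all polar atoms retracted beyond 3.5 Å; pi stacks
parallel at 3.5 Å; retracted residues at ≥ 10 Å), so detector/truth
agreement is exact and independent of floating-point rounding — which
states a residue type can realise is validated up front. Water scripts
are piecewise-linear z-paths; bundle helices are vertical Cα stacks
(1.5 Å rise) with closed-form splay truth derived from the placement
functions. Oxygraph traces are piecewise linear with phase changes on
sample times and injections annotated one sample later, so that
central-difference fluxes inside the averaging windows are exact at
zero noise. One integer seed drives each generator; identical seeds
give byte-identical outputs.

Passing the planted-truth tests therefore demonstrates that the
*analysis operators* implement their criteria exactly; it does not
demonstrate robustness to the ambiguities of real trajectories
(imperfect hydrogen placement, wrapped ligands spanning the boundary,
tilted membranes, instrument drift in oxygraph traces). Problem sizes
in the test suite and acceptance script — tens of frames, hundreds of
atoms, hundreds of oracle instances — are chosen so the whole
verification runs in seconds on one CPU while still exercising every
code path; the detectors themselves are O(N·M) per frame pair-counts
and scale to real systems.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* No cation–pi, halogen-bond or water-mediated interaction detection;
  no interaction energies.
* Center-of-mass calculations do not unwrap molecules across the
  periodic boundary; ligands should be kept whole upstream.
* The hydrogen-assignment fallback is geometric and assumes chemically
  reasonable input coordinates on the first analysed frame.
* Permeation counting requires the slab to be thinner than the box and
  samples dense enough that a genuine crossing does not move more than
  half a box length per frame (a physical certainty for MD output).
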