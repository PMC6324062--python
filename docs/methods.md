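# Methods

This note documents the models, parameters and numerical choices behind
`cgmem`, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Coordinate model and units

All internal lengths are Å; GRO files (nm) are converted on read/write.
Boxes are orthorhombic only; triclinic input raises an explicit
unsupported-format error. The membrane normal is z. The minimum-image
convention is applied laterally (x, y) only — z is non-periodic, the
standard geometry for a bilayer spanning the box in-plane. Residue indices
are 1-based, following GRO/PDB conventions. Lipid molecules are grouped by
(residue name, residue index) because CG coordinate formats carry no bonds;
each lipid must contain exactly one phosphate bead. GRO carries no chain
identifiers, so frames read from GRO place all protein beads in chain "A";
PDB chain IDs are preserved.

Bead chemistry is table-driven: DPPC (NC3 → choline, PO4 → phosphate,
GL1/GL2 → glycerol, C1A..C4A / C1B..C4B → tail positions 1–4), MARTINI
water W, ions NA+/CL−, and the 20 standard amino acids (any bead name).
Other lipid species can be added through a YAML table. Ions are tracked
separately from water internally and merged into "solvent" only for
fractions and display.

## Leaflets and flip-flops

Leaflets are the two large connected components of a graph over phosphate
beads with edges below `leaflet_graph_cutoff` = 15 Å. A graph, rather than
a z-threshold, keeps the assignment correct for curved or locally deformed
bilayers — the deformation analysis would be self-defeating otherwise.
"Large" means ≥ max(2, 5% of lipids); smaller satellites (e.g. a lipid
caught between leaflets) are attached to the component of their nearest
phosphate neighbour. Anything other than exactly two large components is a
non-bilayer state and raises an error carrying the component count. UPPER
is the component with the greater mean z.

A flip-flop is emitted when a lipid's leaflet label changes and the new
label persists: maximal constant-label runs of length ≥ `persistence_frames`
(default 5) are "stable" (the first run, the initial condition, is always
stable); consecutive stable runs with different labels yield one event with
`start_frame` = first frame after the old stable run and `end_frame` =
first frame of the new one. Single-frame flickers are treated as noise.

## Head-group RDF and annular shells

Each phosphate's r is its minimum-image distance to the nearest protein
bead, i.e. distance to the protein surface rather than to a centroid, so
non-globular proteins are handled. g(r) divides the per-bin count by
ρ·2πr·Δr with ρ = N_phosphates/(Lx·Ly). Because each leaflet is
approximately planar at a fixed z-offset from the protein midplane, the ring
area element satisfies l·dl = r·dr and the offset cancels: g → 1 in the
bulk without any leaflet bookkeeping. Defaults: bin width 1 Å, r_max 40 Å
(must not exceed half the smallest lateral box edge), moving-average
smoothing over 3 bins. Shell boundaries are the radii of the first k local
minima (default k = 2 — the number of shells to delineate is exposed rather
than fixed) of the smoothed g beyond its first maximum.

## Membrane surfaces, thickness, deformation

Each leaflet's surface is a Nadaraya–Watson estimate on a lateral grid
(default spacing 2 Å): the Gaussian-weighted mean phosphate z with
bandwidth σ = 5 Å and a 3σ support cutoff; cells with no phosphate within
3σ are NaN. Thickness is upper minus lower surface — phosphate centroid to
phosphate centroid. Bulk thickness is the mean thickness over cells farther
from any protein bead than the second annular shell boundary (fallback
25 Å when no RDF is available); if no cell qualifies, the 25% of defined
cells farthest from the protein are used, with a warning. The deformation
map is thickness − bulk, so its mean over bulk cells is zero by
construction.

The kernel bandwidth sets the lateral resolution: planted features narrower
than ~2σ are attenuated (a Gaussian dip of 1/e-radius 10 Å loses ~a third
of its depth). The fixture's planted deformation is therefore a plateau
profile (super-Gaussian, exponent 6), whose depth survives smoothing; the
analytic-surface oracle test tolerates a median error of 1 Å at the plateau
edge for the same reason.

Per-residue depth is the residue position (backbone bead if present, else
bead centroid) minus the local midplane z of the nearest supported grid
cell; local thickness is read from the same cell. Residues farther than 1.5
grid spacings from any supported cell fall back to the bulk value and are
flagged.

## Contacts

A contact is a protein bead–other bead pair within `cutoff` (default 6 Å,
the common CG bead-contact convention; exposed as a parameter since no
single value is canonical). Counting is per bead pair — a lipid touching a
residue through three beads contributes three counts — because the
sequence-viewer tracks are per bead class. Counts accumulate over all
supplied frames; the CLI analyses the final 10% of frames by default to
approximate post-assembly snapshot behaviour, and both raw counts and the
number of frames analysed are stored so either convention (raw or
per-frame) is derivable. Contacts with lipids that have a flip-flop event
overlapping the analysed window are additionally tallied in a flip-lipid
track. Head = choline+phosphate+glycerol, tail = tail 1–4, solvent =
water+ions; fractions are defined for residues with ≥ 1 contact and sum
to 1. The environment label is the argmax of (head, tail, solvent) counts,
ties broken HEADGROUP > ACYL_TAIL > SOLVENT; zero contacts ⇒ BURIED.

## Topology

Geometric secondary structure from CG backbone beads is necessarily
approximate: windows with d(i, i+3) ∈ [4.2, 6.2] Å mark helix (an ideal CG
helix has d(i,i+3) ≈ 5.1 Å), remaining windows with d(i, i+2) ∈
[6.2, 7.8] Å mark strand, with minimum segment lengths 4 (H) and 3 (E). A
user-supplied SS string always takes precedence — assignments derived from
an atomistic model are more reliable than CG geometry.

A helix/strand segment is TM when at least one residue lies beyond each
leaflet surface, evaluated at each residue's own lateral position, so
locally deformed membranes are treated consistently with the surface
module. Tilt is the angle between the segment's principal (SVD) axis and z.
A chain is MEMBRANE_SPANNING with ≥ 1 TM segment; otherwise INTERFACIAL
when ≥ 20% of residues have |depth| within ±6 Å of the half-thickness —
this band rule is this package's documented choice, not an established
convention — otherwise SOLUBLE. The density profile is a 1 Å histogram of
residue depths.

For the 2D diagram each chain is projected onto the plane spanned by the
membrane normal and the chain's principal lateral direction (PCA over the
TM segments' lateral axis components — one coherent plane per chain).
Helix traces are smoothed with a 4-residue moving average first: the
backbone wobbles ±2.3 Å about the helix axis, and the diagram should trace
the axis. Each segment starts as the straight chord between its terminal
projections (a cubic Bézier with collinear control points); while the local
fit RMSD (3-point window) exceeds `kink_tol` = 2 Å, a knot is inserted at
the worst-fit parameter and a weighted least-squares cubic B-spline is
refitted (endpoints pinned by weight 10⁶, so they coincide with the
terminal projections to ≪ 0.1 Å). Starting from the chord, rather than a
free cubic, is what makes kinks the feature that earns knots: a free cubic
absorbs a 30° bend with < 2 Å residual, and no knot would ever be placed.
The recorded RMSD history is non-increasing (insertions that fail the
Schoenberg–Whitney condition or would not reduce the residual stop the
loop). Segments shorter than 4 residues fall back to a flagged polyline.
Loops are polylines, marked non-continuous (rendered dashed) when
consecutive residues jump > 10 Å. The membrane band samples both local
surfaces along the projection axis.

## Ensemble analyses

The built-in aligner is dependency-free progressive MSA: pairwise global
alignments (BLOSUM62, gap open −10, extend −0.5) give percent-identity
distances; a neighbour-joining guide tree orders profile–profile merges;
profiles are aligned by an affine-gap Gotoh DP whose column score is the
composition-averaged BLOSUM62 score (residue–gap pairs score 0). An
external MSA tool (e.g. MAFFT) can be plugged in through a command adapter
when fidelity to a specific aligner matters. Aggregation carries
per-residue head/tail/solvent fractions, SS and depth onto alignment
columns; consensus SS is the modal character over members with a residue at
the column, conservation its fraction, and coverage the fraction of
members without a gap.

The propensity scale treats "probability of contact" as residue-level
incidence: p(aa, cat) = (surface residues of type aa with ≥ 1 contact in
the category) / (surface residues of type aa), where "surface" means ≥ 1
non-protein contact. Incidence keeps abundant residue types from
dominating; a count-share alternative (category's share of the type's total
contacts) is available as a mode. Normalization anchors glycine at 0 and
the maximum at 100: s = 100·(p − p_Gly)/(max p − p_Gly). Types less
contact-prone than glycine take negative values; if the maximum equals
glycine's probability, the denominator vanishes and the scale is undefined
(an error).

Depth distributions use z′ = 2·depth/local thickness, which places the
phosphate surfaces at ±1 and removes membrane-thickness variation between
structures (the ±1 convention is this package's choice). Pore-inner
residues are discounted under a concrete rule of this package's own
devising: solvent-contacting, |z′| < 0.8, and laterally inside the 2D
convex hull of the chain's TM segment axes; without TM axes no pore
exclusion is applied. Histograms cover z′ ∈ [−2, 2] in 0.1 bins; relative
mode normalizes each type to sum 1. Types are clustered by average-linkage
hierarchical clustering on the Jensen–Shannon distance between relative
histograms, cut at 4 clusters by default (the hydrophobic-core /
interfacial-aromatic / basic / polar-solvent pattern); amino acids enter in
lexicographic order so merges are deterministic. Thickness summaries report
per-class (α-helical vs β-barrel) mean and population-convention standard
deviation (one member ⇒ sd 0).

## Synthetic fixtures

The generator emulates post-assembly snapshots: DPPC lipids on a jittered
lattice (64 Å² per lipid, 1 Å jitter — typical fluid-phase PC), 12 beads
per lipid in the canonical vertical arrangement (NC3 3 Å outside the PO4
plane; GL1/GL2 3 Å inside; tail beads stepping 3.1 Å toward the midplane),
phosphate planes at a chosen separation (37 Å default, the class-typical
value for α-helical-protein membranes; 33 Å for the β-barrel class);
idealised proteins as backbone-bead traces (helices: 1.5 Å rise, 100°/turn,
2.3 Å radius; strands: 3.3 Å rise with a small zig-zag), with extramembrane
connecting loops; water on a 5 Å lattice outside the membrane slab; 10 ions
of each species. When a protein is present, an explicit annular ring of
lipids is placed one bead-diameter outside the protein's exclusion radius,
because a jittered lattice alone leaves angular gaps that would make
genuinely lipid-facing residues appear buried. Planted flips mirror a lipid
through the midplane at a stated frame. Planted deformations are plateau-
shaped radial thinnings (see above). Per-frame bead noise is 0.3× the
lattice jitter. Everything is deterministic under the seed.

Planted environment truth labels only unambiguous residues: outward-facing
(beyond the bundle/barrel radius) and inside clear z-bands (acyl band
|dz| ≤ t/2 − 6, head band t/2 − 3 ≤ |dz| ≤ t/2 + 2, solvent |dz| ≥
t/2 + 7); transition-zone and inward-facing residues carry no label.

What the fixtures do **not** emulate: thermal disorder beyond isotropic
jitter, lipid tail conformational entropy, protein side chains (backbone
beads only), curvature, realistic water density, or any dynamics — frames
are independently jittered statics. Passing tests therefore demonstrate the
correctness of the geometric and statistical machinery on systems with
known truth, not the biophysical fidelity of any simulation.

The cohort generator samples per-category Bernoulli contact incidences per
residue; a residue that draws no contact at all receives one water contact
(so the propensity denominator equals the cohort size and head/tail
recovery is unbiased; effective solvent incidence is then
p_s + (1−p_s)(1−p_h)(1−p_t), the closed form used as the test oracle).

## Problem sizes and defaults used in the shipped analyses

The worked GPCR-like example uses 128 lipids/leaflet (≈ 90 Å box) and 3
frames; flat thickness-recovery fixtures use 256 lipids/leaflet (128 Å
box); unit tests mostly use 64 lipids/leaflet. These sizes give sub-0.1 Å
standard errors on bulk thickness and stable contact statistics while
keeping each analysis in seconds.

## Known limitations

- Leaflet assignment requires phosphate-bearing lipids; phosphate-free
  species (e.g. cholesterol) are out of scope.
- Geometric SS assignment is coarse; supply an SS string for production
  use.
- The INTERFACIAL band rule and the pore-exclusion rule are package
  choices, documented above, not community conventions.
- Multi-frame input is a list of single-frame files or a multi-model PDB;
  binary trajectory formats are not read directly (convert first, or adapt
  via MDAnalysis).
- The built-in progressive aligner is adequate for closely related
  sequences; for distant homologues use the MAFFT adapter.
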