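# Methods

## Scope and model

`gliamorph` quantifies microglial morphology on single-channel confocal
z-stacks. Microglia are treated as planar objects: a roughly circular soma
from which a tree of processes radiates. All analysis is two-dimensional —
each stack is divided into three contiguous ~10 µm sub-volumes (6/5/5
planes for the default 16-plane, 2 µm-step acquisition; earlier blocks take
the remainder) and each sub-volume is reduced by maximum-intensity
projection. The per-cell criteria are:

* **body area** and **roundness** `4πA/P²` of the soma mask;
* **cytoplasm area** — soma plus the foreground covering the order-1
  (primary) processes only;
* branch counts by order (primary = touching the soma contour; +1 at every
  junction; orders ≥ 3 folded into "tertiary") and total process length;
* **complexity index** `CI = n_segments / n_primary`, the mean branching
  complexity per primary process; `CI = 1` ⇔ no junction nodes ⇔ the
  amoeboid phenotype;
* **covered environment area** `CEA` — the planar territory spanned by the
  process extremities. We take the *convex hull* of the endpoints: the
  phrase "polygon linking the extremities" fixes no vertex order, and the
  hull is the unique order-free reading;
* **areal density** — retained cells per mm² of scanned tissue.

## Segmentation

The projection is Gaussian-smoothed (σ = 0.3 µm) and thresholded globally
(Otsu by default; a median+6·MAD background rule is available for very
sparse fields). Somata are isolated by binary opening with a 2 µm disk —
wider than any process, narrower than any soma — and labelled. The
foreground minus a 2-px-dilated soma mask is thinned (Lee skeleton) and
converted to a graph: pixels whose reduced 8-adjacency degree differs
from 2 become endpoint/junction nodes (diagonal links that shortcut an
orthogonal pair are discarded first, which removes staircase artefacts),
and the degree-2 chains between them become segments. Segment length is
measured on the Douglas–Peucker-simplified polyline (tolerance 1 px),
because the raw 8-connected step length overestimates oblique lines by up
to ~8 %.

Cleanup, in order: terminal spurs < 0.6 µm are pruned; junction pairs
joined by an edge < 0.9 µm are contracted (thick junctions thin into two
nearby nodes); clusters of soma-contact nodes joined by edges < 2.2 µm are
fused into one root, and contact-to-contact stubs < 2 µm are dropped (the
flat cut at the soma produces "fishtail" forks); pass-through degree-2
nodes are re-merged throughout. Each connected component is attributed to
the body whose contour it approaches within 1 µm (plus the 2-px cut
margin); components touching several bodies are divided by geodesic
distance along the skeleton, which splits a connecting path at its
midpoint; components touching none are returned flagged unattributed.
Primary segment lengths include the small root-to-contour gap the soma cut
removes. Cells whose processes were all pruned are reported with
`n_primary = 0`, `CI = 1`, amoeboid — operationally an amoeboid form has
at most stub processes without branch nodes.

Branch ordering walks outward from the root contacts: edges leaving a root
are order 1; the order increments at nodes of degree ≥ 3 and is carried
through degree-2 continuations.

## Population filtering

Size outliers (body < 10 or > 500 µm²) and noisy forms (roundness < 0.7)
are rejected; the inequalities are strict, so boundary values survive.
Edge cells are removed when the bounding extent of hull ∪ body enters the
border band (default width 0 µm: touching the border suffices); for an
axis-aligned band the bbox test is exact. Duplicates are cells on
*adjacent* sub-volumes within 5 µm (≈ one soma radius) centroid distance —
the matching radius and rule are ours, the goal (no double counting) is
standard; matched groups keep the largest body, ties keep the lower
sub-volume index. Roundness is normalized by 4π so a circle scores 1; the
perimeter comes from the simplified half-level contour, whose staircase
removal lets a rasterized disc approach its analytic limit (a square
scores ≈ 0.79 and passes the 0.7 gate; elongated debris does not).

## Clustering and sub-populations

k-means (k = 4, k-means++, 10 restarts, fixed seed) runs on z-scored
(CI, CEA): CEA spans 10²–10³ µm² while CI stays below ~10, so unscaled
clustering would be CEA-only. Clusters are renumbered by descending
frequency. Quadrant sub-populations use cell-pooled control means as
cutoffs (clustering is cell-level, so the "average in the control group"
is read at cell level): SP1 (−/−), SP2 (CI high only), SP3 (CEA high
only), SP4 (+/+); "high" is strictly above the cutoff, values at the
cutoff are low. Amoeboid cells are excluded from both views by default
(`include_amoeboid=True` restores them) since their CI is pinned at 1.
A Pearson/Spearman + 2-feature-PCA screen warns at |r| > 0.7 before
clustering is trusted.

## Statistics

Animals are the sampling units: per-animal means/medians of each criterion
feed the tests. Two groups: Shapiro–Wilk at α = 0.05 per group gates
Student's t (equal variances) vs Mann–Whitney; MW is exact for ≤ 12 per
group without ties, tie-corrected normal approximation otherwise, and a U
at its null midpoint reports p = 1. Three or more groups: Kruskal–Wallis.
Phenotype distributions: chi-square without continuity correction.
Correlations: Spearman. No multiple-testing correction is applied.

The sample-size calculator uses the classical normal approximation
`n = 2 t σ²/(m̄_A − m̄_B)²` per group with
`t = (z_{1−α/2} + z_{1−β})² ≈ 10.507` at α = 0.05, power 0.90, and ceiling
rounding. The noncentral-t (iterated) solution gives systematically larger
n (e.g. 8 instead of 7 at d ≈ 1.78) and is deliberately not used; the
normal-approximation constant is the documented convention of this
package.

## Synthetic tissue generator

The generator is the package's ground-truth source, not a fixture. A cell
is a rooted tree of polyline segments drawn in continuous µm coordinates:
`n_primary` processes start on the soma contour in disjoint angular
sectors; a segment of order *o* bifurcates with probability
`branch_prob_per_order[o−1]` into two children that inherit disjoint
halves of the parent's sector. Segment lengths are normal, truncated to
[max(2.5, µ−2σ), µ+2σ]. Sibling headings are forced at least ~27° apart
at the junction and segments run straight for their first 4 µm (the
"launch"), after which bounded turning noise (σ = 6°/step) resumes;
positions are steered to keep a ~2 µm arc clearance from sector
boundaries. These three rules exist so that *rendered* topology equals
*drawn* topology: every junction is resolvable at the 0.19 µm / 0.7 µm
(pixel/process) scale, which is what makes the generator a valid oracle
for the measurement chain. Five archetypes realize the four
high/low CI × CEA phenotypes (CI ≈ 1.9 vs ≈ 5, hull territories of
~10² vs ~10³ µm²) plus the amoeboid form (two unbranched thick stubs,
CI ≡ 1). Published descriptions of these phenotypes fix only the
*orderings* of such quantities, so the archetype parameters are calibrated
to preserve the orderings, not to reproduce any absolute regional value.

Truth records store the tree itself; CI/CEA/counts are recomputed from it
in tests by independent brute-force traversal and hull-by-triangulation.
Truth CEA uses a monotone-chain hull in continuous coordinates
(pixel-independent, and a different code path from the measurement side's
geometry library). Truth cytoplasm area uses the *realized* raster width
of a process — the declared thickness rounded to whole dilation pixels —
so the truth matches what any pixel-based measurement can see.

Rendering paints each cell into the middle plane of its assigned
sub-volume (maximum projection makes within-sub-volume plane choice
irrelevant; no PSF, bleaching or 3D structure is simulated), adds the
background level, then i.i.d. Gaussian noise. SNR is defined as
(process intensity − background)/noise SD. The soma disc is drawn with a
half-pixel pull-in to compensate rasterization/threshold bloom.

Placement is rejection sampling, largest-first, with a hard non-overlap
constraint using each cell's realized arbor radius (plus 2 µm clearance),
so ground truth stays unambiguous; `allow_overlap=True` produces dense
entangled networks at the price of ambiguous attribution. Failure names
the achievable count. When no raster is produced (`render=False`),
placement is unconstrained uniform, since arbors cannot collide.

Planted duplicates (`duplicate_fraction`) echo a cell onto an adjacent
sub-volume with ≤ 1 µm centroid jitter, emulating a soma caught by two
axial windows.

## Cohorts

`generate_cohort` simulates a two-condition design (default 7 control vs
6 treated animals, mirroring a typical LPS-challenge layout). Treatment
multiplies cytoplasm-area parameters by `cytoplasm_factor` (default 2 —
soma radius by √2, process thickness by 2), emulating the roughly twofold
cytoplasm enlargement under inflammatory activation while leaving CI and
CEA distributions unchanged. Animal-to-animal variability is lognormal on
size (CV 0.25), branching (CV 0.08) and reach (CV 0.10); the size CV was
chosen once as a typical inter-animal spread for morphometric means — it
is deliberately smaller than the between-group SDs printed for real
cohorts, which include staining and sampling variance the generator does
not model. Regional presets (frontal cortex, hippocampus, striatum,
cerebellum, uniform) vary the archetype mix and density; the cerebellum
preset is dominated by compact and amoeboid forms, giving it lower mean
CI, CEA and density than cortex, again an ordering rather than an
absolute calibration.

Because the truth-only mode feeds generator values directly into the
feature schema, cohort-level results validate the *statistical* machinery
(calibration, power, clustering recovery), not image measurement; the
rendered-tissue experiments validate the measurement chain separately.

## What passing tests do and do not show

The generator draws non-overlapping, sector-separated arbors on a clean
background. Real tissue has entangled networks, uneven illumination,
out-of-focus light and anisotropic PSFs; exact branch-count recovery on
synthetic renders therefore demonstrates the correctness of the
skeleton/graph/ordering logic, not field performance on dense tissue.
Similarly, the type-I/power results hold under the generator's lognormal
animal-effect model.

## Numerical choices and problem sizes

Default validation sizes: 200 rendered cells (five ~650 µm square tiles at
~100 cells/mm²) for segmentation recovery, noise-free and at SNR 5;
1000 random trees / 1000 random point sets for the CI/CEA oracles;
n = 2000 cells for mixture-recovery checks; 2000 simulated null cohorts
(10 cells/animal) for type-I calibration and 300 cohorts (25 cells/animal)
for power. Degenerate inputs: CEA of < 3 non-collinear points is 0; CI of
a process-free cell is undefined (the cell is reported amoeboid rather
than given a fake value); identical-sample comparisons report p = 1;
all-identical feature points make k-means fail loudly rather than return
arbitrary clusters. All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence`.

## Known limitations

* 2D only; processes crossing in projection are merged by the skeleton.
* No watershed separation of touching somata.
* The convex hull makes CEA insensitive to concavities of the territory.
* The detection stage is a standard high-content operator chain (Otsu,
  opening, thinning); its parameters are configurable defaults rather
  than values fitted to any particular instrument.
* Branch orders beyond 3 are folded into "tertiary".
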