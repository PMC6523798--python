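# Methods

`lassokit` studies lasso-shaped polymers: a closed loop of N segments
with one or two linear tails of t segments attached at a single bridge
vertex. Two model tracks are implemented — an ideal (phantom) track for
threading statistics and an excluded-volume Monte Carlo track for loop
shape under threading — plus a bridge to protein structures.

## Phantom lasso ensembles

Loops are equilateral closed polygons sampled from the uniform measure
on polygon space using action-angle (diagonal/dihedral) coordinates: the
fan diagonals d_1..d_{k-3} from vertex 0 and the dihedral angles about
them parametrize k-gon space, and Lebesgue measure on the valid region
of (diagonals, dihedrals) pushes forward to the uniform measure. We
sample the k-3 consecutive diagonal differences uniformly on [-1, 1],
reject any sequence violating a fan triangle inequality (d_i > 0,
d_i + d_{i-1} >= 1, d_{k-3} <= 2), draw dihedrals uniformly on [0, 2pi),
and rebuild the polygon triangle by triangle. Rejection preserves
uniformity; the sampler is validated against the exact equilateral-ring
result <Rg^2> = (N+1)/12 and against an independent crankshaft-fold
Markov chain (tests).

Tails are equilateral random walks (isotropic unit steps) anchored at
loop vertex 0, which plays the role of the covalent bridge; with two
tails both share that anchor, mirroring a disulfide joining both
termini. All phantom chains use unit edges — the analysis is
scale-free.

Seeding: each (N, t, sample) triple derives a child seed from the master
seed via `numpy` SeedSequence, so any cell or single conformation is
independently reproducible.

## Threading classification (minimal-surface method)

Threading is detected by spanning a near-minimal triangulated disk on
the loop and counting transversal tail crossings, signed by direction.

Construction. The initial triangulation is a greedy minimal-area ear
clipping of the 3D polygon: repeatedly remove the boundary vertex whose
ear triangle has the smallest area. This yields a tight interior-free
disk that hugs the loop. The mesh is then midpoint-subdivided towards a
target edge length (one loop-edge length, capped at `max_triangles` =
12000 triangles) and relaxed at each refinement level. Relaxation is a
monotone area descent: every interior vertex in turn is proposed at its
cotangent-Laplace average and the move is accepted, with backtracking
halving, only if it lowers the vertex-star area; sweeps stop when the
relative area decrease falls below 1e-4. The total area is therefore
non-increasing across sweeps, and the boundary (including subdivision
midpoints, which lie on the straight loop edges) stays exactly on the
loop.

A centroid-fan initialisation (`SurfaceParams(init="fan")`) is kept as
an alternative. It converges to a different, visibly "baggier" local
minimum for long random loops: the fan threads the cone through the
middle of the coil and area descent cannot change the disk's isotopy
class, which inflates spurious crossing pairs (at N = t = 500 it roughly
halves the trivial-lasso probability and lifts the domination number
from ~5 to ~8). The ear-clip surface reproduces the phantom-ensemble
anchors and is the default. This sensitivity is exactly the known
caveat of spanning-surface methods: piercing *parity* is a topological
invariant (tested under refinement), piercing *counts* are a property
of the spanned surface.

Crossing detection uses Moller-Trumbore segment/triangle intersection
with consistent mesh orientation; crossings within epsilon (1e-9 loop
edges) of the boundary curve or the anchor vertex are excluded, and
near-degenerate hits (on mesh edges, triangle corners, or segment
endpoints) trigger a deterministic retry with the whole tail shifted by
a tiny fixed vector (the anchor exclusion radius grows with the shift,
since the anchor lies on the surface). Raw transversal crossings are
reported without cancelling adjacent opposite-sign pairs; direction
classes are merged, so the class label is L0 (no crossings), L_n (one
tail, n crossings) or LL_{i,j} (both tails cross).

## Ensemble statistics

Per-(N, t) class counts give binomial probabilities and standard errors
(zero-variance cells are floored at 1/(2n) for weighting). The decay of
the trivial-lasso probability is fitted with

    P(x; L0) = P_inf + c_a exp(-alpha x) + c_b exp(-beta x)

by weighted nonlinear least squares with multi-start initialisation over
fast/slow rate pairs (0.3, 0.03) x (0.05, 0.005) — the two regimes
typically differ by an order of magnitude. Bounds: P_inf in [0, 1],
|amplitudes| <= 2, rates in [1/span, 10] where span is the fitted length
range. The rate floor is an identifiability constraint: a decay slower
than 1/span changes by less than a factor e across the data and trades
off against P_inf without bound. Because the constant is reached only
asymptotically, the fit needs the short-chain cells (the full diagonal
runs from N = 10) to pin the fast regime; with long cells alone the
asymptote is unidentifiable. The (N, t) probability surface uses the
same machinery with separate loop and tail exponentials sharing one
P_inf.

The piercing spectrum of a cell is summarised by the domination number
d(N, t): the largest p such that non-trivial lassos with at least p
piercings are a strict majority (ties do not count). An idealised
geometric model P(n) = p (1-p)^n with p equal to the asymptotic
trivial probability serves as an upper reference for the asymptotic
spectrum.

## Excluded-volume loop on a periodic thread

The loop is a ring of N beads with harmonic bonds (k = 20000
kJ/mol/nm^2, r0 = 0.38 nm) and purely repulsive A/r^12 excluded volume
(A = 0.16777216e-4 kJ nm^12/mol, cut at 2 nm) — a ~0.4 nm contact
diameter, slightly above the bond length so strands cannot cut through
each other. A thread of thickness factor w in {1..4} is an immobile
straight line of N_B = max(N/2 + 5, 12) beads spaced r0 apart, periodic
along its axis (box 0.38 N_B nm) so the loop cannot slip off; thread
beads are w times thicker than loop beads, implemented with additive
radii (loop-thread coefficient A ((1+w)/2)^12). w = 0 means no thread at
all. There are no angular or attractive terms. The smallest legal loop
per thickness is N_small = (3, 4, 6, 7, 7) for w = (0, 1, 2, 3, 4).

Sampling is Metropolis Monte Carlo rather than Langevin dynamics: every
observable here is an equilibrium ensemble average, and MC with the same
potential samples the same Boltzmann ensemble without an external MD
engine. Temperatures are Kelvin with energies in kJ/mol (beta =
1/(k_B T), k_B = 0.0083145 kJ/mol/K); T = 100 is the "most flexible"
condition used for all headline fits. The energy of overlapping beads
is capped per pair (1e6 kJ/mol) so the chain cannot produce infinities.

Moves: single-bead displacements (step auto-tuned to 30-50% acceptance
during a frozen-afterwards tuning phase) and crankshaft rotations about
the chord through the arc endpoints, which preserve every bond length
exactly and make the stiff-bond ring mix efficiently.  Crankshaft arcs
are mostly short (<= 12 beads); a quarter of proposals rotate arcs up
to half the ring — pivot-scale moves without which the global
size/shape modes of loops beyond ~200 beads stay correlated over
hundreds of recorded frames and independent runs disagree by several
quoted standard errors.  For w > 0 any move that would change the
loop's winding number around the thread axis (total signed angle of the
xy projection) is rejected, so threading is conserved exactly; the
excluded volume alone already makes crossings energetically
prohibitive.

Equilibration and decorrelation: each run starts with an unrecorded
pre-equilibration phase (20 N sweeps — the regular-polygon initial
state is far from the equilibrium loop size for large N), then uses the
chord (unit bond vector) autocorrelation C(tau), computed by FFT over
all bonds and time origins: frames up to three times tau(0.1) (first
lag with C <= 0.1) are discarded — extended, if later, to the first
frame whose Rg reaches the stationary band (median of the last half of
the run) — and runs extend adaptively until the retained frames contain
a requested number of decorrelation times.  Standard errors of ensemble
means use block averaging with the block length set by each
observable's own integrated autocorrelation time (never below three
chord times): global observables such as Rg decorrelate more slowly
than the chords that define tau.

## Shape descriptors and scaling laws

Per frame: Rg (centroid-centred RMS distance), distension D =
(2 Rg / r0) sin(pi/N) (equal to 1 for the flat regular N-gon with
relaxed bonds), gyration-ellipsoid semi-axes a >= b >= c (square roots
of gyration-tensor eigenvalues — the principal radii of gyration, the
convention under which the disk/stick asphericity anchors 0.25/1 hold),
asphericity A and prolateness P from the semi-axes. P is undefined for
an exact sphere and clipped to [-1, 1] against round-off at the
degenerate limits.

Scaling fits (loops of >= 30 beads, where small-loop rigidity is
excluded; weighted by block-averaged SEs):

    <Rg> = c_r + a_r N^nu      nu free, or frozen at 0.59 when comparing
                               prefactors a_r across thread thicknesses
    <A>  = A_inf + a_A N^mu    all three parameters free, multi-start
    <P>  = P_inf + a_P N^-0.47 exponent frozen (a free exponent is not
                               identifiable on these ranges); linear fit

Expected unthreaded anchors: nu ~ 0.58 (close to the self-avoiding-walk
value), A_inf ~ 0.071, P_inf ~ 0.33; threading raises distension and
asphericity at small N and the Rg prefactor by ~6% independent of w.

## Protein bridge

Chains are read from PDB files as Calpha traces (nm); disulfides come
from SSBOND records, geometric SG-SG detection (<= 2.5 A), and explicit
user-specified pairs for non-disulfide bridges. Each bridge closes a
loop (residues between the bridged pair, bridge edge implicit) with the
chain termini as tails; one residue maps to one bead. Classification
reuses the minimal-surface method. The fitted probability surface gives
each tail p_i = 1 - P(N, t_i; L0) (clamped; zero-length tails cannot
thread), combined by inclusion-exclusion under independence across
tails and loops; an observed m-fold piercing is weighted by the
geometric multi-piercing factor (1 - P_inf)^(m-1). Loops observed
threaded despite model probability < 0.2 are candidate functional
lassos. Tests run on synthetic, programmatically constructed PDB
fixtures with known ground truth; the full curated protein corpus is
external data and out of scope.

## Problem sizes used in the shipped runs

The full-scale study behind the anchors used 1e6 lassos per (N, t) cell
and 1e9-step trajectories. The package's own runs use sizes chosen so
the whole pipeline reproduces the headline numbers on a single CPU in
minutes: ~1000 lassos per cell on an 11-length diagonal N = t from 10
to 500 (binomial SE ~0.015; the short cells pin the fast regime of the
decay fit), ~1000 lassos at N = t = 250 for the domination number, and
MC sweeps over N in {30, 40, 50, 70, 100, 150, 200, 300} with ~1500
decorrelated frames per condition. At these sizes the statistical error
dominates the comparison: the fitted trivial-lasso asymptote scatters
by several hundredths across seeds (on top of the ~0.03 plateau offset
noted below), the asphericity asymptote by ~0.01, and the
threaded-vs-unthreaded prefactor ratio is resolved only as a
statistical consistency check (its full-fidelity version needs
hour-scale sweeps, available via `analysis/03_loop_simulations.py
--frames`).

## Known limitations

* The spanned surface is a relaxed triangulation, not an exact soap
  film; piercing counts (not parities) depend mildly on the
  construction, although the trivial/non-trivial split itself proved
  robust to every construction variant tried (fan vs ear-clip
  initialisation, refinement depth, relaxation tolerance, edge flips).
  The trivial-lasso probability at N = t = 500 comes out ~0.03 below
  the expected plateau; as a consequence the fitted diagonal asymptote
  tends to undershoot.
* The asymptotic asphericity and the decay-law asymptote are
  extrapolation-dominated at any feasible loop length (A(N) is still
  ~0.011 above its limit at N = 500): their fitted values inherit a
  prior-like sensitivity to the exponent bounds, which are therefore
  chosen by identifiability arguments and documented above.
* Phantom ensembles carry no excluded volume: sharp tail turns produce
  shallow boundary-adjacent piercings that are genuinely counted (raw
  convention); with chain thickness these would fade.
* The MC thread is immobile and straight; a fluctuating thread would
  soften the confinement slightly.
* Protein loops are classified on Calpha traces; side-chain geometry
  beyond the SG-SG bridge test is ignored.
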