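# Methods

`subwave` reproduces, end to end, a computational study of microwave-based
detection of subdural hematoma (SDH): a parameterized 2D electromagnetic
model of a human head inside an antenna helmet, a multiport S-parameter
solver, a nearest-subspace classifier over the raw complex channels, and the
evaluation protocol (grouped fivefold cross-validation, learning curves and
a binary validation set with unseen parameter values).  This note records
the model, its assumptions, the defaults and the choices made where the
design was genuinely open.

## Electromagnetic model

**Geometry.**  The head cross-section is an ellipse of full axes
18.2 x 14.8 cm (the dimensions of the cranium the instrument was validated
on), containing, inward: a cortical-bone skull shell (default 7 mm), a CSF
layer whose thickness is a scenario parameter (2-5 mm), the brain (gray
matter), and a small interior CSF ellipse (default 3 x 1.5 cm) coarsely
mimicking the ventricular system.  A crescent-shaped subdural bleeding can
be attached to the inner skull surface at one of ten angular stations 36
degrees apart, with station 1 on the +x axis so that the direct path between
the two antennas at y = 0 crosses a position-1 lesion.  The crescent is the
set of points within a depth profile d(theta) = t cos^2(pi (theta -
theta_c) / (2 Delta)) of the inner-skull ellipse; its angular half-width
Delta(t) = 18 deg + 6 deg/cm (t - 0.5 cm) is calibrated so adjacent
stations start overlapping exactly above t = 0.5 cm, matching the stated
design.  Eight parallel-plate waveguide ports (aperture 25 mm, stub 30 mm,
filling eps_r = 20, metal side walls) sit on a fixed ring of radius 105 mm;
water bags (25 C Debye water) bridge each aperture to the skull as
trapezoidal patches.  Scenario randomization follows the study design: head
scale in {0.94 ... 1.06} (2 % steps), helmet rotation uniform in +-6 deg
applied to the head while the port ring stays fixed, CSF thickness uniform
in 2-5 mm, bleeding thickness in {0, 0.2, 0.5, 1, 2, 2.5} cm, position
1-10, side left/right.  A left-side scenario is *defined* as the mirror
image (about the y axis) of the right-side scenario with the rotation
negated; its S-matrix is obtained from the right-side solve by the port
reflection permutation P, S_left = P S_right P^T, which is exact for the
symmetric port ring and verified against direct left-side solves.

Skull thickness, port/water-bag dimensions and the interior CSF ellipse are
not constrained by the study description; the defaults above are anatomically
and instrumentally plausible and are all exposed in `HeadModelConfig`.
Head scaling is applied to the outer ellipse only — the skull shell and CSF
layer keep their absolute thicknesses, treating them as anatomically
independent of head size.

**Dielectrics.**  All materials are evaluated analytically on demand
(no interpolation tables) with the convention eps = eps' - j eps'' and time
dependence e^{+j omega t}.  Water uses a single-pole Debye model with
standard 25 C parameters (eps_s = 78.36, eps_inf = 5.2, tau = 8.27 ps).
Blood, gray matter, cortical bone ("skull") and CSF use the published
4-term Cole-Cole parametric database.  The study matched its blood and
gray-matter simulation values to its own phantom-solution measurements,
which are not tabulated; the published tissue parameters are the only
reproducible anchor, and a JSON config hook substitutes user spectra when
measured values are available.  The port filling is lossless eps_r = 20;
the metallic port walls are modeled as a good conductor (sigma = 10^7 S/m),
which in the chosen polarization behaves as a PEC wall without requiring
the mesh to resolve the skin depth.

**Polarization and ports.**  The solver works with the out-of-plane
magnetic field H_z (TM polarization):

    div((1/eps_r) grad H) + k0^2 H = 0.

This choice is deliberate: in the H_z formulation a PEC surface is the
natural (Neumann) condition, so a parallel-plate waveguide carries a
cutoff-free TEM fundamental mode with beta = k0 sqrt(eps_r) — exactly the
broadband behavior the instrument's 0.1-3 GHz excitation requires.  The
alternative E_z formulation would give the 25 mm, eps_r = 20 stub a ~1.34
GHz fundamental-mode cutoff and could not reproduce a broadband port.  Each
port plane carries a first-order modal Robin condition
dH/dn + j beta H = 2 j beta H_inc that absorbs the outgoing TEM wave and
injects a unit incident wave on the excited port; S_ij is the TEM overlap
(mean of H over the plane) minus the incident wave.  Because all ports are
identical the power-wave normalizations cancel, and the discrete S matrix
is exactly symmetric (S_ij and S_ji are the same bilinear form of the
factorized system), so reciprocity holds to factorization round-off
(< 1e-10 relative in practice; the sweep verifies <= 1e-6 and then
symmetrizes).

**Discretization.**  Linear (P1) triangles on an unstructured Delaunay mesh
of an interface-conforming point cloud: points sampled along every material
boundary at the local target spacing plus graded hexagonal background
lattices.  The target size is lambda(material)/EPW at the highest solved
frequency (EPW = elements_per_wavelength, default 8; floor 0.8 mm, cap 6 mm;
air and the metal walls use a pseudo-permittivity of 9 so refinement scales
cleanly).  The domain is the full disk bounded by the truncation circle of
radius 135 mm, on which port planes alternate with a first-order absorbing
condition (with curvature correction, gamma = j k0 + 1/(2R)); the metal
wall ends are natural.  One sparse LU factorization per frequency serves
all eight excitations.  Verification: against the closed-form TEM
dispersion relation a straight guide reproduces |S21| = 1 within 1 % and
the phase within 2 deg (P1 dispersion error ~ (beta h)^2, so the phase
check uses h = 0.7 mm); a PEC-terminated guide reflects fully; lossy
scenarios are strictly passive; and successive refinements (EPW
8/12/16/24) show clean O(h^2) decay of channel-magnitude differences.  A
caveat the verification makes explicit: the *constant* in front of h^2 is
large.  The 2-5 mm CSF layer (eps' ~ 68) acts as a resonant matching layer
and through-head paths span ~15 wavelengths at 2.5 GHz, so individual
channel magnitudes at EPW 8 can still differ noticeably from EPW 16;
channel-level mesh-independence at the few-per-cent level would require
EPW ~ 40+ (hundreds of thousands of nodes), beyond a sensible operating
point for a study of this size.  The classifier does not rely on
channel-level convergence — all classes share the same discretization, and
the discretization perturbation is an order of magnitude below the
smallest lesion signature (measured below).

**Frequency grids.**  The instrument grid is 0.1-3.0 GHz at 7.25 MHz steps
(401 points).  The default simulation grid is 16 points over 0.5-2.5 GHz;
the packaged end-to-end study uses 8 points over 0.7-1.7 GHz, a band where
through-head transmission is well above the discretization floor, which
keeps the full 1500-scenario study within minutes on one CPU (see problem
sizes below).

## Features and classifier

Per observation, the unique channels (i, j), j >= i, of the 8x8 S matrices
(36 of 64; j < i are redundant by reciprocity) are concatenated over
frequencies into one complex vector in a fixed canonical order — all
frequencies of (1,1), then (1,2), ... then (2,2), ... No scaling,
detrending or other preprocessing is applied; additive complex white
Gaussian noise is available as an explicit option (default off, keeping the
pipeline deterministic).  For the instrument layout (10 antennas, 401
frequencies) the same layout yields 55 channels and 22,055 elements.

Each class c is modeled as x = U_c alpha + e: observations lie near a
low-dimensional complex subspace spanned by the leading left singular
vectors of the class data matrix (observations as columns).  Classification
minimizes the projection residual d_c = ||x - U_c U_c^H x||; ties break to
the lowest class index.  The subspace dimension m_c is the one genuinely
open design choice.  The default is the **full class span**, m_c = n - 1:
in helmet data the within-class variability (head size, rotation, CSF)
exceeds the between-class lesion signature by orders of magnitude
(||dS|| ~ 1.9 for +-6 % head size against ~0.04-0.08 for a lesion), and an
energy-truncated basis absorbs only the shared variability, leaving every
class with the same residual — measured accuracy collapses to chance with a
99 %-energy rule (the class mean alone carries ~95 % of the energy).  With
the full span, d_c measures the distance to everything the class training
set exhibited, and the class-specific lesion structure separates the
classes.  Energy-threshold and fixed-m rules remain available
(`fit(energy=...)`, `fit(m=...)`), and mean-centering/normalization are
options that default off.

## Evaluation protocol

Grouped, class-stratified fivefold cross-validation: replicate groups
(measurements without helmet repositioning; singletons for simulated data)
are dealt whole, shuffled within class, to the currently smallest fold, so
folds balance to group granularity and every training split contains every
class.  Metrics: total accuracy, per-class accuracy (diagonal over row
sum), and for bleeding detection all bleeding classes merge into one
positive class, giving TPR (sensitivity) and TNR (specificity); counts and
percentages are both reported, rounding only at presentation.  Learning
curves draw class-balanced random subsets (whole groups) of growing size
and repeat the full CV per subset (default 5 seeded repeats, mean +- sd).
The binary validation protocol fits all six subspaces on the full training
data and classifies an unseen dataset — generated with off-grid parameter
values (thicknesses 0.35/0.75/1.5/2.25 cm, head scales 0.95 ... 1.05)
spanning the training ranges, 250 no-bleeding and 1250 bleeding
observations by default — as bleeding unless the no-bleeding subspace is
closest.  The Whittaker-Eilers smoother (penalty lam on the d-th
difference, solved by one sparse banded system; defaults d = 2, lam = 10)
is included for presenting raw magnitude traces.

## Problem sizes and numerical choices

The packaged study (tests and the acceptance script) runs the full design —
250 observations per class, 1500 scenarios, plus a 600-observation
validation set (100 no-bleeding + 4 x 125 bleeding, preserving the 1:5
class ratio) — on an 8-point 0.7-1.7 GHz grid with EPW = 6 (about 3000
nodes per mesh, ~0.25 s per scenario on one CPU).  This band-and-resolution
choice is the package's scaled operating point: per-scenario solves are
coarse but deterministic and identical across classes, and the
discretization perturbation (measured by re-solving an unchanged scenario
on a jittered mesh, ||dS|| ~ 0.002) is an order of magnitude below the
smallest lesion signature (~0.04), so class structure survives.  The exact
percentages of the original study are not expected to transfer: its FEM
internals (element order, port details, grids) are unpublished, its
feature space is ~40x larger (10 antennas, 401 frequencies), and accuracy
at this task is sensitive to both.  What does transfer, and what the test
suite asserts, is the behavioral pattern: thick bleedings separate from
no-bleeding without error, misclassifications concentrate in adjacent
thickness classes, the distance to the no-bleeding subspace grows
monotonically with bleeding size (also on the unseen validation set), and
accuracy grows with training-set size.

Degenerate inputs and tie-breaks: tied distances go to the lowest class
index (measure-zero but pinned for determinism); all-zero class data raises
a rank error; meshes with non-positive triangle areas are rejected;
reciprocity violations beyond 1e-6 and passivity excess beyond 2 % abort a
sweep rather than silently contaminating a dataset.

## Known limitations

2D physics with an idealized antenna model — no cross-talk structure, no
3D skull anatomy, no measurement noise spectrum (the noise option injects
white noise only).  The phantom recipes of the original instrument work are
documentation, not simulation inputs; measured Touchstone data can be
imported but no measured dataset ships with the package.  Blood/gray-matter
dielectrics use published database values rather than the (untabulated)
phantom-matched spectra.  The crescent parameterization (depth profile,
half-width growth) realizes the stated geometric constraints but is
otherwise a modeling choice.
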