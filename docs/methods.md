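# Methods

`lrtcmr` simulates a free-running (continuously acquired, non-ECG-gated,
free-breathing) whole-heart cardiac MRI exam on a digital phantom,
reconstructs it with a six-dimensional low-rank tensor (LRT) model, and
quantifies myocardial injury — left-ventricular ejection fraction (LVEF),
infarct (MI) size and transmurality, microvascular obstruction (MVO) at an
early and a late gadolinium window, and intramyocardial hemorrhage (IMH) —
against exact ground truth. A second, idealized gated "conventional" arm
is quantified with the same measurements, and the two arms are compared
with Bland–Altman, regression, paired-t and sector-level ROC statistics.

## Acquisition model

The pulse sequence is an inversion-recovery-prepared multi-echo spoiled
gradient echo run continuously: inversions every
`segments_per_ir * TR = 192 * 13.2 = 2534.4 ms`, 5° excitations, six
echoes (1.47–11.42 ms), 14 min 20 s total, and a randomized
Gaussian-density Cartesian (ky, kz) pattern (σ = N/6, truncated at the
index bounds, redrawn independently per readout). Every sixth readout is
a training line at the k-space centre. Two printed protocol values for
the block period conflict (2520 ms vs the product 2534.4 ms); the package
uses the product, with an optional per-block dead time to realize other
periods. Event times are integer 0.1 ms ticks, so timing identities are
exact.

Because `192 % 6 == 0`, training lines only ever visit segments
0, 6, …, 186: the native 192-point inversion-time axis is never fully
covered by training data. The reconstruction therefore groups the
inversion-time axis by a decimation factor aligned with the training grid
(6 at the module level → 32 bins; 12 in the desk-scale study → 16 bins).

## Signal model

Under perfect spoiling the longitudinal magnetization before excitation
`n` of a block obeys `L_{n+1} = M0(1−E1) + a L_n` with `E1 = exp(−TR/T1)`
and `a = E1 cos α`; the block-to-block map (relax → invert with
efficiency η → relax TI₀ → readout train) is affine, and its fixed point
gives the cyclic steady state in closed form. The closed form matches a
brute-force event-by-event Bloch recursion to below 1e−9 and is the basis
of both the simulator and the T1-fit forward model. Echoes decay
mono-exponentially with T2*. Gadolinium concentration follows
`C(t) = A(1−e^{−(t−t₀)/τin}) e^{−(t−t₀)/τout}` per tissue, with
`1/T1 = 1/T1₀ + r₁C`; concentration is frozen at each block start (blocks
are 2.5 s, enhancement varies over tens of seconds).

## Phantom

An analytic annulus stack: cylindrical blood pool (end-diastolic
endocardial radius 22 mm) inside a myocardial shell (epicardial 34 mm),
an infarct wedge (default 90° × transmural fraction 0.72), an MVO core
and an IMH band nested inside it in material coordinates (angle ×
normalized transmural depth), and a static liver slab. Default injury
sizes reproduce an acute reperfused-infarction cohort scale
(MI ≈ 17 %LV, MVO ≈ 5 %LV, IMH ≈ 5–6 %LV); the cohort generator jitters
extent, depth, rates and placement per subject, with about a quarter of
subjects free of MVO and, of those with MVO, a fifth free of IMH.

Contraction scales the endocardial radius by a raised-cosine systolic
window occupying 35% of the cycle; the epicardial radius preserves shell
area exactly (incompressibility). Respiration is a rigid 8 mm translation
along a mostly superior–inferior direction with a deliberate in-plane
component (unit vector ≈ (0.40, 0, 0.92)): a purely through-plane shift
of a near-cylindrical ventricle would be invisible to a k-space-centre
navigator. Tissue values are literature-typical at 3 T (remote myocardium
T1 1200 ms / T2* 30 ms, blood 1800 / 25, IMH T2* 10 ms, infarct T2*
elevated to 38 ms for edema, r₁ = 4.5 /mM/s). Blood retains gadolinium
longer than myocardium (T1 ≈ 360 vs ≈ 780 ms at the late window), as in
vivo — without this no T1-weighted frame shows cavity contrast. The MVO
core barely enhances even late; an internal "rim" subclass fills in
between the early and late windows so persistent MVO is smaller than
early MVO. Hemorrhagic tissue enhances promptly (it is necrotic tissue
with iron, detected via T2*, not via hypo-enhancement).

Ground-truth metrics are voxel counts on rendered label volumes over the
24-phase cine grid (end-diastole/end-systole = max/min cavity), so truth
and measurement share one discretization; closed-form annulus-wedge
integrals agree with the counts to within discretization.

## Simulation

Each scheduled readout sees the phantom at its cardiac/respiratory state
and contrast time. The phantom is piecewise-constant over tissue classes,
so a k-space line is a tissue-signal-weighted sum of cached DFTs of
per-tissue, per-motion-state coil-weighted masks; motion is rendered on a
48 cardiac × 8 respiratory state grid (finer than the analysis bins, so
within-bin averaging behaves like smooth motion). Complex Gaussian noise
is added per sample; "SNR 30" means the remote-myocardium late-window
signal amplitude over the per-sample noise SD (orthonormal DFTs keep the
SD identical in k-space and image domain). The conventional comparator is
rendered directly in image space: balanced-SSFP cine contrast
(`s = PD sin α / (1 + cos α + (1 − cos α) T1/T2)`, using spin-echo T2 for
blood/myocardium), pre-contrast 8-echo GRE for T2*, and gated
inversion-recovery snapshots at 120 s and 900 s.

## Self-navigation

The echo-averaged complex training lines are detrended per segment
position (removing the inversion-recovery modulation and the gadolinium
drift; the drift window is short enough to follow the bolus) and reduced
by PCA. The cardiac component is identified by spectral peakedness in
0.8–3.5 Hz; its precise fundamental comes from a zero-padded FFT with a
second-harmonic guard, refined by the slope of the residual envelope
phase; the cardiac phase is the demodulated envelope phase plus the
carrier (64 s envelope window). Per-beat trigger detection was evaluated
and rejected: with only ~2.7 training samples per systole it misses beats
at realistic SNR, whereas demodulation tracks a regular rhythm to a
median phase error of ~0.01 cycles. Respiration is a projection
navigator: each training line's x-projection (windowed to the central
half of the field of view, so static structures cannot pin the estimate)
is phase-correlated against a per-segment reference, giving sub-voxel
shifts. Both estimates degrade for irregular rhythms — a stated
limitation of demodulation-based gating.

## Binning and reconstruction

Readouts are binned into 24 cardiac phases, 4 respiratory amplitude
groups (distinct amplitude levels are never split across bins), Gd bins
uniform in √time (concentrating bins early where enhancement changes
fastest), and decimated inversion-time bins. The image set is modelled as
`x(r; cell) = Σ_l U_x[r,l] · Φ[l, cell]`. The temporal basis Φ is
estimated from the training lines: cell-averaged into a (profile ×
cardiac × resp × τ × echo × Gd) tensor, reduced along the profile axis,
completed by EM-style Tucker completion at ranks (8, 3, 5, 3, 4)
(alternating HOSVD truncation and re-imputation), and factored; Φ is
taken from the Tucker-projected tensor — the per-axis factors pool weak
dynamics (cardiac motion above all) across every other axis, which keeps
them from being shrunk away as in a raw SVD of the noisy tensor. The
spatial factor (rank 32) solves the subspace-constrained least-squares
data-consistency problem with relative Tikhonov regularization by
preconditioned conjugate gradient: with full kx sampling the normal
operator reduces to per-(ky, kz) L×L Gram matrices between batched FFTs,
and the per-location Gram inverse is an (exact, for a uniform coil)
preconditioner that brings convergence to a handful of iterations.
λ is expressed relative to the mean Gram eigenvalue; the study default
λ = 0.15 controls the noise that consistent convergence would otherwise
amplify from residually mis-binned events.

## Analysis frames and measurements

The method's retrospective inversion-time selection is used deliberately:
cine frames at the late-Gd window averaged over the last three τ bins
(near the driven steady state); the late-enhancement frame at the τ bin
minimizing the myocardial median (remote-nulled); MVO frames at a fixed
long inversion time (520 ms) at both the early (~120 s) and late windows,
where unenhanced tissue nulls — at this sequence's 2.5 s inversion period
the unenhanced core is *not* near-nulled at the remote-nulling time, so
the classic "below remote mean on LGE" rule cannot fire there. Frames
for enhancement analysis are averaged over the diastolic cardiac bins
(one quiescent motion state spanning most of the cycle), the counterpart
of a diastolic-gated acquisition.

Cavity volumes use a radial edge detector: per slice and angle, the
endocardial radius is the first sustained crossing of the
blood/myocardium midpoint intensity, and the per-slice radius is the
median over angles — robust to a bright transmural scar crossing some
rays and to low-level temporal leakage. Frame selection is guarded by a
circular 3-frame median (a rater would reject a single failed contour);
the chosen frame's own volume is used unless it is itself the outlier.
Volume ratios (hence LVEF) are accurate; absolute volumes carry a
blur-dependent positive bias.

Infarct sizing thresholds the (lightly smoothed) late-enhancement frame
at remote mean + n·SD (n = 5), floored by the Otsu valley of the
myocardial histogram — on denoised reconstructions the SD term collapses
into the blur skirt, while the histogram valley adapts to the actual blur
without a regime switch. The endocardial rim (bright-blood partial
volume) is excluded from the statistics and candidates and re-admitted
where bright; components at least a quarter of the largest are kept (a
dark core can split the territory in two); holes enclosed against the
cavity are filled; the detected no-reflow core is unioned in (infarct
size includes MVO, the clinical convention). MVO is the hypointense core
in the infarct's immediate neighbourhood below the midpoint of remote
mean and core floor, hole-filled. IMH is T2* < 20 ms (3 T convention)
inside the infarct, with a remote-minus-2SD alternative. Transmurality
averages the infarct's radial extent over chords substantively crossing
the territory.

T1 maps fit `|A − B e^{−τ/T1*}|` by variable projection over a T1* grid
with polarity restoration and shrinking-window refinement, then invert
the FLASH relation `1/T1 = 1/T1* + ln(cos α)/TR` — exact for a known
readout, unlike the classical Look-Locker correction `T1 = T1*(B/A−1)`,
which under this sequence's incomplete inter-block recovery errs by tens
of percent for native T1 (it is retained as an option, and a
Bloch-dictionary nearest-neighbour estimator serves as a cross-check).
T2* maps use signal-weighted log-linear fits with a Gauss–Newton polish;
at SNR 30 the estimator operates essentially at the Cramér–Rao bound
(whose SD exceeds 5% for any mono-exponential protocol here — the
relevant accuracy statement is the ≤5% median absolute error, which
holds).

## Study scale and runtimes

The default study runs 12 subjects on a 96×96×6 grid (2.8 mm in-plane,
the protocol's 270 mm field of view and 6 mm partitions), 2 coils, the
full 860 s schedule, bins 24×4×8 with τ decimation 12, at SNR 30; the
full-resolution 192×192×14 geometry is a parameter change. A subject
takes ~35 s end to end; the cohort about 7 minutes. The exact-rank
recovery experiment (64×64×4, ranks (8,3,5,3,4), noise-free, default
schedule, spatially smooth random model) reaches NRMSE ≈ 7e−4 in ~2
minutes.

## What the phantom does and does not establish

Passing tests show that the schedule, signal physics, self-navigation,
subspace estimation, solver and quantification chain are internally
consistent and recover known truth under piecewise-constant tissue,
rigid respiration, a regular rhythm and discretized motion. They do not
establish performance under irregular rhythm, nonrigid respiration,
through-plane motion, B0/B1 nonuniformity, flow, or anatomically
realistic texture.

Measured on the default cohort, early-MVO and IMH volumes recover truth
within the in-vivo-like limits for nearly all subjects (MVO within ±2 %LV
for 12/12, IMH within ±1 %LV for 10/12), and the two arms agree tightly
for those metrics (MVO RPC ≈ 1.3 %LV, IMH RPC ≈ 1.6 %LV, detection AUC
0.87–0.98). LVEF and infarct size are noisier at this desk-scale
resolution: residual navigation jitter leaks diastolic signal into
systolic frames (LVEF errors of several points on some subjects), and
threshold-based sizing of a wedge only a few voxels thick is
blur-regime-dependent (infarct size biased high by ~5 %LV). At the
protocol's native 1.4 mm resolution the structures are twice as many
voxels across, which is where the in-vivo tolerances were established;
the desk-scale shortfall is analyzed rather than hidden, and the
corresponding acceptance checks are left failing by design.
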