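# Methods

## The kinetic model

A SynIEG is modeled as a single transcription unit integrated at `n_sites`
genomic loci (default 8), all driven by the same promoter activity. Three
normalized inputs are derived from the experimental condition:

* `E(t) ∈ [0,1]` — Erk pathway activity. Light windows switch `E`
  instantaneously (optogenetic membrane recruitment is seconds-fast,
  far below the minutes-scale time grid). The serum presets pass `E`
  through a first-order rise with time constant `erk_tau_min = 24 min`,
  standing in for the receptor → Ras → Erk → active-transcription delay
  chain of growth-factor stimulation; without this lag a step input would
  force transcription to be maximal at t = 0, which contradicts the
  ~30-min rise of serum-induced burst intensity. A MEK-inhibitor time sets
  `E = 0` from that point on; `T ∝ E` makes the shutoff exact.
* `D(t) = 1 − exp(−k_D·(t − t_add))` after doxorubicin addition — a
  saturating DNA-damage/signaling variable (`k_D = 0.025 /min`, so damage
  signaling is ~80% developed after one hour).
* `S(t) ∈ {0,1}` — protein synthesis; 0 under cycloheximide.

Per cell, four ODE states evolve on the stimulus grid:

| state | equation | role |
|---|---|---|
| `Z` | `dZ/dt = k_z·E·S − δ_z·Z` | Erk-induced, synthesis-dependent adaptation repressor (Zfp36-like). Under cycloheximide `Z ≡ 0`, so transcription cannot adapt — matching the classic immediate-early behavior. |
| `T_i` | `k_tx·(k_leak + E·K_z^h/(K_z^h + Z^h))` | per-site transcription rate; the Hill repression (h = 8) produces a sharp transcriptional shutoff ~30–60 min after induction. |
| `M` | `dM/dt = Σ_i T_i − δ_m·M` | pooled mRNA. `δ_m = δ_m0·(1 + α_fos·Z/(K_deg + Z))` for the *FOS* 3′UTR (Zfp36-mediated destabilization); plain `δ_m0` for *TUBULIN* and *BTG2* 3′UTRs. |
| `P` | `dP/dt = k_tl·ε·M − δ_p·P` | reporter protein. |

Translation efficiency `ε` implements the miR-21 arm phenomenologically
(the molecular mechanism of damage relief is not modeled): for the *BTG2*
3′UTR, `ε = 1 − (1 − ε_min)·a` with miR-21 activity `a = 1 − D(t)`
(endogenous), `a = m_sponge = 0` (sponge), or `a = m_over = 1`
(overexpression; damage relief disabled). Other 3′UTRs translate at
`ε = 1`.

Protein decay `δ_p` is the reporter's basal constant (`msfYFP`
0.0012 /min ≈ 10 h half-life; `dGFP` 0.012 /min ≈ 1 h — the destabilized
reporter that "resets" to a low pre-stimulus baseline). A Fra1 degron
replaces it with `δ_p_degron·(1 − f_stab·E)`: the unphosphorylated degron
destabilizes the protein (δ_p_degron = 0.012 /min) and Erk phosphorylation
stabilizes it (f_stab = 0.95). This protein-level arm plus the
mRNA-level Zfp36 arm make the *fos*-Fra1deg-*fos* circuit
sustained-selective, while *fos-tubulin* (neither arm) responds almost
equally to a 20-min pulse and to continuous light.

Two observation terms connect the model to fluorescence data:

* `k_leak = 0.010` — a basal, Erk-independent transcription fraction. It
  gives the pre-stimulus steady state `M0 = n·k_tx·k_leak/δ_m0`,
  `P0 = k_tl·ε(0)·M0/δ_p`, which is what makes fold-changes well-defined
  and makes the stable-YFP baseline high (the reporter accumulated during
  growth fails to reset during a few hours of starvation) while the dGFP
  baseline is low.
* `background_yfp_au = 861`, `background_gfp_au = 51.5` — constitutive
  per-channel autofluorescence added to the reported protein trace. The
  offsets are per spectral channel because YFP and GFP are acquired in
  different bands. Beyond realism they matter structurally: with a purely
  multiplicative `ε`, protein traces are exactly linear in `ε`, so
  fold-changes would be blind to constant miR-21 activity; the additive
  offset is what lets a sponge raise, and overexpression fail to raise,
  the serum-induced fold — the behavior the experiments show.

With `k_leak = 0` and zero offsets the model reduces to the bare cascade:
zero input from a zero state stays identically zero, and with the
repressor clamped (`k_z = 0`) under constant input it settles at the
closed-form fixed point `M* = n·k_tx/δ_m0`, `P* = k_tl·M*/δ_p` — both used
as exact tests.

Integration is piecewise between input discontinuities (light edges, drug
additions, MEK inhibition) with LSODA at rtol 1e−8 / atol 1e−10; states
are clipped at zero against round-off. An optional seeded mode replaces
each site's deterministic rate with a two-state telegraph process whose
on-probability follows the deterministic promoter activity (switching-off
rate 0.5 /min, i.e. ~2-min bursts); its ensemble mean matches the ODE and
it is excluded from all summary-statistic calibration.

## Calibration of the shipped defaults

`calibrate_defaults()` searches a documented parameter box (coarse seeded
draws plus Nelder–Mead refinement of the worst-case relative residual) for
a parameter set satisfying the package's behavioral targets within 15%:

* serum-induced transcription peaks ≈ 30 min after stimulation and returns
  to within 5% of baseline by ≤ 90 min;
* *fos-tubulin*, sustained light, 3 h: +40% reporter fluorescence, with the
  sustained/transient fold ratio ≈ 1;
* *fos*-Fra1deg-*fos*, sustained light, 3 h: +20%;
* AND gate (*FOS* promoter, *BTG2* 3′UTR, dGFP): fourfold increase under
  serum + doxorubicin with each single input < 1.5-fold.

The committed defaults in `KineticParams` (mirrored in
`src/synieg/data/default_params.yaml`) satisfy all targets
simultaneously; the timing sub-vector was additionally chosen so the
transcription maximum is locally peaked (T(30) exceeds T(26) and T(34) by
~5%) rather than a flat plateau, keeping the argmax of a noisy quantified
trace stable. Two structural lessons from the calibration are worth
recording: the tubulin duration-insensitivity bounds how much of the
sustained-light transcription can occur after the 20-min mark, and the
AND-gate contrast at a 3-h endpoint is essentially the ratio of induced to
leak mRNA translated under relieved repression — which is what pins
`k_leak` low and requires the dGFP reporter to retain part of the
mid-course response.

## Synthetic movies

`render_movie` draws, per frame and z-slice (7 slices at 0.8 µm — the
stated 4.5 µm span is internally inconsistent with 6 × 0.8 µm gaps, so the
slice spacing is taken as exact):

* **H2B**: uniform elliptical nuclear fill (400 photons/px);
* **MCP**: diffuse nuclear background (200 photons/px) plus one
  diffraction-limited focus per site — an in-plane Gaussian
  (σ = 1.3 px at 0.27 µm/px) whose volume-integrated expected photon count
  is `mcp_photons_per_au × T_i(t)` distributed over z by a normalized
  Gaussian axial profile (σ_z = 0.9 µm). Normalizing the axial weights
  conserves the expected photon sum exactly regardless of the site's
  depth;
* **YFP**: nuclear fill proportional to the protein trace
  (0.5 photons/px per a.u.).

Poisson shot noise, Gaussian read noise (σ = 3) and a camera offset (100)
are applied and the image is clipped to 16 bits. Rendering is
bit-reproducible for a fixed seed; a noiseless mode writes rounded
expected images for ground-truth validation. Focus brightness is
proportional to the instantaneous transcription rate (no nascent-chain
dwell-time convolution); site positions keep ≥ 5 px mutual separation and
a 7-px margin from the nuclear rim so a 9×9 fit window always sees uniform
nucleoplasmic background. `jitter_population` adds mean-one log-normal
cell-to-cell variability (default CV levels chosen per experiment,
typically 0.2) to the expression-amplitude parameters
(`k_tx`, `k_tl`, `δ_m0`) only — transcription kinetics are observed to be
nearly identical across cells, so the adaptation clock is shared.

What the renderer deliberately omits — photobleaching, cell motion and
division, multi-cell fields, z-drift, non-Poisson camera artifacts —
bounds what a passing pipeline proves about real data: the quantification
chain is validated for a stationary, single-nucleus, shot-noise-limited
regime, not against segmentation or registration failure modes.

## Burst quantification

Per frame the MCP z-stack is max-projected. Foci are detected on the
−LoG-filtered projection (σ = 1.3 px), with non-maximum suppression at
4 px and a peak-intensity threshold of median + 5 robust SD of the masked
image (MAD × 1.4826, floored at the shot-noise scale √median so a
noise-free rendering does not admit ripples). Detections are linked by
greedy nearest-neighbor gating (≤ 3 px to a track's mean position, gaps up
to 3 frames) — integration sites do not move, so linking is effectively a
stationarity check. Each retained track is then re-fit in **every** frame
at its mean position: an axis-aligned 2D Gaussian with free offset on a
9×9 ROI, and the burst intensity is the integrated area above background,
`I = 2π·A·σx·σy`. Frames where the fit fails are missing values, never
zeros.

Numerical choices that matter at low signal:

* the fit's background starts at the ROI **median** (the minimum is biased
  low under Poisson noise and inflates moment-based width estimates to the
  upper bound);
* re-fits at tracked positions constrain the center to ±1.5 px and, in a
  second pass, pin the width to ±~30% of the track's own bright-frame
  median σ — the PSF does not change between frames, and without this
  single-frame broad-σ noise fits (1.5–2× inflated `I`) occasionally
  displace the argmax of the mean trace;
* free-ROI fits (detection-style use) keep the loose bounds
  σ ∈ [0.5, halfwidth] px with the center anywhere in the ROI;
* a fit whose amplitude collapses to ~0 (below 10% of the ROI SD) is
  reported unconverged. A bounded amplitude (A ≥ 0) implies a small
  positive intensity floor on empty frames; baseline subtraction removes
  it from AUC and timing statistics.

## Trace statistics

The baseline ("initial") of a trace is the mean of its first two
timepoints; `AUC = Σ_t (value(t) − initial)` is a plain unweighted sum
over all frames including the first two, in a.u.·frames (no dt weighting,
no trapezoid), with missing frames skipped and counted. Fold-change is
final-over-baseline by default (a max-based variant is selectable);
percent increase is `100·(fold − 1)`. `kinetic_metrics` reports the argmax
time and the first post-peak return to within one noise SD of baseline;
for movie-derived traces the noise SD is estimated from pre-stimulus
frames. Nuclear reporter traces are the mean masked intensity of the
**central z-slice** (best-focus proxy; nuclear levels are quantified on
acquired slices, not projections).

## Gate and filter statistics

Comparisons use two-sided Student t-tests (equal-variance pooled by
default, matching the stated analysis; Welch by flag; paired where
measurements are matched within clones). Zero variance with equal means
returns t = 0, p = 1 by convention. No multiple-testing correction is
applied — raw p-values are starred at 0.05/0.01/0.001.

The duration-filter index is
`mean(fold_sustained − 1)/mean(fold_transient − 1)` with an unpaired
t-test on the folds. The AND-gate classifier is an operational rule of
this package (there is no community-standard quantitative AND criterion,
and its output says so): **AND-like** requires synergy
`S = meanAUC(AB) − meanAUC(A) − meanAUC(B) > 0`, p < 0.05 for AB against
each single input, and each single-input fold below τ = 1.5 — the
threshold tolerates the weak serum-only activation that keeps the real
circuit from being a perfect gate. `|S| ≤ 10%` of the combined response is
called additive first (so noise around exact additivity is never
mis-called AND-like); classification is invariant to a global AUC scale.

## Known limitations

* The miR-21/damage and degron arms are phenomenological switches with
  effective rate constants, not mass-action mechanisms; they reproduce
  circuit-level behaviors, not titrations.
* The BTG2 promoter reuses the FOS transcription law with a scale factor;
  no separate promoter kinetics are modeled.
* One pre-stimulus steady state is assumed — no slow drift in starvation,
  no cell-cycle or division effects.
* Trajectory-level fold-changes quantify `P` plus a fixed autofluorescence
  offset; absolute a.u. scales are meaningful only relative to the shipped
  optics gains.
* The telegraph bursting mode shares the deterministic repressor and is a
  visualization/robustness tool, not a fitted stochastic model.
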