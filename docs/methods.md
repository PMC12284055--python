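# Methods

This note documents the models behind `eitpsoc`, the parameter defaults and
why they were chosen, and what the simulation does and does not capture of
the physical device.

## Signal chain

### Cosine synthesis and quantization

Two unipolar current DACs generate the positive and negative half-waves of
a cosine; trans-impedance amplifiers (TIA) with a common feedback
resistance `R_fb` convert the currents to voltages whose difference is the
bipolar load voltage `VL = R_fb (I2 − I1)`. For a period of requested
amplitude `V` sampled 55 times, the register tables are

    D_i± = floor( (255 V / (31.875e-6 · R_fb)) · max(0, ±cos(2iπ/55)) ).

The floor (truncation) operator is used deliberately: the autoranging
table's printed register bounds (e.g. 127 at 1.275 V / 80 kΩ, where the
scale factor is exactly 127.5) are only consistent with truncation, and
truncation is also what a fixed-point register assignment does. The floor
is applied to the full product, so every emitted register is integral, and
a 1e-9 absolute guard is added before flooring because bench amplitudes are
decimal numbers whose binary representation can land a few ulp below an
exact integer scale factor (the guard is ~7 orders of magnitude below half
a register LSB, so it can never promote a genuinely fractional value).

`R_fb` autoranges over six voltage spans (20, 30, 40, 80, 120, 250 kΩ for
0.15–4.625 V) so the register ceiling stays in the upper part of the 8-bit
range; with a fixed 20 kΩ the ceiling below 0.16 V would be 63, i.e. only
five usable bits, which measurably raises harmonic distortion. Distortion
is quantified as the ratio of non-fundamental to fundamental RMS of one
period's discrete Fourier decomposition, DC excluded (the conventional THD
reading; the half-wave floor asymmetry leaves a sub-LSB DC offset that is
not a property of the AC waveform).

Saturation: when the scale factor exceeds the register maximum by more
than one LSB, registers are clipped at 255 and the emitted period carries a
`saturated` flag rather than raising — the hardware would do the same
silently.

### Amplitude control loop

The load current is regulated by a once-per-period multiplicative law
`a[k] = a[k−1]·Id/IL[k]` with `a[0] = 1 V`. The law cancels the (unknown)
load resistance, so the current amplitude equals `Id` from the second
period onward, up to quantization. Design choices where the device's
behavior is not documented:

- **Clipping**: an amplitude request outside the DDS span [0.15, 4.625) V
  is clamped to the nearest boundary and flagged; a setpoint whose required
  voltage lies outside the span for every period raises an
  unreachable-setpoint error instead of looping forever at the rail.
- **Current sensing**: the shunt voltage is read at the sample of maximum
  |cos|, i.e. the waveform peak (index 0), then divided by the 100 Ω shunt.
  The series divider includes the shunt: `IL = VL/(RL + 100 Ω)`.
- **ADC**: mid-rise uniform quantizer, 10 bits over a ±2.048 V
  differential range (the hardware documents the resolution but not the
  range; ±2.048 V gives the round 4 mV step of common SAR front ends).
- **TIA reference**: when not fixed by the user, `Vr` is chosen per period
  as `R_fb·I_fullscale + 0.1 V`, the smallest value satisfying the
  single-supply positivity constraints with margin.

With these defaults the simulated second-period current on a 1 kΩ load at
the 0.98 mA setpoint is 0.9864 mA; the residual 0.0064 mA is the ADC
mid-rise error on the 91 mV bootstrap-period shunt voltage propagated
through one control update, within the ±0.01 mA scatter the bench
characterization reports.

## Acquisition model

The adjacent protocol on `n` electrodes yields `n(n−3)` measurements
(8×5 = 40 here). The literal pin sequence printed in the device's protocol
description mixes connector pins with electrode positions; the package
implements the canonical adjacent pattern on geometric electrode indices
and exposes a `pin_permutation` in the layout so any physical harness can
be expressed as a relabeling. This preserves both the 8×5 frame shape and
the adjacency property.

Noisy captures are truth + i.i.d. Gaussian noise + a slow random-walk
drift accumulated across the 40 measurement slots of a frame. The walk
makes late-slot variance grow linearly with slot index, which is the
statistical signature of multiplexer settling drift at long switching
times; actual switching-transient circuit physics is out of scope. The
three named profiles (1 ms, 10 ms, 100 ms switching) set the additive sd
to put a 0.2 mV channel at ≈60/50/10 dB respectively (0.2 mV is the median
adjacent-protocol differential voltage at 0.98 mA in the 2D tank model);
drift steps are 0, 0.05 and 0.2 of the additive sd. The absolute levels
are a modeling choice — only the ordering across profiles is treated as
contractual in tests.

Frame files are whitespace-delimited 8×5 matrices in volts, `Frame<k>.txt`,
`Frame0.txt` the homogeneous reference; the reader tolerates blank lines
and scientific notation and accepts a flat 40-vector layout, preferring
the matrix.

## Forward model

2D Poisson conduction `∇·(σ∇u) = 0` on a disk, linear triangular elements,
point current sources at boundary electrode nodes. Point electrodes (not
the complete-electrode model) were chosen because no contact impedances
are documented for the reference experiments and the point model keeps the
solver minimal while preserving reciprocity; a gap/contact model can be
added at the layout level. The potential gauge is zero mean (the system is
grounded at one node for factorization, then shifted). The DC solution
stands in for the 50 kHz envelope: the phantoms are purely resistive, and
the demodulator reports magnitudes, so protocol voltages are reported as
`|u[q] − u[p]|`.

The mesh is a structured concentric-ring triangulation: ring `i` of `R` at
radius `r·i/R`, per-ring node counts proportional to circumference with
the outer ring a multiple of the electrode count so electrodes land
exactly on boundary nodes; annuli are stitched by an angular two-pointer
sweep. This is deterministic and avoids the degeneracy of Delaunay on
cocircular boundary points. Desk-scale default is ~1800–2500 elements
(boundary voltages change <1% on refinement past ~4000; the reference
25 511-element resolution is available by parameter but unnecessary for
the properties tested here). Against the closed-form homogeneous-disk
solution `u = I/(πσ)·(ln|x−x_sink| − ln|x−x_source|)` the FEM boundary
potentials agree to 0.7% relative L2 at 2500 elements (drive nodes and
their ring neighbors excluded, where the analytic solution is singular).

The sensitivity Jacobian uses the adjoint identity
`dV/dσ_e = −A_e ∇u_drive·∇w_meas` per element, where `w` is the
unit-current field of the measurement pair; on the 8-electrode adjacent
protocol all drive and measurement pairs share the same 8 unit-current
fields, so one factorization and 8 solves produce the full 40×n_elem
matrix. The background measurement's sign converts the signed derivative
to the magnitude convention. Verified against central finite differences
(every column <1e-7 relative on a 240-element mesh) and the Euler identity
`σ·Σ_e J[m,e] = −V_m` for homogeneous σ.

## Reconstruction

Time-difference imaging with the Jacobian evaluated at the homogeneous
background. The one-step operator is

    R = P (JᵀJ + λ² LᵀL)⁻¹ Jᵀ,

with `J` row-normalized by the reference frame, `L` the element-adjacency
graph Laplacian (identity available), `λ = 0.05` relative to the largest
singular value of the normalized `J` (no hyperparameter is documented for
the reference reconstructions; 0.05 is a conventional mid-range choice and
is exposed in the API), and `P` the element→pixel map: each triangle's
area is deposited at four interior sample points and each in-disk pixel
averages the elements sampled into it, area-weighted; pixels outside the
disk are identically zero. On the 32×32 grid over the 14 cm tank square,
797 of 1024 pixel centers fall inside the disk. Note the Laplacian prior
has constant vectors in its null space, so the λ→∞ limit vanishes only
under the identity prior.

The iterative variant minimizes
`‖JΔσ − Δv‖² + λ²‖LΔσ‖² + λ_tv·TV_β(Δσ)` by lagged-diffusivity
Gauss–Newton, where `TV_β = Σ_edges √((Δσ_i−Δσ_j)² + β²)` over
edge-adjacent element pairs and `β` defaults to 1e-4 of the one-step
image's dynamic range. Lagged diffusivity was preferred over primal-dual
methods for implementation economy; it is one standard reading of
"Gauss–Newton with total-variation regularization". The first iterate with
`λ_tv = 0` is exactly the one-step solution; a backtracking line search
keeps the objective non-increasing. Sign convention throughout: a
conductive inclusion reconstructs positive, an insulating one negative.

## Metrics

SNR uses the standard deviation in the denominator (`20·log10(|mean|/sd)`
per channel): paired with the 20 dB/decade factor this is the amplitude
ratio convention, and it is the only reading consistent with ~60 dB values
at sub-millivolt scatter on the measured signals; the raw-variance variant
is exposed for comparison. Channels with zero dispersion report a `+inf`
sentinel with a warning rather than raising. Accuracy in simulation is
measured against the noise-free forward-model voltages; for archived
hardware captures the long-run channel mean is the appropriate reference.

The GI index is reported per frame (pixel sum of each difference image)
and cumulatively over a frame sequence, with `|GI|⁻¹` for both.

## Known limitations

- **GI vs volume ordering.** Because the per-frame image is a fixed linear
  map of `Δv` and a larger conductive cavity strictly increases the
  difference signal on every channel, the pixel sum — hence |GI| — grows
  monotonically with cavity area in this model, and `|GI|⁻¹` therefore
  *decreases* with simulated fluid volume (e.g. medians ≈0.083/0.035/0.032
  for the 1.3/2.5/2.7 cm cavities at 1.227 S/m). The index still tracks
  volume strictly monotonically — the model's volume law is
  |GI| ∝ area — but the direction is the reverse of the reciprocal
  convention used in experimental reports, where between-phantom
  systematics (electrode contact, agar batch variation) enter the
  reference frame. The test suite asserts the model's own law as the
  contract and records the reciprocal ordering check separately.
- The 1.3 cm cavity is at the edge of what the 8-electrode one-step
  reconstruction resolves — consistent with the documented difficulty of
  small inclusions — though its GI remains well separated from the larger
  cavities.
- Op-amp nonidealities, slew rate, multiplexer charge injection, Bluetooth
  transport and all wall-clock timing (frame rate) are not modeled.
- The FEM is 2D and real-valued: out-of-plane current spreading in the
  30 cm-tall physical tank and reactive tissue behavior are absent, so
  absolute simulated voltages are smaller than bench readings; all
  difference-imaging quantities are normalized and unaffected.
- Frames are synthesized; the package can read externally captured
  `Frame<k>.txt` directories, but no measured data ships with it.
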