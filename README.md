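# eitpsoc

A desk-scale digital twin of an eight-channel electrical impedance
tomography (EIT) device built on a programmable system-on-chip. The package
is for instrumentation and biomedical-imaging researchers who want to study
the device's signal chain and imaging performance — quantization effects,
current-control convergence, SNR/accuracy statistics, and volume indices —
entirely in simulation, without the hardware.

EIT injects a small alternating current through pairs of surface electrodes
and measures the resulting boundary voltages; images of the internal
conductivity change are reconstructed from a homogeneous reference.

## What is simulated

**Signal chain.** The device synthesizes a cosine current with two 8-bit
current DACs updated 55 times per period (one DAC per half-wave), converted
to a bipolar voltage by trans-impedance amplifiers with an autoranged
feedback resistance R_fb. Sample *i* of a period of amplitude *V* is
quantized as

    S_i = cos(2 i π / 55),   D_i± = ⌊ 255 V / (31.875e-6 · R_fb) · max(0, ±S_i) ⌋

and the load-current amplitude is regulated once per period by the
load-independent control law `a[k] = a[k-1] · Id / IL[k]`, `a[0] = 1 V`,
which reaches the setpoint `Id` in the second period. A 100 Ω shunt and a
10-bit SAR ADC model the current sensing.

**Acquisition.** The adjacent protocol on an 8-electrode ring: drive each
consecutive pair, measure the 5 consecutive pairs not touching the drive —
an 8×5 frame of 40 RMS differential voltages, stored as `Frame<k>.txt` text
files with `Frame0.txt` the homogeneous reference.

**Imaging.** A 2D finite-element forward model of the 7 cm circular tank
(point electrodes, adjoint-method conductivity Jacobian), and
time-difference reconstruction from normalized differences
`Δv = (v_nh − v_h)/v_h`: either the one-step regularized Gauss–Newton
operator `R` (a 1024×40 matrix mapping Δv to a 32×32 pixel image,
`I_f = R Δv`) or iterative Gauss–Newton with total-variation
regularization.

**Metrics.** Per-channel SNR `20·log10(|mean|/sd)` and accuracy
`(1 − |(mean − truth)/truth|)·100` over repeated frames, and the global
impedance index GI (pixel sum of each difference image, with its
reciprocal magnitude `|GI|⁻¹`) used for fluid-volume monitoring.

Synthetic phantoms reproduce the bench campaigns: a saline tank
(0.278 S/m) with insulating PVC and conductive copper rods, and agar
phantoms (0.217 S/m) with saline-filled cavities of radius 2.7/2.5/1.3 cm
at 1.227/1.890/2.07 S/m.

## Worked example

Simulate the closed current loop on a 1 kΩ load at the 0.98 mA setpoint:

```sh
$ eitpsoc loop --rl 1000 --id 0.98 --periods 4
period,amplitude_V,R_fb_kohm,I_true_mA,I_measured_mA,clipped
0,1.000000,40,0.909091,0.900000,0
1,1.088889,40,0.986364,0.980000,0
2,1.088889,40,0.986364,0.980000,0
3,1.088889,40,0.986364,0.980000,0
```

Period 0 starts from the 1 V bootstrap amplitude and under-delivers
(0.909 mA through the 1.1 kΩ load + shunt). After a single control update
the current is 0.986 mA — the 0.98 mA setpoint within one DAC/ADC
quantization step — and stays there.

The imaging pipeline end to end, from simulated captures to the
global-impedance series of an agar phantom with a large conductive cavity:

```sh
$ eitpsoc acquire --phantom agar-large --frames 5 --elements 1800 --seed 1 --out frames/
wrote 6 frames to frames/
$ eitpsoc gi --frames frames/ --elements 1800
frame,pixel_sum,inv_abs_gi
1,3.064771e+01,3.262886e-02
2,3.073772e+01,3.253331e-02
...
```

The positive pixel sum (~31) says the cavity is more conductive than the
agar background; its magnitude grows with cavity area, so `inv_abs_gi`
shrinks as the simulated fluid volume increases.

## Layout

- `src/eitpsoc/waveform.py` — DDS quantization, autoranging, control loop, RMS demodulation
- `src/eitpsoc/acquisition.py` — adjacent protocol, frames, frame-file format, noise
- `src/eitpsoc/forward.py` — disk mesh, FEM solver, protocol voltages, Jacobian
- `src/eitpsoc/reconstruction.py` — normalized differences, one-step operator, GN+TV
- `src/eitpsoc/metrics.py` — SNR, accuracy, global impedance
- `src/eitpsoc/phantoms.py` — named phantom scenarios and noise profiles
- `src/eitpsoc/cli.py` — the `eitpsoc` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
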