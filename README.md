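# granafit

Quantitative phenotyping of plant photosynthesis from chlorophyll
fluorescence, P700 absorbance, circular dichroism and electron-microscopy
lattice data — the measurement battery used to characterise *Arabidopsis*
LHCB antenna mutants whose PSII supercomplexes pack into semi-crystalline
arrays in the grana membranes.

The package is for photosynthesis researchers who have instrument exports
(fast-induction fluorometer, Dual-PAM-style saturation-pulse system,
kinetic spectrometer, CD spectropolarimeter) or micrograph-derived lattice
points/masks, and want the standard derived quantities with tests,
uncertainty-aware fits and a paired synthetic-data generator for every
input class.

## What it computes

**Fast induction (O–J–I–P), `granafit.ojip`.** Landmarks F₀ (50 µs),
F₃₀₀µₛ, F_J (2 ms), F_I (30 ms) and F_M, and the JIP-test derivatives

    FV/FM = (FM − F0)/FM            VJ = (FJ − F0)/(FM − F0)
    M0 = 4 (F300µs − F50µs)/(FM − F0)      TR0/RC = M0/VJ

TR₀/RC is an effective-antenna-size statistic. For DCMU-blocked induction
the complementary area between the double-normalised curve
V(t) = (F(t)−F₀)/(F_M−F₀) and its plateau gives the PSII absorption
cross-section via CA = 1/(σI), i.e. σ ∝ 1/CA at fixed intensity.

**Flash-decay deconvolution, `granafit.flash_decay`.** Bounded
trust-region least squares of the Q_A⁻ reoxidation model

    FV(t) = A0 + A1 e^(−t/T1) + A2 e^(−t/T2) + A3/(1 + t/T3)

over 15 µs–50 s, with canonical phase ordering and relative amplitudes
(fractions of A1+A2+A3).

**Saturation-pulse analysis, `granafit.pam`.** Y(II) = (F_M′−F)/F_M′,
NPQ = (F_M−F_M′)/F_M′, F₀′ by the Oxborough–Baker estimate,
qP = (F_M′−F)/(F_M′−F₀′); P700 yields Y(ND) = P/P_m,
Y(NA) = (P_m−P_m′)/P_m, Y(I) = 1−Y(ND)−Y(NA);
ETR = PAR·Y·0.84·0.5 and cyclic electron flow CEF = ETR-I − ETR-II.
State transitions: qT = (F_M′−F_M″)/F_M′ and the half-time of the
post-far-red fluorescence decay from a single-exponential fit.

**Psi-type CD bands, `granafit.cd`.** Qy-normalised amplitudes
CD(685)−CD(750) and CD(505)−CD(620) and their ratio, reporting long-range
chiral macro-order of PSII–LHCII.

**PSII array geometry, `granafit.lattice`.** 2D Bravais cell (a, b, α with
a ≥ b, α folded into (0°, 90°] and reported with its supplement), the φ
angle between the a vector and the supercomplex diagonal, and
crystalline-area fractions of grana membranes with a decile histogram.

**Synthetic data, `granafit.synth`.** Seeded generators for every input
class whose parameters are exactly the quantities the analyses recover;
the saturation-pulse generator is the algebraic inverse of the quenching
formulas, so forward analysis of its noiseless output is an identity.

## Worked example

```python
import granafit as gf

# a flash decay with fast/middle/slow phases at 475 us, 75 ms, 3.8 s
trace = gf.synth.gen_decay(
    {"A0": 0.0, "A1": 0.63, "A2": 0.15, "A3": 0.22,
     "T1": 4.75e-4, "T2": 7.5e-2, "T3": 3.8},
    noise=gf.NoiseSpec("gaussian_rel", 0.02, seed=5))
fit = gf.FlashDecayModel(trace).fit()
print(fit.summary())
```

prints

```
Flash-induced variable-fluorescence decay fit
  FV(t) = A0 + A1 e^(-t/T1) + A2 e^(-t/T2) + A3/(1 + t/T3)
  phase              tau   amplitude  fraction
  fast         0.0004778      0.6252     0.629
  middle         0.07547      0.1485     0.149
  slow(hyp)        3.768      0.2207     0.222
  A0 = 0.0001067   rss = 0.02323   converged = True (nfev 9)
```

i.e. the fast Q_A⁻→Q_B phase carries 63% of the variable fluorescence with
a ~478 µs time constant, the middle phase (centres with an empty Q_B
pocket) 15% at ~75 ms, and the slow recombination phase 22% at ~3.8 s —
the fitted values recover the generator's ground truth to a few percent at
2% multiplicative noise.

The same pattern applies everywhere: `gf.extract_ojip(trace)`,
`gf.complementary_area(vtrace)`, `gf.analyze_protocol(...)`,
`gf.state_transition(...)`, `gf.psi_band_amplitudes(spec)`,
`gf.fit_lattice(points)`. A thin CLI mirrors the library:

```sh
granafit simulate lattice --seed 0 --out demo/
granafit lattice demo/points.tsv --out demo/cell.json
```

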