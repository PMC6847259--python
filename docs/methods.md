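# Methods

## Thermodynamic model

Helical elements are scored with the unified oligonucleotide
nearest-neighbor (NN) parameter set: 10 unique stack terms plus a
bimolecular initiation term (ΔH = +0.2 kcal/mol, ΔS = −5.7 cal/mol/K) and a
per-end terminal-A/T penalty (+2.2, +6.9), shipped as a user-overridable
TSV (`tadsim/data/nn_unified.tsv`). Units are kcal/mol (ΔH),
cal/(mol·K) (ΔS) and kelvin internally; every user-facing interface speaks
°C and the file formats use °C and µM. Hairpin loops carry an entropy-only
penalty from a published loop-size table (ΔS = −1000·ΔG37/310.15),
linearly interpolated between tabulated sizes and Jacobson–Stockmayer
extrapolated beyond 30 nt. Note the published table is not strictly
monotone at every adjacent size (it plateaus at 3→4 nt and dips at
9→10 nt), so hairpin stability is only piecewise-monotone in loop length.

Salt: an entropy-only divalent correction,
ΔS += 0.368·(n_bp−1)·ln[Na⁺]_eq with [Na⁺]_eq = [mono] + 3.795·√[Mg²⁺]
(molar), applied once at design construction over the *net* base-pair change
of the reaction. The default buffer is 10 mM MgCl₂, matching the standard
TE/Mg²⁺ conditions for these systems. Mismatches, bulges, dangling ends and
full secondary-structure partition functions are out of scope; an optional
coaxial-stacking bonus per blunt stem exists but defaults to zero.

## Reaction thermodynamics of a design

The displacement I·S + ΣAC ⇌ AC·S + I is treated as a single lumped
all-or-nothing reaction (no partially bound intermediates at equilibrium).
Because the branch-migration domains β, γ are paired on both sides of the
reaction and the AC hairpins (H_L bp stem, H_l nt loop) stay folded whether
or not the AC is bound, both cancel exactly; what remains is

    ΔH°, ΔS°  =  [α-helix stacks + distal-end penalty]
               + N · [stem stacks + blunt-end penalty]
               + Δstrands · initiation
               + junction_count · junction penalty
               + salt correction over Δbp.

Topology per N follows the three reference architectures: N=0 → one AC
strand with two hairpins; N=2 → two AC strands with two blunt stems;
N=4 → three AC strands with four stems; all three form a pair of four-way
junctions (junction_count = 2, overridable). The default blunt-stem
sequence is AT-rich (`ATTA` repeats). This is a deliberate design choice:
it places per-base-pair stem stability near the operating temperatures in
the regime where adding stems (larger N) costs more in strand-sequestration
entropy than it gains in enthalpy — the regime the characterized designs
exhibit (T_d decreases with N). GC-rich stems would invert that trade-off.
Stem sequences are inputs and can be overridden per design.

The four-way-junction term defaults to (0, 0) and is calibrated: holding
its ΔH fixed, the per-junction ΔS is solved by bisection so the predicted
T_d of a chosen design matches an observed value (to 0.05 °C). Calibrating
the N=0 reference design to its observed 62 °C gives ΔS_junction ≈
−8.3 cal/(mol·K) per junction, i.e. junctions are entropically penalized
and increasingly destabilizing at high temperature. The model cannot
distinguish an enthalpic from an entropic junction penalty from a single
T_d; with richer data one would fit both.

## Equilibrium solve and melt summaries

At each temperature, K(T) = exp(−ΔG°(T)/RT) (1 M standard state) is
equated to the reaction quotient Q(x) of the single extent x; ln Q − ln K
is strictly increasing in x with guaranteed bracketing, so plain bisection
is used (≤200 iterations, |residual| < 1e−12). f = [AC·S]/S_total is
non-increasing in T whenever ΔH° < 0. T_d and ΔT are extracted either on a
grid (default 0.1 °C) with interpolation linear in (T, logit f) — which
removes sigmoid grid bias — or by direct bisection on f(T) = level
(`crossing_temperature`), used for scans and calibration. ΔT is reported as
the positive width T(1%) − T(99%).

## Melt-curve fitting

Plates are normalized per replicate against the per-temperature means of
the negative/positive control wells (0%/100% displacement), then
aggregated (normalize-then-aggregate propagates control noise honestly);
background subtraction is per-temperature, not scalar. The normalized
curve is fitted by weighted nonlinear least squares (lmfit) to the
two-state van't Hoff sigmoid

    f(T) = b_lo + (b_hi − b_lo) / (1 + exp[(ΔH_vH/R)(1/T − 1/T_half)]),

with constant baselines, oriented f-high-at-low-T (ΔH_vH < 0). Weights are
inverse replicate variances with the sd floored at 0.005 to avoid singular
weights. Initialization takes T_half from the smoothed derivative extremum
(ties broken toward the median f = 0.5 crossing) and |ΔH| from the midpoint
slope via |ΔH| = 4RT²|df/dT|; a small restart grid over ΔH guards against
local minima. Fits require the data to span at least 0.2–0.8 in f; when a
transition sits near the edge of the default 5–65 °C window, the
measurement window should be re-centred on the transition (the plate
protocol this emulates does exactly that), and the synthetic-recovery tests
follow suit (T_d − 30 … T_d + 20 °C). Hysteresis between annealing and
melting ramps is flagged when max|f_melt − f_anneal| strictly exceeds a
0.05 threshold. Kinetics traces are fitted to a single exponential;
flat traces and traces much shorter than the fitted half-life raise an
unidentifiability error rather than returning a silent fit.

## Kinetics, cycling, multiplexing

The lumped displacement reaction is integrated as a 1-D extent ODE with
forward rate k_f·[I·S]·Π[ACᵢ] and the reverse fixed by detailed balance
against K(T), so kinetic endpoints always agree with the equilibrium solve.
k_f defaults to the conventional 1e5 M⁻¹s⁻¹ bimolecular scale
(1e5·1000^(n_AC−1) for higher order) with an Arrhenius factor
(E_a = 10 kcal/mol) making low-temperature operation slower. Thermal
cycling applies square-wave protocols with instantaneous temperature
transitions (small well volumes equilibrate fast; a ramp option exists but
defaults off); per-cycle ON/OFF endpoint fractions, drift relative to cycle
1, and the largest run of cycles within tolerance are reported. Holds
shorter than five half-lives are recorded as warnings in the report — the
endpoints then converge geometrically to the periodic steady state of the
two-phase map rather than to equilibrium. The model contains no
degradation mechanism: thermally accelerated depurination, which must
eventually erode activity over very many cycles, is deliberately not
modelled, so unlimited cycle endurance in simulation says nothing about
chemical damage in a real sample. Multiplexed operation assumes declared
sequence orthogonality and factorizes into independent per-design solves;
cross-hybridization is not checked.

## Circuit model

The gate network is fixed in `tadsim/circuit.py` (advanced users can
replace rates and per-reaction thermodynamics wholesale):

| reaction      | scheme                              | kf (default)        |
|---------------|-------------------------------------|---------------------|
| thresholding  | w + Th ⇌ W_th                       | 2e6 M⁻¹s⁻¹          |
| initiation    | w + G + AC_i ⇌ C_i + O              | 5e6 M⁻²s⁻¹          |
| amplification | G + AC_a ⇌ C_a + O, catalysed by w  | 1e8 M⁻²s⁻¹          |
| reporting     | O + I1·S1 + AC_r ⇌ C_r + I1         | 1e8 M⁻²s⁻¹          |
| leak          | G + AC_a ⇌ C_a + O (uncatalysed)    | 1e-5 M⁻¹s⁻¹         |

Amplification is catalysed by the free *input* strand and is therefore
linear in input: output rises at a rate proportional to (input − threshold),
and input below the threshold — absorbed by the much faster thresholding
reaction — leaves the reporter at the circuit leak. (An output-autocatalytic
amplifier was rejected: exponential self-amplification saturates from any
leak seed within the 8 h operate phase and destroys thresholding.) Each
reaction's ΔH/ΔS defaults are set by two-point van't Hoff inversion of
anchor equilibrium constants at 35 and 65 °C, chosen so every reaction is
strongly forward at 35 °C at µM working concentrations and reverse-favored
at 65 °C (effective midpoints between the operate and reset temperatures);
thresholding is the most stable so an input titrated exactly at threshold
leaves only ~nM free input. All reverse rates are k_f/K(T) (the catalyst
accelerates both directions of amplification), so detailed balance holds
exactly and a 300 s hold at 65 °C resets every species; with no waste
accumulation, consecutive reset/operate cycles repeat the computation to
better than 1e−3. Integration is LSODA, rtol 1e−8, atol 1e−16 M, recorded
at 60 s intervals. Default concentrations: reporter 1 µM, gate/output 2 µM,
AC fuels 10 µM, threshold 0.6 µM (OR) or 1.2 µM (AND), 1 µM input per TRUE.

The leak constant is 1e−7 of the amplification rate referenced to a 1 µM
catalyst concentration. Note that at 35 °C the full network's true global
equilibrium is unreachable on experimental timescales (the uncatalysed
leak path equilibrates on ~1e10 s and the catalyst is progressively
sequestered by initiation), so 8 h endpoints are kinetically determined —
as they are in the laboratory protocol being modelled.

## Synthetic data

The generator emulates the plate experiments: 5 replicates per condition,
negative/positive controls defining 0%/100% displacement, 5–65 °C ramps at
1 °C resolution in both directions, additive Gaussian noise in *signal*
space (sd = noise_sd × gain, default 0.02 in fraction units), independent
noise in control wells, fixed seeds recorded in the output. Ground truth
is either an explicit van't Hoff curve or the equilibrium model of a
design. What it does not emulate: photobleaching, temperature-dependent
quantum yield, well-position effects, heteroscedastic or correlated noise,
instrument drift between ramps. Passing the recovery tests therefore shows
the estimators are correct and well-calibrated under the stated noise
model, not that real plates are free of those systematic effects.

## Problem sizes used in the shipped checks

The packaged verification suite uses 500 random design/temperature pairs
for the solver-vs-extent-scan equivalence (1e6-point scans), 50 synthetic
plates for T_d recovery, 600 thermal cycles for endurance, an 11-point
input sweep and a 4-point threshold grid for circuit behaviour, and
two reset/operate cycles for repeatability — sizes at which each check's
statistical power is already saturated.

## Known limitations

- The junction penalty is a single calibratable entropy per junction; real
  junction thermodynamics (sequence dependence, ion dependence, conformer
  exchange) are far richer, and quantitative design of TAD systems is
  limited by exactly this knowledge gap.
- Hairpin-stem length effects on T_d (observed when stems are shortened
  below the default 6 bp) are outside the lumped two-state model, which
  cancels hairpins exactly; modelling them needs partially folded states.
- Predicted absolute T_d values depend on the chosen stem sequences and on
  the NN set; the supported claims are the calibrated fixed point and the
  parameter-trend directions, not ab initio transition temperatures.
- The circuit's strand-level architecture is a reference implementation;
  rate constants are plausible defaults, not measurements.
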