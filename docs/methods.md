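# Methods

`neuroqsp` is a quantitative-systems-pharmacology pipeline that predicts how
three common genotypes — COMT Val158Met, the 5-HTTLPR rs25531 length
polymorphism and DRD2 Taq1A — modulate the clinical response of seven
antipsychotics (aripiprazole, clozapine, haloperidol, olanzapine,
paliperidone, quetiapine, risperidone) on three endpoints: change in PANSS
Total, extrapyramidal side-effect (EPS) liability, and 2-back working-memory
accuracy. This note documents the model layers, their assumptions, the
calibration choices, and what the simulations do and do not establish.

## Synaptic layer

Each neurotransmitter pool follows a pulsatile-release / first-order-clearance
model: tonic presynaptic firing at rate *r* (Hz) releases a concentration
quantum *q* (nM) per event, cleared with half-life *t½* (ms). The mean level
is `r · q · t½ / ln 2`. Genotypes act exclusively through clearance:

| locus | parameter | values |
|---|---|---|
| COMT VV / MV / MM | cortical dopamine *t½* | 100 / 130 / 160 ms |
| 5-HTTLPR LL / Ls / ss | serotonin *t½* (all compartments) | 55 / 75 / 100 ms |
| DRD2 A1A1 / A1A2 / A2A2 | striatal D2 receptor expression | 0.7 / 1.0 / 1.3 |

Striatal dopamine clearance is COMT-independent (the COMT effect is
documented by cortical D1-tracer displacement), and DRD2 Taq1A does not touch
the cortical compartment, so cognition is structurally independent of that
locus. Default quanta are scaled so that healthy basal levels are
100 nM-equivalents of striatal dopamine, 30 nM cortical dopamine and 50 nM
serotonin at the reference heterozygote (MV/Ls/A1A2); all are config-exposed
calibration conveniences, not measurements.

Schizophrenia pathology enters as a hyperdopaminergic striatum (release
× 1.5), a hypodopaminergic cortex (× 0.7), 20% glutamatergic and 20%
GABAergic cortical deficits, and a 1.3× noise gain.

## Receptor layer

Every receptor is a single Hill-1 competitive binding site at equilibrium:
`occ_drug = (D/Kd) / (1 + D/Kd + L/KL)`, the endogenous ligand analogously.
The activation signal is `(occ_ligand + α · occ_drug) · expression_scale`,
with intrinsic efficacy α (aripiprazole's D2 α = 0.25; 5-HT1A partial agonism
for aripiprazole, clozapine and quetiapine). Equilibrium is justified because
every downstream use is time-averaged; binding kinetics are cross-checked in
the tests against a brute-force two-ligand rate-equation oracle.

Eleven receptors are implemented (D1, D2, D4, 5-HT1A/2A/3/6, M1, α1, α2, H1).
Drug Ki values and endogenous-ligand affinities ship as a TSV/YAML config with
order-of-magnitude literature values; they are inputs, not study outputs.

Clinical dose is converted to an intrasynaptic functional concentration by
inverting simulated PET displacement: each (dose, striatal D2 occupancy)
anchor is inverted through the binding closed form with pathological striatal
dopamine competition, log-concentration is interpolated linearly in log-dose
between anchors, and extrapolation beyond the anchor range is proportional to
dose. Anchors near occupancy saturation amplify occupancy noise into
concentration error by `1/(occ·(1−occ))` — the synthetic anchor generator
therefore truncates its Gaussian noise at 1.5 sd, which bounds the round-trip
error below 15% for mid-range (≈40%) anchors.

## Circuit surrogates

All three readouts run on the same engine: vectorised leaky-integrate-and-fire
(LIF) populations (threshold 1, reset 0, 2 ms refractory, 1 ms Euler step)
coupled by population-level exponential synaptic traces normalised so that a
weight of 1 delivers unit current when the presynaptic population fires at
100 Hz. All populations operate in the fluctuation-driven regime (per-unit
Gaussian current noise, sd 2.8), which makes population rates smooth,
monotone functions of their inputs. Runs are deterministic given (config,
seed). Receptor signals couple as multiplicative gains
`exp(c · (signal − signal_ref))` relative to the untreated pathological
reference heterozygote, so the untreated reference is the calibration
operating point of every circuit.

**Efficacy loop** (40 cortical E, 10 cortical I, 20 D1-MSN, 20 D2-MSN,
10 GPi, 10 thalamic, 10 TRN): cortex drives both striatal pathways; the
direct (D1) pathway inhibits GPi, the collapsed indirect (D2) pathway excites
it; GPi gates thalamus; thalamus drives the thalamic reticular nucleus (TRN)
and closes the loop through cortex (including a corticothalamic branch). The
D1 signal scales direct-pathway excitability up (coupling 3), the D2 signal
scales indirect-pathway excitability down (coupling 4): D2 antagonism
re-engages the indirect pathway that hyperdopaminergic tone has silenced,
lowering thalamic/TRN rates. The readout is the plug-in Shannon entropy of
binary TRN spike words (10 ms bins, word length 3, pooled across units,
overlapping words, no bias correction — runs are long relative to the word
space). In this realisation the untreated pathological state sits at a higher
TRN rate and word entropy than treated states; the sign is carried entirely
by the affine calibration.

**ΔPANSS calibration**: piecewise-linear through anchors; default anchors put
zero entropy change at −8 points (placebo) and the mean relative entropy
change of the reference heterozygote on 10 mg haloperidol (−0.036, measured
over 8 seeds in this realisation) at −17 points. Placebo arms are simulated
as zero drug with full pathology and the subject's own genotype, referenced
to the untreated reference heterozygote, which reproduces genotype-dependent
placebo responses. With these surrogate anchors the simulated placebo span
across the 27 genotypes is ≈ −6 to −12 points.

**Motor loop** adds an external pallidum (GPe) and subthalamic nucleus (STN)
to the same cortical/striatal stage. STN receives a fast hyperdirect cortical
current (3 ms synapse — the gamma-band carrier) and a slow indirect-pathway
current (12 ms — the beta-band carrier) whose presynaptic source is the
D2-MSN population with the disynaptic pallidal relay collapsed into an
effective disinhibitory kernel; an explicit GPe↔STN pair at fixed modest gain
adds pallido-subthalamic temporal structure. Because pooled spike-train power
scales with rate, beta-band power tracks the D2-MSN rate, which is strictly
monotone in D2 antagonism; the motor loop uses a smaller D2 coupling (2.5)
than the efficacy loop so the D2-MSNs stay irregular across the whole drug
range (regular firing would invert the power-rate relation). The LFP proxy is
the summed rectified synaptic current into STN; the endpoint is the Welch
beta/gamma band-power ratio (13–30 / 30–80 Hz, 1 s Hann windows, 50%
overlap) mapped through a logistic (midpoint 1.74, slope 2) onto the fraction
of patients needing anticholinergics. The midpoint places the untreated
reference at ≈24%, inside the 16–32% untreated span, and the simulated
untreated genotypes cover ≈18–33%.

**Cognition network** (80 pyramidal, 30 interneurons, 20-unit memory subset):
slow (80 ms, NMDA-like) recurrent excitation within the stimulated subset
sustains activity after a 50 ms stimulus at t = 2 s; spike-frequency
adaptation with a long time constant (8 s, increment 0.008) ramps throughout
the trial so persistence ends at a graded, condition-dependent time rather
than switching between "never" and "forever". Modulator hooks: cortical D1
(and M1) raise pyramidal excitability — the coupling on D1 is large (40)
because basal cortical D1 occupancy is ≈0.01; D4 scales the recurrent
conductance (weakly, 1.0); 5-HT3 and 5-HT6 activation speed adaptation
(coupling 3 each), so the 5-HTTLPR ss genotype (high serotonin tone)
destabilises the network and drugs that block 5-HT6/5-HT3 (clozapine,
olanzapine) stabilise it; 5-HT1A agonism and α2 activation reduce noise;
5-HT2A activation adds noise. Working-memory span is the time from stimulus
offset until subset rate stays below 10 Hz for 100 ms (cap: trial end).
Accuracy is logistic in span (floor 50% = 2-alternative chance, ceiling
100%, midpoint 3 s, steepness 0.8), with the schizophrenia deficit applied
as a 1.5-SD (10.5 percentage point, SD 7) offset on accuracy, clamped at
chance — the offset is applied post-mapping because the published deficit is
stated on the cognitive readout scale. Simulated accuracies span ≈50–82%.

## Study pipeline

The factorial crosses drugs at their standard clinical doses (20 mg
aripiprazole, 200 mg clozapine, 10 mg haloperidol, 15 mg olanzapine, 9 mg
paliperidone, 400 mg quetiapine, 4 mg risperidone; dose grids within 20–140%
of standard for slope fits) with the 27 genotypes, the three endpoints and an
untreated arm. Per-cell seeds derive from the master seed through
`numpy.random.SeedSequence`; the cognition endpoint's seed ignores the DRD2
locus so the locus's null effect is bit-exact in study tables too.

Ranking follows the published procedure: each endpoint is centred per drug on
its genotype-frequency-weighted average (Hardy-Weinberg weights, allele
frequencies 0.5 per locus as the printed 12.5%/1.56% frequencies require),
oriented so lower is better (accuracy negated), ranked 1–7 within each
genotype with average ranks on ties, and summed across endpoints. Ties make
per-endpoint rows sum to 28 and totals to 84 exactly. Best-drug counting is
tie-inclusive — the only rule consistent with the published tie annotations.
Single-gene aggregates marginalise the two other loci with renormalised
Hardy-Weinberg weights. Dose-response slopes are ordinary least squares over
the 20–140% grid, reported per 100% of standard dose.

## Synthetic data

The generator emulates the study's inputs, not its outputs: virtual drugs in
three archetypes (strong-D2 antagonist Ki 0.5–5 nM, weak-D2 antagonist Ki
50–500 nM, D2 partial agonist α 0.2–0.4), with log-uniform affinities and
noise-free anchors hitting 80%/40%/85% standard-dose occupancy respectively;
noisy occupancy anchors (truncated Gaussian, monotonized); Hardy-Weinberg
cohorts. It does not emulate PET measurement physics, dose-exposure
pharmacokinetics or population stratification, so green generator tests
establish internal consistency of the binding/inversion machinery, not
fidelity to any real PET dataset.

## Numerical choices and degenerate inputs

1 ms Euler integration (the engine rejects steps above 1 ms); synaptic traces
are exact exponential decays; entropy requires rasters of at least
100 · bin · word_length; the spectral ratio guards division by zero gamma
power with a capped value and a warning; occupancy anchors at or above 100%
are rejected as infeasible; marginalisation over an incomplete genotype table
raises with the missing genotypes listed.

## Known limitations

* Circuit topologies and weights are documented surrogates tuned to sit at a
  plausible operating point; only directional and structural claims are
  asserted in tests (D2 antagonism raises beta/gamma; basal dopamine
  MM > MV > VV; basal serotonin ss > Ls > LL; DRD2 invariance of cognition).
  Published per-drug point values and per-genotype ranges depend on a
  proprietary calibration and are characterization context only; in
  particular the published direction "A2A2 improves efficacy for all drugs"
  is not reproduced by this realisation, whose placebo-referenced efficacy
  favours A1A1 (lower D2 expression acts like mild extra antagonism).
* Pharmacokinetics, CYP450 metabolism genotypes, plasma protein binding,
  active metabolites, the tri-allelic 5-HTTLPR variant, smoking and
  comedication are out of scope; paliperidone is its own profile, not derived
  from risperidone.
* The entropy estimator is the uncorrected plug-in; with 10 units × ~350
  overlapping words per run its seed-to-seed sd is ≈0.005 bits, an order of
  magnitude below the drug effects it discriminates.
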