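# Model and methods

`sdglu` simulates spreading depolarization (SD) in a single neuron–glia–ECS
unit with explicit glutamate homeostasis, and analyses SD recovery with a
slow–fast decomposition of the model's phase space. This note documents the
model equations and assumptions, the free parameters and how their defaults
were fixed, the numerical choices, and the limits of what the packaged
simulations demonstrate.

## Compartments and state

One neuron (resting volume ω_n0 = 15,000 μm³), one astrocyte
(ω_g0 = 15,000 μm³), and a shared extracellular space (ω_e0 = 7,500 μm³)
form a closed box: ω_n + ω_g + ω_e is constant and each cell exchanges
water osmotically with the ECS. The dynamical state comprises

- Hodgkin–Huxley gates n, h (Na⁺ activation m is instantaneous, m = m∞(V)),
  a slow Na⁺ window-current inactivation gate s, and first-order NMDA/AMPA
  receptor gates;
- Na⁺, K⁺ and Cl⁻ amounts in the neuron and the ECS (fmol);
- two slow K⁺ pools: the glial buffer load W and the cumulative amount
  exported to the bath;
- neuron and glia volumes;
- four glutamate pools: per-synapse releasable glutamate N_i, per-synapse
  cleft glutamate N_c, total ECS glutamate N_e and total buffered
  (taken-up, unrecycled) glutamate N_up.

The membrane potential is not integrated separately: it is the capacitor
voltage implied by the neuron's net charge,
V = (F / C_m A_m)(N_Na + N_K − N_Cl + z_A A_n), so C dV/dt = −ΣI holds as
an identity and charge bookkeeping can never drift from the potential. A
dynamical V next to complete per-ion bookkeeping would carry an exactly
conserved redundancy (a structural zero eigenvalue) that breaks fixed-point
continuation; the electroneutrality formulation removes it.

Impermeant intracellular anions (amount and mean charge fixed at
initialization) make the resting state simultaneously electroneutral and
isotonic. Leak conductances for Na⁺ and K⁺ are solved from the resting
flux balance, and neuronal Cl⁻ is placed at its Nernst equilibrium, so the
constructed resting state is an exact fixed point of the full system.

## Membrane and ion dynamics

Gated currents use standard HH rate functions (the shifted α/β forms of
the ion-homeostasis modelling lineage) with a gating speed factor φ = 3.
The Na⁺/K⁺ pump is electrogenic (3 Na⁺ out / 2 K⁺ in),
I_p = ρ_p · σ(Na_n) · σ(K_e), a product of sigmoids with half-activations
at 25 mM Na⁺ (slope 3 mM) and 5.5 mM K⁺ (slope 1 mM), ρ_p = 5.25 μA/cm².
Setting the protocol's pump scale to zero models complete pump failure.

**Slow Na⁺ inactivation (s).** The gated Na⁺ current is
g_Na m∞³ h s (V−E_Na) with ds/dt = (s∞(V) − s)/τ_s,
s∞ = 1/(1+exp((V−V_s)/k_s)), τ_s = 30 s, V_s = −40 mV, k_s = 5 mV.
This persistent-current inactivation — a standard ingredient of the
detailed biophysical SD models — caps the window current that can hold a
sustained depolarization. It is the model's repolarization engine: during
SD, K⁺ clearance necessarily loads the neuron with Na⁺ (the impermeant
anions pin the intracellular cation sum), E_Na collapses, and once the
remaining window current cannot match the pump's 3I_p Na⁺ export the
depolarized fixed point disappears in a fold and the membrane drops
abruptly to the pump-dominated hyperpolarized state. Without this gate the
depolarized state of the bare HH+pump+leak system is unconditionally
stable — V stays locked ≈ 2I_p/g_K above E_K on a quasi-static slide all
the way to K⁺ exhaustion — and SD under sustained high-K⁺ perfusion would
never terminate. Because τ_s is of the same order as the K⁺-pool
timescales, s is treated as a slow (clamped) variable in the fast-subsystem
analysis.

**Glial K⁺ buffering.** First-order uptake onto a finite capacity,
J_glia = k_f σ(K_e)(W_max − W) − k_b W, with a sigmoidal K_e activation
(half 18 mM, width 2.5 mM: glia engage strongly only at SD-level K⁺); the
backward rate is fixed by requiring equilibrium at the resting load W0.
Buffered K⁺ takes Cl⁻ along, so glia swell osmotically while buffering —
the model's glial-swelling pathway. Capacity W_max = 800 fmol bounds both
the clearance contribution and the total glia-driven ECS shrinkage.

**Bath exchange.** Diffusive in (K_bath − K_e) with rate λ = 2·10⁻⁵ /ms
referenced to the resting ECS volume. The exchanged K⁺ is swapped
one-for-one against Na⁺ — the equimolar NaCl/KCl replacement of a
perfusion bath — which is electro- and osmotically neutral for the ECS. A
KCl-co-export variant (`bath_mode="kcl"`) is available; it is osmotically
active and, during glutamate-prolonged SDs, shrinks the ECS to the
integration-abort level before the delayed recoveries can complete, which
is why the exchange mode is the default. An optional K_e-gated
amplification of the exchange coefficient (a functional-hyperemia-like
recruitment) exists but is disabled by default.

**Chloride and volumes.** Cl⁻ is fully dynamic with a small leak
(g_Cl = 0.005 mS/cm²); it is one of the slowest variables. Water moves at
P = 10⁻³ μm³/(ms·mM) per membrane, driven by the difference of total
osmolarities (ions plus impermeant anions); the ECS absorbs the opposite
of the summed cell volume changes. Integration aborts with a diagnostic if
the ECS falls below 5% of the box.

## Glutamate subsystem

Geometry: each of the N_syn = 10,000 synapses (half presynaptic to the
modelled neuron) has a half-spherical cleft of radius r = 0.2 μm and
height h, with envelope volume ω_en = 3 ω_c = 6πr²h. h ≈ 5.1 nm is chosen
so that one 3,000-molecule quantum raises the envelope concentration by
1.3 mM. Only 5% of the outer sphere is open for diffusion to the ECS;
the neural cleft-uptake contact area is twice the glial one.

Release is continuous: J_rel = R_max ((V−V_cr)/(V_hi−V_cr))² N_i/N_max
above V_cr (−40 mV; V_hi = 30 mV), zero below; R_max is calibrated so the
integral over one simulated action potential equals 3,000 molecules per
synapse (frozen value 8.51·10⁻⁶ fmol/ms). The releasable reserve is
N_max = 8·10⁻³ fmol (≈5·10⁶ molecules; tens of quanta are re-docked from
the recycling pool during an SD). Buffered glutamate recycles into N_i at
k_rec = 10⁻⁴ /ms; recycling is distributed as (2/N_syn)·k_rec·N_up per
synapse so the weighted total (N_syn/2)(N_i+N_c) + N_e + N_up is exactly
conserved. A `literal_recycling` flag reproduces the non-conserving
bookkeeping in which every synapse receives the whole recycled amount.

Receptors: first-order NMDA/AMPA gates driven by the cleft concentration
(Destexhe-type constants: AMPA α = 1.1 /(mM·ms), β = 0.19 /ms; NMDA
α = 0.072 /(mM·ms), β = 0.0066 /ms), ohmic Na⁺/K⁺ currents, NMDA with the
voltage-dependent Mg²⁺ block 1/(1+0.33[Mg]exp(−0.07V−0.7)), [Mg] = 1 mM.
Conductance densities 0.139 (NMDA) and 0.486 (AMPA) mS/cm² follow from
per-event conductances of 10⁻⁷ and 3.5·10⁻⁷ mS spread over the 5,000
active postsynaptic contacts of a 1.8·10⁻⁴ cm² membrane.

Uptake: Michaelis–Menten transporters (K_m = 0.02 mM) on four pathways.
Only v_cn_max (0.03 mM/ms) is free: glia have 8× the binding-site density
on half the contact area, so v_cg_max = 4 v_cn_max; ECS pathways use
v_en_max = 0.12 v_cn_max · ω_e0/ω_e and v_eg_max = 0.24 v_cg_max · ω_e0/ω_e
(the 0.12/0.24 coefficients are taken as printed constants of the model
family; the inverse-volume factor reflects that uptake velocity is a
concentration rate). Neuronal uptake cotransports 3 Na⁺ per glutamate,
carried as a membrane current. Cleft–ECS diffusion is linear in
(G_c − G_e) through the 5% window with D_G/Δx = 0.01 μm/ms; the cutoff
distance Δx = 40 μm stands in for the tortuous effective path to the
well-mixed ECS and sets the ~3–10 s cleft–ECS equilibration seen when
clearance is disabled.

## Protocols

- *Perfusion*: bath K⁺ steps 4 → 15 mM at t = 0 and stays elevated; all
  regulation intact.
- *OGD*: pump, glial/bath, and uptake activity ramp 1→0 over 15 s, hold at
  0 for 40 s, ramp back over 15 s (linear by default, cosine optional);
  bath K⁺ stays 4 mM.
- *Impaired uptake*: a constant fraction multiplies v_cn_max (all four
  pathways follow).

## Numerics

LSODA (stiff/non-stiff switching) with relative tolerance 10⁻⁸ by default
and per-variable absolute tolerances scaled to each component's typical
magnitude; dense output is sampled on a fixed 10-ms grid decoupled from
solver steps. The packaged analysis runs and the test suite use
rtol = 10⁻⁶, at which the detected SD duration agrees with a 10×-refined
run to well under 0.5%. The model is deterministic: identical
configurations give bit-identical sampled trajectories.

SD events: depolarization onset is the first time V exceeds −30 mV and
stays above it for 5 s (this skips the onset spike burst); repolarization
is the first later return to within 2 mV of the pre-SD baseline (mean over
the first 5 s). All three thresholds are configurable.

Fixed points of the clamped fast subsystem (V, n, h, receptor gates,
neuronal Na⁺, volumes; K⁺ eliminated through the charge–potential
relation; slow pools, neuronal Cl⁻, s, and glutamate clamped) are located
by damped Newton iteration with per-variable scaling and followed by
pseudo-arclength continuation with adaptive steps. Eigenvalues come from
central finite-difference Jacobians (relative step 10⁻⁶ per variable);
Hopf/fold markers are bracketed by sign changes of the leading real part
and refined by bisection in arclength. Continuation of limit cycles is out
of scope; the low-amplitude oscillations near branch ends are observed
only in direct simulation.

## Slow–fast analysis

ΔN^K = ΔN^K_glia + ΔN^K_bath (K⁺ removed from the neuron+ECS system) is
the bifurcation parameter; ΔN^K_glia must be specified separately because
the two pools affect Cl⁻ and glial volume differently. Neuronal Cl⁻ is
clamped with the slow variables: with Cl⁻ free, every depolarized fixed
point would satisfy the Donnan condition V = E_Cl, which pushes equilibria
to near-collapse volumes and destroys the timescale separation, while in
the full model Cl⁻ moves as slowly as the K⁺ pools. Cleft glutamate is
clamped as a second parameter (this is exact, not an approximation —
glutamate is fast).

Along a simulated perfusion SD, ΔN^K attains its cycle minimum at
depolarization and its maximum at repolarization, and continuation of the
depolarized branch at the last pre-repolarization clamps ends (fold)
within a few percent of the trajectory's repolarization ΔN^K: the
trajectory leaves the branch exactly where it loses existence.

Two independent determinations of the critical cleft-glutamate level are
computed. (1) *Branch overlap*: for each clamped G_c, the depolarized
branch end and the polarized branch start are continued from
trajectory-anchored seeds; recovery requires the polarized branch to begin
before the depolarized branch ends, and the overlap vanishes at a finite
G_c (≈0.05 mM at the packaged defaults) because the polarized branch
itself disappears. (2) *Membrane model*: with ion concentrations frozen at
the late-SD configuration, the stable hyperpolarized state (below E_K,
created by the pump current against collapsed conductances, Eq-32-type
balance) disappears above ≈0.011 mM. Both land inside the plausible
0.01–0.10 mM band, but they differ by a factor ≈5 in this
parameterization: the fast subsystem's polarized branch survives to higher
glutamate because its free ion amounts re-equilibrate (Na⁺ loading
re-activates the pump), which the frozen-ion membrane model cannot do.
Pump scaling moves both values together, so the gap is structural here
rather than a tuning artifact.

## Calibration summary

Free lineage parameters were fixed, in this order, against the printed
behavioral targets of the model family: bath rate λ for a depolarization
onset near 70 s under 4→15 mM perfusion; τ_s and the clearance rates for a
sustained depolarization of ~70 s with repolarization near 140 s;
glial capacity and the bath exchange mode so that glutamate-prolonged SDs
(~400–500 s near the failure threshold) complete without ECS collapse;
release threshold V_cr and reserve N_max so the cleft concentration jumps
to the millimolar range at onset, holds a 10–80 μM plateau during normal
SD, and equilibrates with the ECS near 5 mM when clearance is disabled.
After calibration the defaults were frozen in the packaged configuration
file and are not adjusted by any test or script.

## What the packaged runs do and do not show

The simulations demonstrate the qualitative SD phenomenology of a single
homogeneous unit: ignition by bath K⁺ or pump arrest, sustained
depolarization with near-collapsed gradients, cell swelling with ECS
shrinkage, abrupt pump-driven repolarization with a brief (seconds)
hyperpolarizing overshoot, glutamate-clearance-dependent SD duration with
a recovery-failure threshold, and the slow-fast structure connecting all
of this to fixed-point bifurcations. They do not capture spatial
propagation, Ca²⁺ signalling, transporter reversal, receptor
desensitization, or metabolic dynamics (OGD is represented purely by
activity scales). Two known cosmetic deviations: the hyperpolarizing
overshoot is deeper than physiological (the phenomenological pump lacks a
low-Na⁺ shutoff fast enough to soften it), and the OGD transition carries
a short (~0.4 s) spike burst, because any slow passage through the
excitable voltage window fires unless channels are already inactivated.
Quantities tied to the unprinted details of the source model family
(exact ΔN^K values in fmol, the precise failure-threshold fraction, the
critical glutamate levels) are parameterization-dependent calibration
outputs, not measurements.
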