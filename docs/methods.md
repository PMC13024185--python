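# Methods

`flashchem` models the radiation chemistry of a single, instantaneous
("Dirac") pulse of heavy charged particles crossing an aerated, cell-like
aqueous medium, and computes the oxygen-consumption yield G(−O₂) — the net
number of O₂ molecules consumed per 100 eV of absorbed energy — together with
oxygen-depletion fractions, from 1 ps to 1 s. The pipeline has three stages:
ion-track sampling (1 ps initial conditions), stochastic nonhomogeneous
chemistry by the independent-reaction-times (IRT) method (1 ps → 0.2 µs), and
deterministic well-mixed kinetics (0.2 µs → 1 s).

## The medium

A homogeneous "cellular water" at 25 °C: dissolved O₂ at 30 µM, a generic
1 M pool of oxidizable biomolecules RH, 6.5 mM glutathione (GSH), 1 mM
ascorbate (AH⁻), 1 µM nitric oxide (•NO), 0.2 mM α-tocopherol (TOH), plus
2.5 µM of carbon-centred bio-radicals R• created by direct ionization of RH
(entering at the homogeneous stage, independent of the pulse's stochastic
chemistry). These solutes are treated as continuum scavengers during the
particle stage; in the homogeneous stage O₂ and •NO can be integrated as
dynamic species while the large pools (RH, GSH, AH⁻, TOH) are held fixed
(their consumption at ≤ 30 Gy is orders of magnitude below the pool size).

## Reaction scheme

`flashchem/data/` ships an editable three-table scheme (species, reactions,
background solutes): the standard pure-water radiolysis set at 25 °C
(Elliot/Buxton-compilation rate constants, 25 reactions) plus a cellular
extension (18 reactions). The cellular core is the oxygen-consumption
network

* R• + O₂ → ROO•  (k = 2×10⁹ M⁻¹s⁻¹)
* •OH + GSH → GS• + H₂O  (k = 1.4×10¹⁰)
* GS• + GSH → GSSG•⁻ + H⁺  (k = 3.5×10⁸)
* GSSG•⁻ + O₂ → GSSG + O₂•⁻  (k = 5.1×10⁸)

supplemented by H-abstraction from RH by •OH (k = 1×10⁸, a typical
H-abstraction value; with 1 M RH this gives a scavenging capacity of
1×10⁸ s⁻¹, comparable to GSH's 9.1×10⁷ s⁻¹, so the bio-radical and
glutathione routes to O₂ consumption are of comparable size), repair of R•
by the thiol and by ascorbate (R•+GSH → RH+GS•, R•+AH⁻ → RH+A•⁻, both
k = 1×10⁷) — the classical competition between chemical repair and oxygen
fixation — and the superoxide network: HO₂•/O₂•⁻ proton equilibrium
(pKa 4.8, explicit H⁺), the O₂-regenerating dismutation channels
(HO₂•+HO₂•, HO₂•+O₂•⁻), and O₂•⁻ + •NO → ONOO⁻.

Deliberate omissions, each swappable by editing the scheme file:

* reducing channels of e⁻aq toward RH/GSH — the pools are modeled purely as
  targets of oxidizing radicals; e⁻aq reacts with O₂, H⁺, H₂O₂ and other
  radicals;
* O₂•⁻ + ascorbate (literature rate constants span 10²–3×10⁵ M⁻¹s⁻¹ and the
  channel is commonly neglected at physiological pH);
* Russell-type peroxyl self-termination (which would regenerate O₂): at
  cellular antioxidant levels ROO• is repaired by AH⁻/TOH (~10³ s⁻¹) long
  before self-encounter at µM radical densities;
* channels with scavenging capacity below ~5×10⁴ s⁻¹ for a given radical.

Every bimolecular rate constant is converted to an encounter description:
fully diffusion-controlled reactions invert the Smoluchowski relation
R = k/(4πD′N_A) (with the Debye factor for charged pairs; the Onsager radius
in water at 25 °C is 0.714 nm); partially diffusion-controlled ones carry a
physical radius and a Collins–Kimball activation rate. Reactions whose rate
constant lies below the Coulomb-funnel diffusion limit of an attractive pair
(e⁻aq+H⁺, O₂•⁻+H⁺, HO₂⁻+H⁺) are classified partially controlled.

## Track model (1 ps initial conditions)

LET is an input; the ion's energy per nucleon is either given or chosen from
a bundled proton stopping-power table with Barkas effective-charge scaling
(this reproduces, at the few-percent level, the standard energies of He, C
and Ne ions at ~70 keV/µm). The deposited energy is exactly LET × segment
length, partitioned into ~47 eV deposition events:

* **Core**: events along the ion path at a radial Gaussian spread
  σ_core = max(8 nm, 11.6 β nm). The 8 nm floor represents the radial
  dispersal of deposition sites by sub-threshold (< 100 eV) secondary
  electrons plus prehydration transport; it was calibrated once against
  published pure-water •OH decay kinetics of ~70 keV/µm proton tracks
  (G(•OH) ≈ 3.5/2.2/1.2/0.9 at 1 ns/10 ns/100 ns/1 µs), not against any
  oxygen-depletion value.
* **Penumbra**: a velocity-dependent fraction
  f = ln(T_max/T_cut) / (2 ln(T_max/I)) of the energy (T_cut = 100 eV,
  I = 75 eV, T_max = 2m_ec²β²γ²) is carried by explicit δ rays drawn from
  the 1/T² knock-on spectrum. Each δ ray lays its spurs along a radial
  straight path with spacing set by the electron's stopping power at its
  full sampled energy (so a δ ray that deposits only part of its energy
  within the segment's budget still spreads it at the correct spacing).
  Electron ranges come from a bundled CSDA-style lookup.

Species per event are Poisson-sampled from the 1 ps yields (low-LET
convention: e⁻aq 4.2, •OH 5.0, H• 0.6, H₂ 0.15, H⁺ 4.2 per 100 eV) with
Gaussian displacements (σ = 4 nm for e⁻aq, 1 nm for heavy species). The
per-event yields are LET-independent: all LET and track-structure effects
emerge from spatial overlap. N track axes are placed uniformly over the
beam disc (R₀ = 0.1 µm); the segment is periodic along the beam axis for
pair distances. Default segment length: 1 µm below 10 keV/µm, 0.2 µm above
(convergence-checked; high-LET tracks at 0.2 µm already hold ~4×10⁴
particles).

The absorbed dose of the pulse is N·LET/(πR₀²ρ); for the reference N = 20,
0.3 keV/µm, R₀ = 0.1 µm pulse this is 30.6 Gy (the "~30 Gy" FLASH pulse,
instantaneous dose rate ~10⁶–10⁷ Gy/s).

## IRT stage (1 ps → 0.2 µs)

For every eligible pair the first-passage reaction time is sampled from
W(t | r₀) = (R_eff/x(r₀)) · erfc[(x(r₀) − R_eff)/√(4D′t)], with
R_eff = k/(4πD′N_A) and x the Debye-transformed separation for charged
pairs; scavenging channels draw exponential times at k[S]. Candidate times
are processed in order; reactants die, products appear and are re-sampled
against the survivors (no retroactive re-draws — the conventional IRT
bookkeeping). Three position-bookkeeping refinements matter and are worth
stating:

* a particle consumed by a *scavenger* dies at a freely-propagated position
  (exact, since continuum sinks are spatially homogeneous);
* products of a *pair* event get the pair's centre-of-diffusion spread,
  N(0, 2·D₁D₂/(D₁+D₂)·(t−birth)) around the diffusion-weighted point
  between the reactants (the centre coordinate diffuses independently of
  the relative coordinate that hit contact);
* optionally (``age_partner_positions``, default off), candidate
  separations between a newborn and an older survivor age the survivor's
  position by its diffusion since birth.  The default follows the
  conventional IRT bookkeeping (sampling against stored positions, no
  retroactive re-draws); switching aging on shifts the 1 s yields by less
  than ~4% at a 2–4x runtime cost.

Numerical choices: candidate pairs are screened by a per-pair-type cutoff
(reachability within the remaining horizon at 3σ, plus an ultimate-
probability floor of 10⁻⁴); coincident-birth pairs react at contact;
simultaneous events tie-break by heap order; a single xorshift128+ stream
per run seeded from the master seed makes every run bit-reproducible. The
switch time t_switch = 0.2 µs is the end of spur expansion; it is
configurable.

**Validation.** The engine is cross-checked against a step-by-step
random-walk simulator (Brownian steps, bridge-crossing correction,
identical effective-absorber radii) on a fixture catalogue (isolated pair,
7-species spur, two spurs, scavenger bath): all channels agree within 3σ of
the combined Monte Carlo error, except H⁺ + OH⁻ recombination inside a
compact spur, which the independent-times approximation overestimates by
~30–40% relative to the brute-force walk (bounded in the tests; the true
value lies between the two, since the drift-free walk underestimates the
Coulomb funnel). Neutralization does not enter the O₂ bookkeeping. The
isolated-pair time distribution matches the erfc closed form to better
than 1% at 10⁵ samples.

## Homogeneous stage (0.2 µs → 1 s)

Surviving yields are mapped to concentrations through
c = G × 0.103364 µmol J⁻¹ × D and integrated as mass-action kinetics with a
stiff BDF solver on a log-spaced grid; per-reaction extents are integrated
alongside for the ΔG(−O₂) decomposition, whose signed sum equals the total
exactly. Two oxygen conventions are always computed side by side: continuum
(O₂ held at its pool value; the convention for reporting G(−O₂), which is
then dose-independent) and self-consistent (depletable O₂; the convention
for depletion fractions).

**Dose context.** The concentration map needs a dose. The in-cylinder
energy density of an N = 20 pulse exceeds the cell-average dose by the LET
ratio (7.2 kGy at 71 keV/µm), and using it would put the homogeneous stage
in a radical-radical-dominated regime no cell at ~30 Gy ever sees. The
track segment is a per-unit-energy microcosm of the cell's track
population, so the homogeneous dilution is set by a *cell-average dose
context*: by default absorbed_dose(N, 0.3 keV/µm, R₀), i.e. the reference
low-LET FLASH pulse of the same geometry (30.6 Gy at N = 20). It is
configurable (`RunOptions.dose_context_gy`).

**Depletion conventions.** The self-consistent depletion fraction is read
at the end of the window (1 s). Because superoxide dismutation regenerates
O₂, the trajectory dips below its final value (trough ~58% vs ~44% at 1 s
for the reference pulse at 30 µM); the transient maximum is reported
separately (`transient_depletion_fraction`).

## What the defaults mean scientifically

| parameter | default | meaning |
|---|---|---|
| N | 20 | ions per pulse; ~30 Gy, 10⁶–10⁷ Gy/s instantaneous |
| R₀ | 0.1 µm | beam radius; fluence N/πR₀² |
| segment | 1 µm (0.2 µm ≥ 10 keV/µm) | simulated track length |
| mean spur energy | 47 eV | Magee-spur convention |
| σ(e⁻aq), σ(heavy) | 4, 1 nm | 1 ps displacement about a deposition site |
| σ_core floor | 8 nm | sub-100 eV electron transport (calibrated, see above) |
| δ threshold | 100 eV | explicit-δ-ray cutoff |
| t_switch | 0.2 µs | end of spur expansion |
| t_end | 1 s | reporting horizon |
| [O₂]₀ | 30 µM | well-oxygenated tissue |
| direct R• | 2.5 µM | direct-action bio-radicals, dose-independent |
| replicates | 16 (8 for the heaviest configurations) | seeded, independent |

## What the generator does and does not emulate

The synthetic tracks reproduce the features that drive the chemistry:
total energy per length (LET), the core/penumbra energy split and its
velocity dependence, δ-ray range scaling, spur-scale clustering, and
multi-track proximity in a FLASH pulse. They do **not** emulate
event-by-event ionization/excitation cross-sections, sub-excitation
electron thermalization, LET-dependent 1 ps yields, charge-changing
collisions, or nuclear fragmentation. Consequently the pipeline's absolute
yields inherit the calibration of the core width and the 1 ps yields;
agreement on trends (LET dependence, track-structure ordering) is the more
robust prediction, and passing tests certify the stated model, not
event-level track structure.

## Known limitations

* The proton-vs-heavy-ion contrast at fixed ~70 keV/µm is compressed: slow
  protons (and He) come out ~0.3–0.5 G units above the published values
  while the heavy ions land on them. The 0.15 MeV proton core is
  insufficiently recombinative at the calibrated core width; narrowing it
  would break the mid-LET and heavy-ion agreement. The high-LET proton
  yield is therefore expected to read ~2.0–2.1 rather than ~1.6.
* The Z-scan has no mechanism that penalizes the most extended penumbrae:
  dilution saturates at the low-LET chemistry limit, so the yield rises
  gently toward argon instead of turning over near Z ≈ 8.
* H⁺ + OH⁻ recombination inside compact spurs is overestimated by the IRT
  approximation (see Validation); this perturbs the early pH trace
  slightly but not the O₂ budget.
* The medium is unbuffered: the pulse acidifies it transiently (pH ~5 at
  30 Gy), which accelerates HO₂•/O₂•⁻ dismutation relative to a buffered
  cytosol.
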