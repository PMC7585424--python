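# Methods

## Steady-state isotope box model

The lake's DIC pool is treated as a single well-mixed box at steady
state: total carbon and ¹³C are both conserved,

    Σ f_in = Σ f_out,        Σ f_in·δ¹³C_in = Σ f_out·δ¹³C_out,

with fluxes f in mmolC m⁻² d⁻¹ and isotopic compositions in ‰ VPDB.
Steady state is justified by the multi-decadal stability of the sediment
δ¹³C record.  Every term ties its composition to the pool either through
an absolute δ¹³C (the detrital and magmatic inputs) or through a **net
enrichment offset** ε with δ¹³C_term = δ¹³C_DIC + ε.  Organic-derived
terms compose their offset from the photosynthetic fractionation ε_ph
(26.2 ‰, from the DIC–POC contrast): respiration returns organic carbon
at −ε_ph + ε_resp; methanogenic CO₂ at −ε_ph + ε_CO2-meth; the oxidized
methane at −ε_ph − ε_CH4-meth − ε_oxy.  Degassing CO₂ sits at −ε_deg.

With this convention the isotope balance is linear in δ¹³C_DIC:
Σf·δ over a side equals A·δ¹³C_DIC + B, where ε-type terms contribute
flux to A and flux·ε to B, absolute terms only flux·δ to B, so

    δ¹³C_DIC = (B_out − B_in) / (A_in − A_out).

The solver refuses networks whose ε-carried flux difference A_in − A_out
vanishes (the pool composition is then unconstrained) and networks that
are not mass-balanced.  Because published flux tables are rounded, the
forward solver takes a caller-stated mass tolerance (`mass_rtol`); the
packaged reference network is imbalanced by 0.9 mmolC m⁻² d⁻¹ (inputs
528, outputs 528.9) and is evaluated at `mass_rtol = 5e-3`.

**Carbonate sign convention.** The measured carbonate (+16.2 ‰) is
heavier than the DIC (+12.1 ‰), so the carbonate output is modelled at
δ¹³C_DIC **+** ε_carb (ε_carb = 4.1 ‰).  The alternative sign (−ε_carb)
would shift the reference forward solution from +11.768 to +11.871 ‰;
with f_carb only 1.9 mmolC m⁻² d⁻¹ the choice is a 0.1 ‰ effect, and the
measured-composition convention is retained.

**Inverse problem.** When exactly the combined detrital + magmatic input
is unconstrained, the mass balance gives its flux f_nc = Σout − Σin and
the isotope balance at the measured δ¹³C_DIC gives its composition
δ_nc; a two-end-member linear unmix then splits it between the detrital
(−26.7 ‰) and magmatic (−2.7 ‰) sources.  A negative solved flux, or a
δ_nc outside the end-member interval, raises an error — it is never
clipped silently.  (The pipeline, which feeds the solver noisy synthetic
campaigns, is the one consumer that catches the out-of-interval case and
pins the split to the nearest end-member, with a logged warning.)

## Methane partitioning

Methanogenesis degrades sedimentary organic carbon (SOC, −14.5 ‰) into
CO₂ and CH₄ at a production ratio r (baseline 1:1).  Of the CH₄
produced, a fraction `escape_frac` (baseline 0.64 — an upper-limit
assumption, exposed as config, not a derived quantity) reaches the
atmosphere; the rest is oxidized in the water column.  Mass balances:

    f_meth = f_CO2-meth + f_CH4-meth,   f_CH4-meth = f_oxy + f_CH4-deg.

Isotope balances give the methanogenic CO₂,
δ_CO2 = ((1+r)·δ_SOC − δ_CH4)/r, hence ε_CO2-meth = (δ_SOC − δ_CH4)/r
(53.6 ‰ at r = 1, equal to ε_CH4-meth by symmetry), and the oxidized
CH₄, δ_oxy = (f_CH4-meth·δ_CH4 − f_CH4-deg·δ_CH4-deg)/f_oxy, i.e.
ε_oxy = (e/(1−e))·(δ_CH4-deg − δ_CH4) at escape fraction e.  The
porewater CH₄ mean (−68.1 ‰) is used as the produced-CH₄ signature, per
the measurement closest to the production site; the water-column mean
(−71 ‰) is a config alternative.  At 100 % escape the oxidation term
carries no carbon and is dropped from both balances rather than
evaluated with an undefined composition.

## Sediment burial

Porosity follows φ(z) = −0.0199 ln z + 0.8188 (z in metres), clipped at
0.98 near the surface where the log form diverges.  Solid-mass
conservation, d[(1−φ)ω]/dz = 0, fixes the sedimentation rate from the
radiocarbon anchor ω = 1.2 mm yr⁻¹ at 1 m; the solids flux
(1−φ)ω = 0.21744 mm yr⁻¹ is therefore depth-independent, and the organic
burial flux

    f_burial = (1−φ)·ω·ρ_dry·TOC · 10⁶ / 12.011   (mmolC m⁻² d⁻¹)

depends on porosity only through the anchor.  The dry-solids density
ρ_dry is not measured; it is calibrated once (739.78 kg m⁻³,
`scripts/calibrate_rho_dry.py`) so that the midpoint TOC (0.15 of the
0.10–0.20 range) yields 5.5 mmolC m⁻² d⁻¹; the TOC range then spans
3.67–7.33, bracketing the reported 3.6–7.2.  Carbonate burial scales
from the organic flux by the sediment carbonate:organic carbon ratio,
defaulting to 1.9/5.5 (back-computed from the reported averages — the
ratio itself is not printed).  Burial shares are reported against GPP
(404) and NPP (404 − 214): 1.4 % and 2.9 %.

## Primary production

Bottle incubations across a 0–1500 µmol photons m⁻² s⁻¹ gradient give
gross rates (net + |dark respiration|, O₂→C at PQ = 1).  The default PI
form is the exponential photoinhibition model

    P(I) = Pₛ(1 − e^(−αI/Pₛ))·e^(−βI/Pₛ),
    Pmax = Pₛ·(α/(α+β))·(β/(α+β))^(β/α),

fit by bounded least squares (scipy) with analytic initials; the
Eilers–Peeters peak function P(I) = I/(aI² + bI + c) is available via
`model="eilers_peeters"` since the literature citation behind the
original analysis admits either.  Fits whose observations stop short of
the saturation onset Ik = Pmax/α are flagged, not rejected.

Incident PAR is simulated from solar geometry (declination + hour angle,
local solar time) scaled by a single turbidity/shortwave-to-PAR factor
(default 0.75 of a 2400 µmol m⁻² s⁻¹ normal-incidence ceiling), because
the exact radiative scheme behind the original simulation is not
specified; PAR is therefore exactly linear in that factor.  The
underwater field is I(z,t) = I₀(t)e^(−kz) (default k = 4.5 m⁻¹ for this
turbid system).  Daily GPP is a trapezoidal quadrature over the photic
column (default z_max 5 m, dz 0.05 m) and 24 h (dt 0.25 h); halving both
steps moves the default-campaign result by < 0.1 %.  Respiration
integrates the dark rate over the oxic layer (default 1.5 m) for 24 h.
The annual rate is the mean of the parameterized months (April and
October — the two the campaign measured; a weighting hook exists).

## Sensitivity sweeps

The baseline network is rebuilt at full precision from the anchors (GPP
404, respiration 214, CO₂ degassing 123, carbonate 1.9, CH₄ degassing
77, escape 0.64, r = 1, measured δ¹³C_DIC +12.1); the detrital/magmatic
input is solved and split as above, so the baseline reproduces +12.1
exactly and the identity scenario returns the baseline network itself.

Scenarios vary the remineralization partition x = f_meth/(f_resp+f_meth)
with the total remineralized carbon held at its baseline sum
(454.625 mmolC m⁻² d⁻¹) — the conserved quantity along the sweep axis is
a design choice, made so the baseline point and the limiting behaviours
are reproduced.  The escape fraction sweeps 0–0.85; CO₂:CH₄ takes
1.2:1 and 1:1.2; the photosynthesis multiplier scales GPP **and** the
remineralized pool proportionally (remineralization degrades the
production, so scaling one without the other would drive the network
through a degenerate point where the ε-carried flux difference
vanishes); extra burial (7 % of GPP vs the baseline 1.36 %) is
reallocated out of remineralization; the detrital/magmatic split can be
fixed at 68/32 instead of the solved ≈ 86/14.  Within a scenario only
the combined detrital + magmatic input rebalances the network (at its
fixed split); grid points needing a negative rebalancing flux are
flagged infeasible, never raised.  Published curve values are not
digitized; the sweeps are validated through the baseline band crossing,
orderings and monotonicity.

## Synthetic campaigns

The generator emulates the campaign's statistical structure, not its
hydrodynamics: each isotope pool is an independent normal with the
reported mean and SD (δ¹³C_DIC +12.1/0.6 mixed, +13/+11 across the 2-m
halocline when stratified; POC −14.1/0.8; carbonate +16.2/1.1; organic
−14.5/0.7; porewater CH₄ −68.1/2.4; water-column CH₄ −71/6; degassing
CH₄ −65.4/0.7), with stated analytical noise added on top (0.16 ‰ DIC,
0.2 ‰ carbonate, 0.01 M DIC concentration).  DIC concentration is 0.2 M
(0.1 above / 0.2 M below the chemocline when stratified).  Porosity is
the log law plus 0.01 noise, clipped to (0, 0.98]; TOC is uniform on
[0.10, 0.20]; chamber fluxes are normals at 123/77 mmolC m⁻² d⁻¹ (SDs
30/20 — chosen as plausible chamber scatter; the campaign reports only
means); the ebullitive share is a truncated normal (0.18, 0.15) on
[0, 1].  The default incubation truth (Pₛ = 95, α = 0.31, β = 0.017,
dark respiration 5.94 mmolC m⁻³ h⁻¹) was chosen once so the integrated
campaign reproduces the measured GPP (≈ 404) and respiration (≈ 214).
All draws flow through one `numpy.random.default_rng(seed)` (PCG64) in a
fixed order, so a seed fully determines a campaign on any platform.
Because pools are drawn independently, passing tests demonstrate the
machinery and its statistical calibration — not covariances, seasonal
dynamics or spatial structure of real field data.

## Numerical choices and limitations

- All arithmetic runs at double precision; rounding to 0.1 ‰ and
  1 mmolC m⁻² d⁻¹ happens only in reporting layers.
- Solver closure tolerances are 1e-9 relative; the packaged reference
  table is the one input evaluated at a coarser, documented 5e-3 mass
  tolerance (its printed values are rounded).
- Published values recomputed from printed (rounded) inputs land close
  but not exactly: the forward solve gives +11.77 vs +12.1 ‰ and the
  detrital/magmatic split ≈ 131/21 vs 133/18 — the original chain used
  unrounded supplementary values not reproduced in the main text.
- The model is a single box at steady state: no time dependence, no
  vertical resolution of the DIC pool, no chemical speciation, no
  mechanistic methanotrophy or ebullition transport, and no uncertainty
  propagation beyond the scripted scenario sweeps.
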