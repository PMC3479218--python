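# Methods

## The model

The package implements a deterministic, receptor-centred interpretation of
the human ovulatory cycle in which the gonadotropin surge needs no
"positive feedback" switch in the sign of estrogen action.  Three
mechanisms carry the cycle:

1. **Two-mode GnRH secretion.** The hypothalamus secretes GnRH at a low
   rate `g_low` through the follicular phase and at a high rate `g_high`
   from the preovulatory days to luteolysis.  The mode is set by the
   estrogen signal the hypothalamus can actually sense, `S = E_f · ERh`
   (free estradiol times hypothalamic estrogen-receptor availability).
   LOW→HIGH requires `S > theta_on` sustained for `tau_on` days;
   HIGH→LOW fires the moment `S < theta_off` (`theta_off < theta_on`,
   a hysteresis band).  The asymmetry reflects the slow build-up of
   estrogen action before the surge versus the abrupt end of the luteal
   phase.

2. **Pituitary GnRH-receptor turnover.** Receptor availability `R ∈ [0,1]`
   obeys `dR/dt = alpha_R (1 − R) − beta_R G R`: receptors accumulate
   under low drive and downregulate under high drive.  The surge is the
   transient product of *accumulated* receptors meeting *increased*
   drive; it self-terminates as `R` collapses.  Gonadotropin secretion is
   proportional to `G_sec · R`, where `G_sec = G / (1 + G/G_sat)` is the
   drive saturated by the finite release capacity of the gonadotrophs.
   The saturation matters for one prediction only, but decisively:
   because secretion saturates while downregulation keeps growing
   linearly in `G`, *continuous overexposure* (a depot GnRH agonist,
   modelled as a locked drive `g_agonist ≫ g_high`) ends in hypogonadal
   LH below the follicular level.  With fully linear forms the steady
   drive `G·alpha_R/(alpha_R + beta_R G)` is increasing in `G` and that
   clinical observation is unreproducible — this is the one place the
   package departs from the simplest mass-action writing of the model.

3. **Steroid-receptor cross-regulation.** Estrogen exposure induces
   progesterone receptors (`alpha_PgR · E_f · ER · (1 − PgR)`), while
   progesterone signalling (`Pg · PgR`) represses both ER and PgR.  The
   small induction constant makes pituitary PgR expression *lag* the
   estrogen rise by days, which is what delays the luteal LH–progesterone
   negative feedback to the mid-luteal phase; the same repression acting
   on hypothalamic ER eventually blinds the hypothalamus to estrogen and
   triggers the HIGH→LOW switch (luteolysis).  Hypothalamic and pituitary
   pools share kinetic forms with separate constants; the shipped
   defaults tie the corresponding constants to reduce the calibration
   dimension.

The ovary is reduced to a dominant-follicle activity `F` (logistic growth
driven by FSH, hard reseeded to `F0` once the corpus luteum has regressed
below 1% of its post-ovulation value) and a corpus-luteum activity `L`
(set to `F` at ovulation, decaying at `mu_L / (1 + LH/kappa_L)` so that
falling LH accelerates luteolysis).  Ovulation fires when LH exceeds
`LH_ov` while `F > F_ov`.  Estradiol is secreted by both compartments and
buffered by a saturable SHBG pool (`E_f = E_tot − B_max E_tot/(K_B +
E_tot)`, clipped at zero): early-cycle estrogen is largely captured by
the empty pool, which keeps FSH from being suppressed prematurely.
Inhibin is not a state variable; its follicular restraint of FSH is
absorbed into the `kappa_E` half-inhibition constant.

## Numerics

The state advances by the explicit midpoint rule (second-order
Runge–Kutta) with step `dt = 0.002` day.  The three threshold events —
ovulation, LOW→HIGH, HIGH→LOW — are *localized inside the step* by linear
interpolation of the crossing condition, the regime change is applied at
the interpolated time, and the remainder of the step is integrated under
the new regime.  Both pieces are necessary: with plain explicit Euler and
step-boundary events, the O(dt) phase error of the switch times is
amplified by the steep surge (day-sampled LH can shift by tens of percent
when dt is halved at any practical step).  With the packaged scheme,
halving dt changes every day-sampled hormone value by less than 1% over a
120-day run.  All receptor fractions are clipped to [0,1] and all
concentrations to ≥ 0 after every stage.  The inner loop is JIT-compiled
(numba); one 120-day simulation takes a few milliseconds, which is what
makes derivative-free calibration and the parameter-recovery test cheap.

`simulate` samples at integer days and is bit-deterministic for identical
inputs; events carry their interpolated continuous times.

## Units and scales

Gonadotropins are reported in IU/L, estradiol in pmol/L, progesterone in
nmol/L; day 0 of a cycle is the LH maximum, so one idealized cycle spans
days −14…+13.  The published medians anchor three LH values only
(follicular plateau 7.02, surge 41.19, post-surge 14.92 IU/L); every
other magnitude in the reference fixture and the simulator is a
calibration product or a qualitative-shape choice, and must not be read
as measured data.  Units on the bare anchor numbers are themselves a
convention.

## The reference fixture

`generate_reference_cycle()` returns a versioned 28-day table built to
satisfy, exactly, the event anchors (LH plateau/surge/post-surge values,
progesterone peak at day +7, luteal LH minimum at day +11, estradiol
rising monotonically over days −6…−1 and collapsing after day +10,
near-zero follicular progesterone) and the two phase-plane patterns: the
FSH–estradiol orbit crosses itself (the "leaning &") and the
LH–progesterone orbit is a simple open loop (the "boomerang").  The
follicular LH reference 7.02 is placed as a flat plateau on days −14…−5
and the follicular baseline is defined as the median over those days,
which makes the printed 5.8-fold surge ratio exactly recomputable.  The
post-surge value 14.92 is assigned to day +1, matching the described
first-postovulatory-day fall.  FSH, estradiol and progesterone magnitudes
are smooth implementer-chosen values.

## Phase-plane descriptors

A trajectory is the ordered day-labelled polyline of one hormone pair,
closed by default from day +13 back to day −14 (the cycle is periodic).
`count_self_intersections` counts transverse interior crossings between
non-adjacent segments using an orientation predicate with a 1e-9 relative
tolerance; collinear overlapping pairs count once; shared endpoints of
adjacent segments never count.  `signed_loop_area` is the shoelace sum
(positive counter-clockwise).  A trajectory is `degenerate` when every
point lies within 1e-9 of the coordinate range from a single line,
`crossed_loop` when it self-intersects at least once, `open_loop`
otherwise.  Hormone data are in general position, so the tolerance choice
is not load-bearing in practice.

## Calibration

`calibration_loss` simulates 120 days from the packaged initial state
(early follicular, just after luteolysis), builds the event table of the
last fully covered cycle (the transient is discarded), and returns a
weighted sum of squared relative errors over seven anchors: period 28 d,
surge ratio 5.87, post-surge retention 36.22%, progesterone peak day +7,
luteal LH minimum day +11, mode switches at days −1 and +10.  Day-valued
errors are expressed in days and divided by the 28-day period.  Parameter
sets that never complete a cycle are charged a fixed penalty per target
so the loss stays finite for the search.  `calibrate` runs Nelder–Mead on
the log of eight free parameters spanning surge height (`g_high`,
`sigma_LH`), surge decay (`beta_R`), PgR induction delay (`alpha_PgR`,
tied across pools), switch timing (`theta_on`, `theta_off`, `tau_on`) and
luteolysis speed (`mu_L`), with seeded restarts around the incumbent
until the evaluation budget is spent; it never returns a worse point than
its input.  The shipped defaults were produced by a longer offline search
of the same loss augmented with the scenario and shape properties, then
frozen.

With the shipped defaults the limit cycle reproduces period 28 d, the
switch days −1/+10, the luteal LH minimum at +11, the surge ratio and
retention to within ~1%, and the receptor retention band.  The simulated
progesterone peak sits at day +5 rather than +7: corpus-luteum activity
in this model only decays after ovulation, so progesterone (a low-pass
filter of `L`) peaks structurally early; the +7 anchor is carried by the
reference fixture.  Calibrating the peak later would require a luteal
compartment that grows before it regresses, which the model deliberately
omits.

## Scenario presets

* `menopause` — gonadal secretion off (`e_F = e_L = p_L = 0`).  With no
  estrogen to sense, the hypothalamus stays LOW, receptors accumulate to
  their LOW fixed point, and LH settles *above* the cycling follicular
  median (which is held down by receptor cycling and the luteal
  progesterone tail).
* `gnrh_agonist` — drive locked at `g_agonist` (overexposure), switch
  disabled.  LH spikes transiently, then receptor downregulation drives
  it below the follicular level: reversible pharmacologic hypogonadism.
* `pg_low` / `pg_high` — constant exogenous progesterone infusion (1 and
  12 nmol/L/day).  The high dose suppresses ovulation; the low dose does
  not, because without prior estrogen action pituitary PgRs are scarce
  and the low progesterone signal is simply not seen.  The infusion
  magnitudes are packaged constants chosen during calibration.

## Synthetic replicates

`add_noise` draws per-value multiplicative lognormal noise with the
median pinned to the reference value and a chosen coefficient of
variation (hormone concentrations are positive and right-skewed).  The
generator emulates assay and biological scatter around a fixed template;
it does not emulate day-label jitter, cycle-length variability between
women, pulsatility within a day, or missing samples — so tests passing
on these replicates show robustness of the *descriptors and event
arithmetic* to amplitude noise, not applicability to arbitrary real
cohorts.

## Known limitations

* Single dominant follicle per cycle; no multiple ovulation, no
  pregnancy, no pulsatile (minute-scale) GnRH dynamics.
* Inhibins, activin, kisspeptin and leptin are not state variables; their
  roles are folded into effective constants.
* The luteal compartment cannot grow, hence the early simulated
  progesterone peak (see Calibration).
* The event table's mode-switch days use the sampled day containing the
  switch; sub-day timing is available in the event list.
* Calibration is a local search; it recovers ±20% perturbations of the
  free subset but is not a global identifiability analysis.
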