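# Methods

This note documents the models behind `ngra`, the defaults that matter,
the numerical choices, and what the packaged tests do and do not
demonstrate.

## Bioactivity indicators (tier 1)

An indicator is the **arithmetic mean AC50 (µM)** of all active,
quality-ok assays a chemical has within one tissue or gene category.
Records flagged `insufficient`/`inconsistent` and inactive records are
excluded; a (chemical, category) pair with no qualifying assay produces no
indicator (a blank cell, never zero). Averaging on the µM scale is a
deliberate screening simplification: it weights insensitive assays more
than a geometric mean would, which is conservative for a potency
indicator. A geometric mean is available (`mean="geometric"`) because the
averaging scale is a genuinely open choice — the packaged category means
cannot adjudicate it without the underlying assay rows. Duplicate
(chemical, assay) rows are kept and averaged.

## Relative potency and the mode-of-action decision (tier 2)

Within a category, `rp(chemical) = min(values) / value(chemical)`;
"most potent" is the smallest value for AC50, ADI and NOAEL alike, ties
share rp = 1.0, and chemicals without a value carry zero potency on charts
while staying blank in tables. Reported tables round half-away-from-zero
to two decimals; internal math is never rounded.

The concordance between two potency patterns is summarized by the Pearson
correlation over shared (category, chemical) pairs (Spearman available)
and the fraction of pairs whose rp ratio lies within f-fold (default
f = 3). The common-mode-of-action call — originally a visual judgement of
equipotency scatter — is made operational as: *common* iff r ≥ 0.8 **and**
fraction-within-3-fold ≥ 0.8. Both thresholds are configurable; on the
packaged pyrethroid tables the decision is rejection (the acceptance
report prints the statistics), and identical tables are accepted, so the
rule brackets the intended behaviour. Bioactivity tissues are paired with
reference endpoints by an explicit mapping (brain ↔ repeated-dose
neurotoxicity NOAEL, kidney/liver/lung ↔ long-term NOAELs, skin ↔
short-term NOAEL); non-organ categories can be mapped to the peripheral
endpoint in the CLI but only the bijective organ pairs enter the
headline concordance statistics.

## Whole-body PBPK model (tiers 3–4)

A deliberately transparent, perfusion-limited model, not a re-implementation
of any particular commercial engine:

* **Structure** — gut lumen → (first-order absorption) → portal/liver;
  venous and arterial blood with the lung in series; nine perfusion-limited
  organs (liver, gut, kidney, brain, lung, skin, adipose, muscle, rest).
  Each organ is one ODE state; interstitial and intracellular
  concentrations are derived algebraically from the free-drug hypothesis:
  `C_interstitial = fu · C_plasma,local` and
  `C_intracellular = Kp_cell · fu · C_plasma,local`.
* **Partitioning** — `Kp_cell = f_lipid · 10^(a·logP) + (1 − f_lipid)`
  with membrane-affinity slope `a = 0.85`. The slope discounts octanol
  lipophilicity for membrane sorption of very hydrophobic solutes; with
  the packaged logP values (5.5–6.24) it yields Kp_cell of roughly
  10²–10⁵ across lean and fatty tissues, reproducing the qualitative
  pattern intracellular ≫ interstitial expected for pyrethroids.
* **Absorption** — `ka = P_int · SA_eff / V_lumen` with effective smooth
  surface area 250 cm² and 1 L lumen volume, giving ka ≈ 0.1–0.4 h⁻¹ for
  the packaged permeabilities (peak absorption a few hours post-dose,
  consistent with observed human pyrethroid kinetics). A first-order
  transit loss (0.04 h⁻¹) routes unabsorbed chemical to a faecal sink so
  the global balance closes. Dissolution kinetics are not modelled; water
  solubility is carried as metadata only.
* **Elimination** — hepatic Michaelis–Menten on the free liver
  concentration with `Vmax = kcat × hepatic enzyme capacity` (default
  capacity 10 µmol, within the range of total human hepatic P450/esterase
  content) and Km in µM from the parameter table. Chemicals without a
  turnover number (bifenthrin, λ-cyhalothrin) fall back to a linear
  intrinsic clearance (default 100 L/h, mid-range for carboxylesterase-
  mediated pyrethroid hydrolysis). Renal filtration removes
  `GFR · fu · C_kidney` (GFR surrogate 7 L/h) into a urine sink.
* **Physiology** — 73-kg adult male; organ volumes/flows from standard
  reference-man compilations; sub-compartment volume fractions validated
  to sum to 1 (±1e-9). A `body_weight` override rescales volumes and
  flows linearly. An optional population mode perturbs flows and volumes
  log-normally (n = 139 by default) with a fixed seed.
* **Numerics** — LSODA, rtol 1e-8, atol 1e-12 µmol, integrated interval
  by interval with instantaneous dose additions; Cmax/Cmin/AUC are
  extracted over the final dosing interval (241-point grid; trapezoidal
  AUC). Negative amounts beyond a small tolerance abort with a solver
  error; tiny round-off undershoots are clipped. Mass balance
  (body burden + metabolized + urine + faeces = administered) holds to
  ~1e-12 relative in practice and is asserted at ≤ 0.1 %.
* **Verification** — a degenerate configuration (one watery organ with
  near-infinite perfusion, bolus input, linear clearance) matches
  `C(t) = (D/V)·e^(−kt)` to < 0.5 % relative error; Cmax is dose-linear to
  < 1 % far below Km; at periodic steady state the absorbed amount per
  interval equals `CLint·fu·AUC_liver + GFR·fu·AUC_kidney` within 2 %
  (checked with a fast-equilibrating test chemical — the pyrethroids
  themselves are still accumulating into adipose at day 90, which is
  physiological, not an artefact).

The packaged external-engine Cmax table (NOAEL simulations from a
different, proprietary distribution model) is used only for log-ratio
diagnostics. The two engines differ in distribution detail, so numeric
equality is neither expected nor asserted.

### Urine back-calculation

The tier-3 validation converts the simulated daily absorbed deltamethrin
(µmol/d over the final interval) into a urinary metabolite concentration:
`daily amount × molar yield × MW(DBCA) / urine volume`, with
MW(DBCA) = 297.97 g/mol, molar yield 0.5 (urinary DBCA recovery of the
absorbed ester in humans is of this order), and 1.5 L/d urine. The result
is compared against the 1.25–3.34 µg/L human-biomonitoring band as a
*reported* consistency check — the generic operation also supports basing
the conversion on the renally excreted or metabolized parent stream.

## In-vitro disposition (tier 4 refinement)

A linear equilibrium mass balance distributes `C_nom · V_total` over six
phases: aqueous medium, serum protein, medium lipid, cell water, cell
protein and cell membrane lipid. Protein phases bind with
`10^log_d_bsa_w`, lipid phases with `10^log_d_lip_w` (both at pH 7.4,
37 °C; pH and temperature enter only through these coefficients — no
internal speciation). The serum-protein phase volume is albumin mass over
a 1360 g/L protein density; lipid density is 1000 g/L. Defaults describe
a reporter-gene assay well (40 µL medium, 10 % serum with 23 g/L albumin,
5000 cells of 2 pL, 5 % cell lipid, 20 % cell protein). Outputs are
C_free, C_cell, C_mem and exact per-phase mass fractions; the model is
kinetic-free (equilibrium only) and ignores volatilization and plastic
binding.

Chemicals without direct partition-coefficient predictions get them by
extrapolation from logP. The default calibration uses the standard
single-parameter hydrophobicity regressions for neutral organics
(liposome–water `1.01·logP + 0.12`; BSA–water `0.71·logP + 0.42`); a
least-squares calibration from any user-supplied reference table is
supported and preferred when direct values exist.

IVIVE classification labels each (chemical, tissue) pair by the smallest
fold band (10×, 100×, beyond) containing the in-vitro/in-vivo ratio; the
bands are nested by construction. On the packaged comparison tables the
two rapidly cleared pyrethroids (deltamethrin, λ-cyhalothrin) have the
majority of their free-vs-interstitial pairs within 10-fold of equipotency
(per-chemical geometric-mean ratio inside [0.1, 10]), while the other four
cluster 10–100-fold below the in-vivo levels — the packaged tests assert
exactly this clustering rather than an every-pair statement, because the
printed values themselves contain individual pairs just outside their
group's band (e.g. deltamethrin kidney at ratio 10.2).

## Risk characterization (tiers 3 and 5)

`MoE = PoD / Cmax`, with half-open concern bins — a value exactly on a
boundary belongs to the upper (less concerning) bin, resolving the strict
inequalities that leave boundary points undefined. Screening bins:
<100, 100–1000, 1000–100,000, >100,000; refined bins: <1, 1–10, 10–100,
>100; both carry the red/orange/yellow/green colour code and are fully
configurable. Missing AC50s or NOAELs produce flagged absent cells
(asterisked in the published tables), never zeros.

Tissue categories map to PBPK organs (brain, kidney, liver, lung, skin,
intestine→gut); systemic in-vitro categories (vascular, immune, breast,
ovary, pancreas, prostate) read the plasma Cmax for both compartments,
as the peripheral concentration stands in for them in the case study.
The tier-5 pairing — refined C_free against interstitial Cmax, refined
C_cell against intracellular Cmax — follows the axes of the published
comparisons and is exposed as configuration.

The mixture total is `MOET = 1 / Σ(1/MoE)`. The source's combined-MoE
formula as printed ("1/(1/Σ(1/MoE))") algebraically collapses to the bare
reciprocal sum, which would violate the single-element identity
(MOET of {50} must be 50); the reciprocal-of-reciprocal-sum form is the
standard definition and is what is implemented. MOET is permutation-
invariant, never exceeds the smallest contributing MoE, and adding a
mixture member can only lower it — all property-tested.

## Synthetic data

The assay generator draws AC50s multiplicatively log-normally around
per-(chemical, category) true means with `mean · exp(σZ − σ²/2)`, so the
arithmetic mean is an unbiased estimator of the truth; a fixed fraction
of records is inactive. Defaults (10 assays/category, σ = 0.5, 10 %
inactive) emulate the scatter of curated high-throughput exports; the
recovery study uses 200 assays/category over 100 seeds and requires 99 %
of category means within three standard errors. What the generator does
*not* emulate: assay-specific bias, censoring at tested-concentration
limits, correlated errors across assays of one platform, and
concentration–response refitting — so passing recovery tests demonstrate
estimator correctness, not robustness to real ToxCast artefacts. The
chemical generator samples uniformly (log-uniformly for solubility,
permeability and dose) inside the spans of the packaged parameter table.

## Fixture conventions

The packaged tables preserve blanks as missing values and are guarded by
SHA-256 checksums. Two transcription conventions matter: partial category
rows whose chemical assignment is not constrained by any other table
assign values to chemicals in column order starting at bifenthrin (this
affects only labels, never a computed statistic); and the gene table's
neuroreceptor row carries five means while its printed potency row has
four values — the fifth computed rp (0.0045, i.e. 0.00 at two decimals)
stays blank in the potency fixture as printed, and regeneration tests
compare printed cells only.

## Problem sizes and runtimes

Default test and acceptance runs use the full 90-day, q24h regimens for
all six chemicals (plus up to three NOAEL doses each), 1,000 random MoE
vectors for the MOET oracle, and the 100-seed × 200-assay recovery study;
the whole acceptance script completes in well under a minute on one CPU.
Engine property checks use 7–14-day regimens of synthetic chemicals, which
is sufficient because the properties tested (linearity, conservation,
closed-form equivalence) are regime-independent.

## Known limitations

* The PBPK model has no enterohepatic recirculation, no dermal or
  inhalation routes, no metabolite kinetics (the urinary metabolite is a
  molar conversion), and no dissolution-limited absorption.
* Interstitial binding is ignored (interstitium treated as plasma water
  at fu·Cp), which understates interstitial totals for highly bound
  chemicals.
* The disposition model's defaults describe a generic reporter-gene well;
  the published comparison table's own assay geometry is not printed, so
  that table is used for structural joins and qualitative grouping, not
  as an equality oracle.
* MoEs are deterministic point estimates; no population or probabilistic
  risk characterization beyond the optional PBPK population mode.
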