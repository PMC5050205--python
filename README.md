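# mfa2s — two-scale ¹³C metabolic flux analysis

`mfa2s` estimates intracellular metabolic fluxes in compartmentalized microbes
(the shipped fixtures model *Saccharomyces cerevisiae* central carbon
metabolism) by combining genome-scale stoichiometry with ¹³C labeling data at
two resolutions:

* **everywhere** — steady-state mass balance `S·v = 0` and flux bounds
  constrain the full network;
* **on a core subnetwork** — curated carbon-atom transition maps let the
  package simulate the steady-state mass distribution vectors (MDVs) of core
  metabolites, so measured amino-acid labeling constrains the core fluxes
  directly.

This is the resolution a metabolic engineer needs to answer questions like
"where does cytosolic acetyl-CoA come from and where does it go after I add a
heterologous ATP citrate lyase?" — with honest uncertainty on every flux.

## Model and estimator

Labeling is simulated with the elementary-metabolite-unit (EMU) decomposition:
linear balance systems per EMU size, condensation reactions as convolutions,
reversible reactions as forward/backward flux pairs, and 0.5/0.5 scrambling
for symmetric metabolites (succinate, fumarate).  A brute-force positional
isotopomer solver validates the EMU path on small networks.

Fluxes are estimated by minimizing the weighted sum of squared residuals

    SSR(v) = Σ_channels ((m_sim(v) − m_meas)/σ)² + Σ_exchange ((v_j − r_j)/σ_j)²

over null-space coordinates of the steady-state constraints (so `S·v = 0`
holds exactly), with analytic gradients through the EMU systems and a seeded
multistart of a local SQP solver.  Confidence intervals come from ¹³C flux
variability analysis: each net flux is minimized/maximized subject to
`SSR(v) ≤ SSR_opt + χ²(α, 1)`, reported as `best [lo–hi]` (e.g.
`0.5 [0.3–0.66]`).  External labeling variability analysis (ELVA) bounds how
much unmapped (non-core) carbon influx could distort each measured fragment,
validating the core-set choice.  Balance reports tabulate the producers and
consumers of any metabolite (cytosolic acetyl-CoA by default) with intervals —
the numbers behind a sankey diagram.

Measured inputs are amino-acid MDVs (12 amino acids measured intact: Gly, Ala,
Val, Thr, Leu, Ile, Asp, Glu, Gln, Arg, Phe, Tyr, tied to cytosolic precursor
pools through curated recipes), exchange fluxes (from tables or from
OD₆₀₀/concentration timecourses via 0.835 gDW/L per OD unit), and the growth
rate.  Because no public labeling dataset ships with the package, a
first-class synthetic generator produces study-shaped inputs: a ~50-reaction
compartmentalized toy yeast network (six strain variants toggling ATP citrate
lyase, malate-synthase downregulation, and the GPD1 knockout), ground-truth
fluxes sampled from the flux polytope at 3 mmol/gDW/h glucose uptake, the
80%/20% [1-¹³C]/[U-¹³C] glucose feed, and Gaussian measurement noise.

## Worked example

Generate a synthetic strain carrying ATP citrate lyase, then run the full
workflow (fit → FVA → ELVA → balance):

```sh
mfa2s synth --variant WRY2_ACL --seed 2 --noise-sd 0.01 --out fixture
mfa2s pipeline --config fixture/config.yaml --out run
```

The log reports the fit and the acetyl-CoA bookkeeping:

```
INFO mfa2s: fitting with 10 starts, seed 2
INFO mfa2s: SSR 65.2978 over 81 residuals (converged=True)
INFO mfa2s: wrote 39 intervals at alpha=0.95
INFO mfa2s: ELVA verdict: pass (threshold 0.01)
INFO mfa2s: accoa_c: 2.4360 produced vs 2.4360 consumed (mmol/gDW/h)
```

An SSR of 65.3 over 81 residuals is what a correctly specified model should
give (the χ² band for this fit is roughly 49–95), the ELVA pass says the core
set is large enough that unmapped carbon cannot move any measured MDV channel
by more than 0.01, and `run/balance_accoa_c.md` holds the balance table:

```
| side      | reaction | flux [CI]          |
|-----------|----------|--------------------|
| consuming | ACCOACr  | 2.11 [1.48–2.68]   |
| producing | ACL      | 1.22 [0.0871–2.98] |
| producing | ACS      | 1.21 [0–2.74]      |
| consuming | BIOMASS  | 0.17               |
| consuming | MALS     | 0.156 [0.116–0.297]|
| |  **total** | 2.44 produced, 2.44 consumed |
```

Read it as: at the best fit, cytosolic acetyl-CoA is made roughly half-and-half
by acetyl-CoA synthetase (ACS) and the added citrate lyase (ACL), and most of
it is committed to fatty-acid synthesis through acetyl-CoA carboxylase
(ACCOACr); the wide `[0–2.74]` interval on ACS warns that the labeling data
alone cannot pin down the ACS/ACL split — exactly the kind of caution the
intervals exist to provide.  Production and consumption agree to machine
precision because the estimate satisfies steady state by construction.

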