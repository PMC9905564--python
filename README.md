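# reefbudget-panama

Census-based carbonate budgets and reef-accretion potential (RAP) for the
coral reefs of Pacific Panamá — the strongly upwelling Gulf of Panamá (GoP)
and the weakly upwelling Gulf of Chiriquí (GoC) — with coral-cover
thresholds for keeping up with sea-level rise under localized RCP
scenarios.

The package is aimed at reef ecologists and carbonate-budget modellers. It
takes point-intercept benthic surveys (100 points per 25-m transect),
buoyant-weight coral out-plant time series, sea-urchin and fish
belt-transect densities, reef-core compaction summaries, and a monthly
tide-gauge record, and produces per-transect budgets, gulf summaries, and
threshold/keep-up reports. A first-class synthetic-data generator emulates
all of these inputs with known ground truth, so the entire pipeline is
testable without field data.

## The model

Gross carbonate production per transect (kg CaCO₃ m⁻² yr⁻¹, planar) is the
cover-weighted sum of taxon calcification rates: `G_gross = Σ_taxa cover ×
rate(g cm⁻² yr⁻¹) × 10`. *Pocillopora* rates come from hydrostatic
weighing: dry skeletal weight `W_d = W_b / (1 − ρ_sw/ρ_ar)`, and the
calcification rate over a growth interval is `ΔW_d / mean area / Δt`.

Bioerosion has five components, each a positive magnitude:

- macroborers: `MB = L·ml_g + T·mt_g + D·md_g` (L, T, D = live-coral,
  thick-turf, dead-substrate cover; rates gulf-specific);
- microborers: a flat Indo-Pacific constant, 0.233 kg m⁻² yr⁻¹;
- boring sponges: `SB = (L·0.46 + RC·0.46 + FC·0.56) × 0.85` (infestation
  prevalences × chemical dissolution rate);
- sea urchins: `UB = (L·ul_g + D·ud_g + T·ut_g) × U × 365/1000` with U in
  ind m⁻²;
- parrotfish and corallivorous pufferfish from density × per-capita
  ReefBudget-style rates.

Net production is `G = gross − ΣTB`. Accretion potential converts mass to
vertical growth through a porosity-corrected framework density
`ρ_x = C_x·D_f + (1 − C_x)·D_w` (core compaction `C_x`, skeletal density
`D_f` = 1.84 g cm⁻³, seawater `D_w`):

```
RAP [mm yr⁻¹] = G/ρ_x + S
```

with S a per-site sediment contribution. The millennial-scale variant uses
`ρ = D_f` (porosity excluded). Cover thresholds come from affine models
`response ~ cover% + gulf` (site random intercepts), inverted at a target
rate; global RCP rates (4/7/15 mm yr⁻¹) are localized by the ratio of the
tide-gauge trend to the global observed trend.

## Worked example

```
reefbudget synth --seed 1 --out fixtures
reefbudget run --survey fixtures/survey.csv --grazers fixtures/grazers.csv \
    --cores fixtures/cores.csv --tide fixtures/tide.txt --out results
```

prints the gulf summary of the synthetic study (3 sites × 6 transects × 5
surveys per gulf):

```
gulf  coral_cover_pct      gross  total_bioerosion       net       rap  millennial_rap  macroborer_share
 GoC        45.200000   9.396222          7.633045  1.763177  1.553884        1.358249          0.864749
 GoP        77.611111  17.281311          9.628597  7.652714  5.489275        4.559084          0.881114
```

The GoP column reads: 78% mean coral cover produces 17.3 kg CaCO₃ m⁻² yr⁻¹
gross, loses 9.6 to bioerosion (88% of it from macroborers), leaving a net
budget of 7.7 kg m⁻² yr⁻¹ and an accretion potential of 5.5 mm yr⁻¹ —
enough to keep up with a localized RCP 2.6 rise (≈3.4 mm yr⁻¹) but not
RCP 8.5. The GoC, at 45% cover, nets only 1.8 kg m⁻² yr⁻¹ (RAP 1.6
mm yr⁻¹). `results/thresholds.csv` holds the per-scenario required-cover
table and keep-up verdicts;
`reefbudget thresholds --budget results/budget.csv --scenarios rcp26,rcp45,rcp85`
recomputes it for chosen scenarios.

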