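# Shared breed parameters and feed compositions for the scenario library.
#
# Feed qualities and all prices are fixture assumptions calibrated to keep
# baseline scenarios in the reported band for each region; they are NOT
# survey-reported values. Plausible ranges and the calibration rationale are
# documented in docs/methods.md. Prices are per kg fresh weight, in the
# currency of the scenarios that use the feed (ETB for Ethiopian feeds,
# INR for Indian feeds). cp_monthly, where given, is the seasonal crude
# protein cycle (fraction of DM, Jan..Dec).

breeds:
  zebu:
    mature_weight: 350.0
    birth_weight: 22.0
    potential_peak_milk: 3.0
    lactation_length: 6
    milk_fat: 0.05
    age_first_mating: 36
    growth_rate_potential: 0.25
  crossbred_ethiopia:
    mature_weight: 420.0
    birth_weight: 28.0
    potential_peak_milk: 8.0
    lactation_length: 9
    milk_fat: 0.04
    age_first_mating: 24
    growth_rate_potential: 0.45
  local_india:
    mature_weight: 350.0
    birth_weight: 22.0
    potential_peak_milk: 3.5
    lactation_length: 6
    milk_fat: 0.045
    age_first_mating: 36
    growth_rate_potential: 0.25
  crossbred_india:
    mature_weight: 500.0
    birth_weight: 30.0
    potential_peak_milk: 9.0
    lactation_length: 9
    milk_fat: 0.04
    age_first_mating: 30
    growth_rate_potential: 0.5
  buffalo:
    mature_weight: 450.0
    birth_weight: 30.0
    potential_peak_milk: 7.0
    lactation_length: 9
    milk_fat: 0.07
    age_first_mating: 36
    growth_rate_potential: 0.4

feeds:
  # --- Ethiopia ---
  lowland_pasture:          # grazed natural pasture, pastoral lowlands
    dm_fraction: 0.35
    me_density: 7.6
    cp_fraction: 0.053
    cp_monthly: [0.035, 0.030, 0.030, 0.035, 0.045, 0.070, 0.080, 0.080, 0.070, 0.055, 0.045, 0.040]
    price: 0.0
    purchasable: false
    storable: false
  highland_pasture:         # grazed natural grasses, highland mixed systems
    dm_fraction: 0.30
    me_density: 8.2
    cp_fraction: 0.10
    cp_monthly: [0.070, 0.065, 0.070, 0.080, 0.100, 0.120, 0.130, 0.130, 0.120, 0.100, 0.085, 0.075]
    price: 0.0
    purchasable: false
    storable: false
  cereal_straw:             # teff/wheat straw, Ethiopia
    dm_fraction: 0.90
    me_density: 6.5
    cp_fraction: 0.04
    price: 1.5
    purchasable: true
    storable: true
  legume_hay:
    dm_fraction: 0.88
    me_density: 8.5
    cp_fraction: 0.16
    price: 3.0
    purchasable: true
    storable: true
  noug_cake:                # oilseed by-product concentrate
    dm_fraction: 0.92
    me_density: 11.0
    cp_fraction: 0.30
    price: 4.0
    purchasable: true
    storable: true
  wheat_bran:
    dm_fraction: 0.89
    me_density: 11.5
    cp_fraction: 0.15
    price: 3.0
    purchasable: true
    storable: true
  lablab_forage:            # Lablab purpureus green forage, cut and carry
    dm_fraction: 0.25
    me_density: 9.0
    cp_fraction: 0.17
    price: 0.0
    purchasable: false
    storable: false

  # --- India ---
  native_grass:             # grazed native grass
    dm_fraction: 0.30
    me_density: 7.5
    cp_fraction: 0.07
    cp_monthly: [0.050, 0.045, 0.045, 0.050, 0.060, 0.080, 0.100, 0.100, 0.090, 0.070, 0.060, 0.050]
    price: 0.0
    purchasable: false
    storable: false
  crop_residue:             # maize/sorghum/wheat residues, rainfed zone
    dm_fraction: 0.90
    me_density: 6.8
    cp_fraction: 0.05
    price: 4.0
    purchasable: true
    storable: true
  cereal_straw_india:       # rice/wheat straw, irrigated zone (5 INR/kg)
    dm_fraction: 0.90
    me_density: 6.3
    cp_fraction: 0.045
    price: 5.0
    purchasable: true
    storable: true
  wheat_bran_india:
    dm_fraction: 0.89
    me_density: 11.5
    cp_fraction: 0.15
    price: 12.0
    purchasable: true
    storable: true
  rice_bran:
    dm_fraction: 0.90
    me_density: 11.0
    cp_fraction: 0.13
    price: 10.0
    purchasable: true
    storable: true
  green_grass:              # purchased good-quality green grass
    dm_fraction: 0.25
    me_density: 9.5
    cp_fraction: 0.14
    price: 2.0
    purchasable: true
    storable: false
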