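# Ethiopia lowland grazing (LG) pastoral zone: extensive grazing, no cropping
# land, Zebu cattle on natural pasture, cows supplemented with 0.4 kg noug
# cake/head/day, male offspring sold at 12 months / 180 kg.
region: ethiopia_lg
currency: ETB
milk_price: 15.0
health_mating_cost: 200.0
animal_prices:
  cull_breeder: 7000.0
  heifer: 5000.0
  female_calf: 1000.0
  male_calf: 1000.0
  growing_male: 7000.0

baseline:
  breed: zebu
  min_breeders: 15
  max_breeders: 30
  male_sale_age: 12
  male_sale_weight: 180.0
  cull_age: 132
  base_mortality: 0.05
  feeds:
    lowland_pasture:
      # communal grazing accessible to this household, kg fresh per month
      supply: [6000, 5500, 5500, 6000, 6500, 8500, 9500, 9500, 8500, 7500, 7000, 6500]
    noug_cake:
      supply: 0.0
  ration:
    breeder: {lowland_pasture: 25.0, noug_cake: 0.4}
    heifer: {lowland_pasture: 18.0}
    female_calf: {lowland_pasture: 6.0}
    male_calf: {lowland_pasture: 6.0}
    growing_male: {lowland_pasture: 18.0}

interventions:
  - name: improved_pasture
    kind: improved_pasture
    params:
      feed: lowland_pasture
      delta_n: 0.005     # +0.5% nitrogen from legume reseeding; CP = 6.25 x N
      min_breeders: 15
      max_breeders: 20
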