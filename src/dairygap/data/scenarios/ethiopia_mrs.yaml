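# Ethiopia highland mixed crop-livestock, rainfall-sufficient (MRS) zone:
# urban dairy production with no cropping or grazing land — all fodder
# purchased. Cows fed cereal straw, legume hay and 0.4 kg noug cake/head/day.
# Male offspring sold at 1 month.
region: ethiopia_mrs
currency: ETB
milk_price: 15.0
health_mating_cost: 200.0
animal_prices:
  cull_breeder: 7000.0
  heifer: 5000.0
  female_calf: 1000.0
  male_calf: 800.0
  growing_male: 4000.0

baseline:
  breed: zebu
  min_breeders: 3
  max_breeders: 4
  male_sale_age: 1
  male_sale_weight: 0.0
  cull_age: 132
  base_mortality: 0.10
  feeds:
    cereal_straw:
      supply: 0.0        # no land: everything purchased
    legume_hay:
      supply: 0.0
    noug_cake:
      supply: 0.0
    wheat_bran:
      supply: 0.0
  ration:
    breeder: {cereal_straw: 6.0, legume_hay: 0.3, noug_cake: 0.4}
    heifer: {cereal_straw: 3.0, legume_hay: 0.3}
    female_calf: {cereal_straw: 1.0, legume_hay: 0.5}
    male_calf: {cereal_straw: 1.0, legume_hay: 0.3}
    growing_male: {cereal_straw: 2.0}

interventions:
  - name: improved_forage
    kind: improved_forage
    params:
      # N content of the cereal straw increased with urea treatment
      feed_updates:
        cereal_straw: {cp_fraction: 0.09}
  - name: concentrate
    kind: concentrate
    params:
      offers: {noug_cake: 0.8, wheat_bran: 0.8}
  - name: improved_genetics
    kind: improved_genetics
    params:
      breed: crossbred_ethiopia
      min_breeders: 4
      max_breeders: 5
      offers: {noug_cake: 0.8, cereal_straw: 7.0, legume_hay: 0.5}
  - name: improved_genetics_improved_forage
    kind: combination
    parts:
      - name: genetics
        kind: improved_genetics
        params:
          breed: crossbred_ethiopia
          min_breeders: 4
          max_breeders: 5
          offers: {noug_cake: 1.0, cereal_straw: 7.0, legume_hay: 0.5}
      - name: forage
        kind: improved_forage
        params:
          feed_updates:
            cereal_straw: {cp_fraction: 0.09}
  - name: improved_genetics_concentrate
    kind: combination
    parts:
      - name: genetics
        kind: improved_genetics
        params:
          breed: crossbred_ethiopia
          min_breeders: 4
          max_breeders: 5
          offers: {cereal_straw: 7.0, legume_hay: 0.5}
      - name: concentrate
        kind: concentrate
        params:
          offers: {noug_cake: 1.6, wheat_bran: 1.6}
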