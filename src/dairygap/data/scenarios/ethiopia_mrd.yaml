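# Ethiopia highland mixed crop-livestock, rainfall-deficient (MRD) zone:
# grazing of natural grasses from 0.8 ha, cereal straw from 1 ha cropping
# land fed as required, cows supplemented with 0.4 kg noug cake/head/day and
# purchased legume hay as required. Male offspring sold at 1 month.
region: ethiopia_mrd
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
  max_breeders: 5
  male_sale_age: 1
  male_sale_weight: 0.0
  cull_age: 132
  base_mortality: 0.10
  feeds:
    highland_pasture:
      # 0.8 ha natural grass plus limited communal access, kg fresh per month
      supply: [450, 400, 400, 500, 650, 900, 1200, 1200, 1000, 750, 600, 500]
    cereal_straw:
      # own 1 ha cereal crop, residues stockpiled at the two harvests
      supply: [0, 1100, 0, 0, 0, 0, 0, 0, 0, 0, 1100, 0]
    legume_hay:
      supply: 0.0
    noug_cake:
      supply: 0.0
    wheat_bran:
      supply: 0.0
    lablab_forage:
      supply: 0.0
  ration:
    breeder: {highland_pasture: 15.0, cereal_straw: 3.0, legume_hay: 0.5, noug_cake: 0.4}
    heifer: {highland_pasture: 10.0, cereal_straw: 2.0}
    female_calf: {highland_pasture: 4.0, legume_hay: 0.3}
    male_calf: {highland_pasture: 4.0}
    growing_male: {highland_pasture: 8.0, cereal_straw: 1.0}

interventions:
  - name: concentrate
    kind: concentrate
    params:
      offers: {noug_cake: 0.8, wheat_bran: 0.8}
  - name: improved_forage
    kind: improved_forage
    params:
      # 0.5 ha of the natural pasture replaced with Lablab purpureus
      scale_supply: {highland_pasture: 0.375}
      feed_updates:
        lablab_forage:
          monthly_supply: [1050, 900, 900, 1200, 1550, 2400, 3100, 3100, 2600, 1900, 1400, 1200]
      offers: {lablab_forage: 13.0}
  - name: improved_genetics
    kind: improved_genetics
    params:
      breed: crossbred_ethiopia
      min_breeders: 4
      max_breeders: 8
      offers: {noug_cake: 0.8, cereal_straw: 5.0, legume_hay: 1.5, highland_pasture: 18.0}
      class_offers:
        heifer: {cereal_straw: 2.5, legume_hay: 1.0}
  - name: improved_genetics_improved_forage
    kind: combination
    parts:
      - name: genetics
        kind: improved_genetics
        params:
          breed: crossbred_ethiopia
          min_breeders: 4
          max_breeders: 6
          offers: {cereal_straw: 5.0, legume_hay: 2.0, highland_pasture: 18.0}
          class_offers:
            heifer: {cereal_straw: 2.5, legume_hay: 1.0}
      - name: forage
        kind: improved_forage
        params:
          # 0.7 ha of the natural pasture replaced with Lablab purpureus
          scale_supply: {highland_pasture: 0.125}
          feed_updates:
            lablab_forage:
              monthly_supply: [1260, 1050, 1050, 1470, 1890, 2940, 3780, 3780, 3150, 2310, 1680, 1470]
          offers: {lablab_forage: 14.0}
  - name: improved_genetics_concentrate
    kind: combination
    parts:
      - name: genetics
        kind: improved_genetics
        params:
          breed: crossbred_ethiopia
          min_breeders: 3
          max_breeders: 6
          offers: {cereal_straw: 5.0, legume_hay: 2.0, highland_pasture: 18.0}
          class_offers:
            heifer: {cereal_straw: 2.5, legume_hay: 1.0}
      - name: concentrate
        kind: concentrate
        params:
          offers: {noug_cake: 1.5, wheat_bran: 1.5}
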