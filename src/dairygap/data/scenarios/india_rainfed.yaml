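# India rainfed zone: 1 ha cropping land (maize, sorghum, wheat); local
# cattle graze native grass supplemented with 4 kg crop residues/head/day.
# Male offspring sold at 1 month; male cattle carry no sale value (slaughter
# restrictions), buffalo male calves do. Buffalo milk attracts a higher
# price for its fat content.
region: india_rainfed
currency: INR
milk_price: 28.0
health_mating_cost: 500.0
animal_prices:
  cull_breeder: 15000.0
  heifer: 12000.0
  female_calf: 2000.0
  male_calf: 0.0
  growing_male: 0.0

baseline:
  breed: local_india
  min_breeders: 1
  max_breeders: 3
  male_sale_age: 1
  male_sale_weight: 0.0
  cull_age: 144
  base_mortality: 0.05
  feeds:
    native_grass:
      supply: [500, 450, 450, 500, 600, 900, 1200, 1200, 1000, 800, 650, 550]
    crop_residue:
      # 1 ha maize/sorghum/wheat, residues stockpiled at three harvests
      supply: [0, 0, 1300, 0, 0, 0, 1300, 0, 0, 0, 1400, 0]
    wheat_bran_india:
      supply: 0.0
  ration:
    breeder: {native_grass: 12.0, crop_residue: 4.0}
    heifer: {native_grass: 10.0, crop_residue: 2.0}
    female_calf: {native_grass: 4.0, crop_residue: 0.5}
    male_calf: {native_grass: 4.0}
    growing_male: {native_grass: 8.0}

interventions:
  - name: improved_genetics_buffalo
    kind: improved_genetics
    params:
      breed: buffalo
      offers: {crop_residue: 5.0, native_grass: 20.0}
      class_offers:
        heifer: {crop_residue: 4.0}
        female_calf: {crop_residue: 1.5}
      milk_price: 42.0
      animal_prices: {cull_breeder: 25000.0, heifer: 20000.0, male_calf: 1500.0, growing_male: 3000.0}
  - name: improved_genetics_crossbred
    kind: improved_genetics
    params:
      breed: crossbred_india
      offers: {crop_residue: 6.0, native_grass: 28.0}
      class_offers:
        heifer: {crop_residue: 5.0}
        female_calf: {crop_residue: 1.5}
      animal_prices: {cull_breeder: 25000.0, heifer: 20000.0}
  - name: low_concentrate
    kind: concentrate
    params:
      offers: {wheat_bran_india: 1.0}
  - name: improved_genetics_buffalo_low_concentrate
    kind: combination
    parts:
      - name: buffalo
        kind: improved_genetics
        params:
          breed: buffalo
          offers: {crop_residue: 5.0, native_grass: 20.0}
          class_offers:
            heifer: {crop_residue: 4.0}
            female_calf: {crop_residue: 1.5}
          milk_price: 42.0
          animal_prices: {cull_breeder: 25000.0, heifer: 20000.0, male_calf: 1500.0, growing_male: 3000.0}
      - name: bran
        kind: concentrate
        params:
          offers: {wheat_bran_india: 1.0}
  - name: improved_genetics_crossbred_low_concentrate
    kind: combination
    parts:
      - name: crossbred
        kind: improved_genetics
        params:
          breed: crossbred_india
          offers: {crop_residue: 6.0, native_grass: 28.0}
          class_offers:
            heifer: {crop_residue: 5.0}
            female_calf: {crop_residue: 1.5}
          animal_prices: {cull_breeder: 25000.0, heifer: 20000.0}
      - name: bran
        kind: concentrate
        params:
          offers: {wheat_bran_india: 1.0}
  - name: improved_genetics_buffalo_high_concentrate
    kind: combination
    parts:
      - name: buffalo
        kind: improved_genetics
        params:
          breed: buffalo
          offers: {crop_residue: 5.0, native_grass: 20.0}
          class_offers:
            heifer: {crop_residue: 4.0}
            female_calf: {crop_residue: 1.5}
          milk_price: 42.0
          animal_prices: {cull_breeder: 25000.0, heifer: 20000.0, male_calf: 1500.0, growing_male: 3000.0}
      - name: bran
        kind: concentrate
        params:
          offers: {wheat_bran_india: 3.0}
  - name: improved_genetics_crossbred_high_concentrate
    kind: combination
    parts:
      - name: crossbred
        kind: improved_genetics
        params:
          breed: crossbred_india
          offers: {crop_residue: 6.0, native_grass: 28.0}
          class_offers:
            heifer: {crop_residue: 5.0}
            female_calf: {crop_residue: 1.5}
          animal_prices: {cull_breeder: 25000.0, heifer: 20000.0}
      - name: bran
        kind: concentrate
        params:
          offers: {wheat_bran_india: 3.0}
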