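# India irrigated zone: 0.5 ha cropping land (rice, wheat); buffalo in a cut
# and carry system fed cereal straw and native grass, supplemented with
# 1.5 kg rice bran/head/day. Male offspring sold at 1 month.
region: india_irrigated
currency: INR
milk_price: 42.0          # buffalo milk, higher fat content
health_mating_cost: 500.0
animal_prices:
  cull_breeder: 25000.0
  heifer: 20000.0
  female_calf: 3000.0
  male_calf: 1500.0
  growing_male: 3000.0

baseline:
  breed: buffalo
  min_breeders: 1
  max_breeders: 3
  male_sale_age: 1
  male_sale_weight: 0.0
  cull_age: 156
  base_mortality: 0.05
  feeds:
    cereal_straw_india:
      # 0.5 ha rice + wheat, straw stockpiled at the two harvests
      supply: [0, 0, 0, 1000, 0, 0, 0, 0, 0, 0, 1000, 0]
    native_grass:
      supply: [300, 250, 250, 300, 400, 600, 800, 800, 650, 500, 400, 350]
    rice_bran:
      supply: 0.0
    green_grass:
      supply: 0.0
  ration:
    breeder: {cereal_straw_india: 6.0, native_grass: 8.0, rice_bran: 1.5}
    heifer: {cereal_straw_india: 3.0, native_grass: 5.0}
    female_calf: {native_grass: 3.0, rice_bran: 0.2}
    male_calf: {native_grass: 3.0}
    growing_male: {cereal_straw_india: 2.0, native_grass: 4.0}

interventions:
  - name: improved_forage
    kind: residue_quality
    params:
      # improved straw cultivars: +1 MJ ME/kg DM, price 5 -> 5.8 INR/kg
      feed: cereal_straw_india
      delta_me: 1.0
      price: 5.8
  - name: green_feed
    kind: green_feed
    params:
      offers: {green_grass: 10.0}
  - name: green_feed_bran
    kind: combination
    parts:
      - name: green
        kind: green_feed
        params:
          offers: {green_grass: 8.0}
      - name: bran
        kind: concentrate
        params:
          offers: {rice_bran: 3.0}
  - name: increased_bran
    kind: concentrate
    params:
      offers: {rice_bran: 5.0}
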