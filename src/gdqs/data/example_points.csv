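group_id,role,low,middle,high,very_high
whole_grains,healthy,0,1,2,
refined_grains_baked_goods,unhealthy,2,1,0,
deep_orange_tubers,healthy,0,1,2,
white_roots_tubers,unhealthy,2,1,0,
legumes,healthy,0,1,2,
nuts_seeds,healthy,0,1,2,
fish_shellfish,healthy,0,1,2,
poultry_game_meat,healthy,0,1,2,
red_meat,unhealthy_in_excess,1,2,0,
processed_meat,unhealthy,2,1,0,
eggs,healthy,0,1,2,
high_fat_dairy,unhealthy_in_excess,0,2,1,0
low_fat_dairy,healthy,0,1,2,
deep_orange_fruits,healthy,0,1,2,
citrus_fruits,healthy,0,1,2,
other_fruits,healthy,0,1,2,
dark_green_leafy_vegetables,healthy,0,1,2,
deep_orange_vegetables,healthy,0,1,2,
cruciferous_vegetables,healthy,0,1,2,
other_vegetables,healthy,0,1,2,
liquid_oils,healthy,0,1,2,
juice,unhealthy,2,1,0,
sugar_sweetened_beverages,unhealthy,2,1,0,
sweets_ice_cream,unhealthy,2,1,0,
purchased_deep_fried_foods,unhealthy,2,1,0,
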