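group_id,boundary,cube_index,original_g,operationalized_g
whole_grains,low_middle,2,4,8
whole_grains,middle_high,3,16,13
nuts_seeds,low_middle,2,4,7
nuts_seeds,middle_high,3,16,13
processed_meat,low_middle,2,8,9
processed_meat,middle_high,4,31,30
refined_grains_baked_goods,low_middle,2,7,7
refined_grains_baked_goods,middle_high,5,28,33
eggs,low_middle,2,7,6
eggs,middle_high,5,28,32
deep_orange_vegetables,low_middle,2,10,9
deep_orange_vegetables,middle_high,5,39,45
legumes,low_middle,2,10,9
legumes,middle_high,5,39,42
red_meat,low_middle,2,12,9
red_meat,middle_high,5,48,46
high_fat_dairy_cheese,low_middle,2,35,9
high_fat_dairy_cheese,middle_high,4,140,28
high_fat_dairy_cheese,high_very_high,7,734,114
dark_green_leafy_vegetables,low_middle,3,10,13
dark_green_leafy_vegetables,middle_high,5,39,37
poultry_game_meat,low_middle,3,12,16
poultry_game_meat,middle_high,5,48,44
sweets_ice_cream,low_middle,3,11,13
sweets_ice_cream,middle_high,5,45,37
cruciferous_vegetables,low_middle,3,11,13
cruciferous_vegetables,middle_high,5,44,36
deep_orange_tubers,low_middle,3,14,12
deep_orange_tubers,middle_high,6,57,63
purchased_deep_fried_foods,low_middle,3,10,9
purchased_deep_fried_foods,middle_high,6,40,45
fish_shellfish,low_middle,3,16,14
fish_shellfish,middle_high,6,63,71
citrus_fruits,low_middle,4,18,24
citrus_fruits,middle_high,6,74,69
white_roots_tubers,low_middle,4,25,27
white_roots_tubers,middle_high,7,100,107
juice,low_middle,4,35,36
juice,middle_high,7,141,144
other_fruits,low_middle,4,26,27
other_fruits,middle_high,7,106,107
high_fat_dairy_other,low_middle,4,35,35
high_fat_dairy_other,middle_high,7,140,143
high_fat_dairy_other,high_very_high,9,734,734
low_fat_dairy,low_middle,4,35,33
low_fat_dairy,middle_high,7,139,132
other_vegetables,low_middle,4,26,23
other_vegetables,middle_high,8,106,114
deep_orange_fruits,low_middle,4,28,25
deep_orange_fruits,middle_high,8,114,123
sugar_sweetened_beverages,low_middle,5,52,57
sugar_sweetened_beverages,middle_high,8,207,180
liquid_oils,low_middle,,,
liquid_oils,middle_high,,,
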