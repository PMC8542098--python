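group_id,name,assessment_mode,reporting_group_id
whole_grains,Whole grains,cube,whole_grains
refined_grains_baked_goods,Refined grains and baked goods,cube,refined_grains_baked_goods
deep_orange_tubers,Deep orange tubers,cube,deep_orange_tubers
white_roots_tubers,White roots and tubers,cube,white_roots_tubers
legumes,Legumes,cube,legumes
nuts_seeds,Nuts and seeds,cube,nuts_seeds
fish_shellfish,Fish and shellfish,cube,fish_shellfish
poultry_game_meat,Poultry and game meat,cube,poultry_game_meat
red_meat,Red meat,cube,red_meat
processed_meat,Processed meat,cube,processed_meat
eggs,Eggs,cube,eggs
high_fat_dairy_cheese,High fat dairy: hard cheese,cube,high_fat_dairy
high_fat_dairy_other,High fat dairy: other,cube,high_fat_dairy
low_fat_dairy,Low fat dairy,cube,low_fat_dairy
deep_orange_fruits,Deep orange fruits,cube,deep_orange_fruits
citrus_fruits,Citrus fruits,cube,citrus_fruits
other_fruits,Other fruits,cube,other_fruits
dark_green_leafy_vegetables,Dark green leafy vegetables,cube,dark_green_leafy_vegetables
deep_orange_vegetables,Deep orange vegetables,cube,deep_orange_vegetables
cruciferous_vegetables,Cruciferous vegetables,cube,cruciferous_vegetables
other_vegetables,Other vegetables,cube,other_vegetables
liquid_oils,Liquid oils,oil_algorithm,liquid_oils
juice,Juice,cube,juice
sugar_sweetened_beverages,Sugar-sweetened beverages,cube,sugar_sweetened_beverages
sweets_ice_cream,Sweets and ice cream,cube,sweets_ice_cream
purchased_deep_fried_foods,Purchased deep fried foods,cube,purchased_deep_fried_foods
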