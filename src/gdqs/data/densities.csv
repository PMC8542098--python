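group_id,mean_density_g_per_cm3,representative_foods
whole_grains,0.65,Maize on cob|whole grain bread|whole maize grains|whole-grain tortilla|whole wheat roti/chapati|oats|whole flour injera|nshima|pearl millet roti/chapati
refined_grains_baked_goods,0.62,White rice|white bread|pasta|biscuits|wheat roti/chapati|tortilla|sweet bread|refined flour injera|ugali|fritters
deep_orange_tubers,0.65,Orange sweet potato
white_roots_tubers,0.78,Potatoes|french fries|white sweet potatoes|plantain|cassava|yam|ginger|taro|yam bean
legumes,0.80,Cowpeas|lentils|soybean|kidney beans|soymilk|peas|mung beans|black beans|pinto beans|chickpeas
nuts_seeds,0.68,Peanuts/groundnuts|sesame seeds|peanut butter|almonds|sunflower seeds|jackfruit seeds|cowpea seeds|cacao seeds|Job's tears|cumin seeds
fish_shellfish,0.57,Tilapia|tuna|catfish|carp|mullet|perch|mackerel|orangefin barb|sea fish|unspecified fish
poultry_game_meat,0.83,Chicken average cut|chicken leg|chicken breast|chicken wings|duck|fowl|buffalo|rat|chicken thigh|donkey
red_meat,0.87,Beef|pork|goat|mutton|liver|beef/goat stomach|beef entrails|pork ribs|lamb|pork organs
processed_meat,0.81,Smoked/dried beef|ham|pork sausage|turkey ham|burger meat|turkey sausage|dried pork|smoked/dried goat meat|chorizo|bratwurst
eggs,0.6,Chicken eggs
high_fat_dairy_cheese,0.84,Hard cheese (unspecified)|cheddar cheese
high_fat_dairy_other,1.02,Whole milk|sour milk|buffalo milk|whole-milk yogurt|curd|whole-milk drinkable yogurt|Oaxaca cheese|soft cheese
low_fat_dairy,0.96,Low fat milk|low fat yogurt|skimmed buffalo milk|low fat curd|low fat cream cheese|low fat cheese spread
deep_orange_fruits,0.73,Mango|papaya|cantaloupe|nanche|persimmon|tree tomato
citrus_fruits,0.71,Orange|lemon|tangerine|pomelo|grapefruit
other_fruits,0.78,Banana|watermelon|apple|avocado|jack fruit|grapes|green papaya|guava|pineapple
dark_green_leafy_vegetables,0.70,Spinach|sweet potato leaves|pumpkin leaves|cowpea leaves|amaranth leaves|kale|baobab leaves|moringa leaves|jute mallow leaves
deep_orange_vegetables,0.85,Carrot|pumpkin
cruciferous_vegetables,0.67,Cabbage|broccoli|cauliflower|Chinese cabbage
other_vegetables,0.68,Tomato|onion|eggplant|water gourd|cucumber|okra|sweet peppers|fresh chili|zucchini|shallots
juice,1.05,Orange juice|apple juice|grape juice|fruit juice (unspecified)|lemon juice|bissap|pineapple juice|cranberry juice|blackberry juice|roselle drink
sugar_sweetened_beverages,1.07,Soda/cola drink|sweet flavored water|energy drink|sports drink|industrial juice|flavored/chocolate milk|ovaltine|zoom komm|lassi
sweets_ice_cream,0.70,Sugar|cake|ice cream|sugarcane|honey|hard candy|jelly|cookies|sorghum cane|jaggery
purchased_deep_fried_foods,0.46,French fries|deep fried doughnuts|fritters|fried onion|chips|churro|fried chicken|deep fried spring roll|fried fish|fried cake
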