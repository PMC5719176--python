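species,body_mass_kg,area_hol_km2,area_hist_km2,area_mod_km2,pct_hist_printed,pct_mod_printed
Ailuropoda melanoleuca,118.00,749840,88817,16285,11.8,2.2
Arctonyx collaris,8.17,3676360,3676360,3657922,100,99.5
Bubalus mephistopheles,929.50,1527357,0,0,0,0
Canis lupus,31.76,8721246,8721246,7524437,100,86.3
Capreolus pygargus,41.37,4157171,3820650,3817317,91.9,91.8
Capricornis milneedwardsii,110.94,2104840,2103325,1999527,99.9,95.0
Cervus elaphus,240.87,4816709,4449413,3972736,92.4,82.5
Cervus nippon,53.00,2919625,274792,27520,9.4,0.9
Cuon alpinus,15.80,5676234,5128031,4956351,90.3,87.3
Elaphurus davidianus,165.99,963240,0,0,0,0
Elephas maximus,3269.80,2072355,5461,4211,0.3,0.2
Eospalax fontanierii,0.26,1231580,1213187,1200262,98.5,97.5
Equus ferus,403.60,1500557,191966,0,12.8,0
Hydropotes inermis,12.76,1744491,546152,145161,31.3,8.3
Hystrix brachyura,8.00,2433237,2417409,2417409,99.3,99.3
Lutra lutra,8.87,3892243,3888360,3785118,99.9,97.2
Macaca mulatta,6.46,2937921,2935508,2844952,99.9,96.8
Meles leucurus,6.25,6245111,6245111,6175069,100,98.9
Muntiacus reevesi,13.50,2217096,2186594,2186042,98.6,98.6
Muntiacus vaginalis,17.61,1388769,1043690,1032519,75.2,74.3
Naemorhedus spp.,28.22,2213673,2212241,2173200,99.9,98.2
Nyctereutes procyonoides,4.22,4664834,4574286,4574274,98.1,98.1
Paguma larvata,4.30,3084952,3084952,3048167,100,98.8
Panthera pardus,52.40,2981579,2772337,2659147,93.0,89.2
Panthera tigris,161.92,3091975,2631057,29423,85.1,1.0
Prionailurus bengalensis,2.78,4708612,4707595,4072294,99.9,86.5
Rhinoceros spp.,1398.08,1903944,23992,0,1.3,0
Rhizomys sinensis,1.91,2013597,1964514,1963625,97.6,97.5
Rusa unicolor,177.52,2617933,1576197,1561201,60.2,59.6
Sus scrofa,84.47,6554098,6539983,6119878,99.8,93.4
Ursus arctos,196.29,5317488,3882979,3364089,73.0,63.3
Ursus thibetanus,99.71,3152699,3084106,1696226,97.8,53.8
Viverricula indica,2.92,2596039,2596039,2591799,100,99.8
Vulpes vulpes,4.82,9327084,9327084,9327084,100,100
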