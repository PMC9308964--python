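ecoregion,q50_pg,q75_pg,q90_pg,area_km2
Boreal Forests/Taiga,1.64,2.33,3.06,174224
Deserts and Xeric Shrublands,3.23,4.45,5.88,1052258
Flooded Grasslands and Savannas,0.97,1.41,1.94,145205
Mangroves,0.20,0.27,0.35,31880
"Mediterranean forests, woodlands and scrub",4.38,5.84,7.58,859799
Montane grasslands and shrublands,1.29,1.73,2.18,214602
Temperate broadleaf and mixed forests,29.47,40.38,54.03,4178195
Temperate conifer forests,1.15,1.54,2.02,173098
"Temperate grasslands, savannas and shrublands",20.33,26.58,33.91,2777674
Tropical and subtropical coniferous forests,0.27,0.37,0.48,43780
Tropical and subtropical dry broadleaf forests,4.89,6.71,9.25,1314051
"Tropical and subtropical grasslands, savannas and shrublands",4.92,6.91,9.53,1262423
Tropical and subtropical moist broadleaf forests,9.87,13.37,17.48,1771950
Tundra,0.05,0.07,0.09,10712
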