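# frosthatch soil texture parameter table, version 1
# Hydraulic parameters (porosity, air-entry potential, Campbell b, saturated
# conductivity) follow the Clapp & Hornberger (1978) class means for the 11
# USDA texture classes; field capacity (-33 kPa) and wilting point
# (-1500 kPa) follow Rawls et al. (1982) class means.  Thermal parameters
# follow Johansen (1975): solids conductivity 7.7^q * 2.0^(1-q) with q the
# class quartz (sand) fraction, dry conductivity from the dry-density
# relation (0.135*rho_b + 64.7)/(2700 - 0.947*rho_b) with rho_b = 2700*(1-porosity).
# Units: porosity/field_capacity/wilting_point m3 m-3; sat_hydraulic_conductivity mm h-1;
# air_entry_potential kPa (magnitude); dry/solids conductivity W m-1 K-1;
# solids_heat_capacity J m-3 K-1.
texture_class,porosity,field_capacity,wilting_point,sat_hydraulic_conductivity,air_entry_potential,campbell_b,dry_conductivity,solids_conductivity,solids_heat_capacity
sand,0.395,0.091,0.033,633.6,1.19,4.05,0.247,6.91,2130000
loamy_sand,0.410,0.125,0.055,562.8,0.88,4.38,0.235,6.04,2130000
sandy_loam,0.435,0.207,0.095,124.8,2.14,4.90,0.216,4.37,2130000
silt_loam,0.485,0.330,0.133,25.9,7.71,5.30,0.182,2.52,2130000
loam,0.451,0.270,0.117,25.0,4.69,5.39,0.204,3.57,2130000
sandy_clay_loam,0.420,0.255,0.148,22.7,2.93,7.12,0.227,4.37,2130000
silty_clay_loam,0.477,0.366,0.208,6.1,3.49,7.75,0.187,2.29,2130000
clay_loam,0.476,0.318,0.197,8.8,6.18,8.52,0.188,3.07,2130000
sandy_clay,0.426,0.339,0.239,7.8,1.50,10.40,0.222,4.03,2130000
silty_clay,0.492,0.387,0.250,3.7,4.81,10.40,0.178,2.17,2130000
clay,0.482,0.396,0.272,4.6,3.97,11.40,0.184,2.69,2130000
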