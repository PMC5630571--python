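name	formula	molar_mass	role
sucrose	C12H22O11	342.30	substrate
fructose	C6H12O6	180.16	substrate
glucose	C6H12O6	180.16	substrate
acetone	C3H6O	58.08	product
butanol	C4H10O	74.12	product
ethanol	C2H6O	46.07	product
acetate	C2H4O2	60.05	product
butyrate	C4H8O2	88.11	product
biomass	CH1.8O0.5N0.2	24.63	biomass
co2	CO2	44.01	gas
co	CO	28.01	gas
h2	H2	2.016	gas
o2	O2	32.00	gas
n2	N2	28.014	gas
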