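# Study-design table: 54 modern perissodactyl patellae (27 Rhinocerotidae,
# 12 Tapiridae, 15 Equidae). Sex/age transcribed per row; body mass is the
# species mean in kg. Equid subspecies are kept in `taxon`; `species` is the
# binomial used for tree matching.
specimen_id,family,taxon,species,body_mass_kg,sex,age_class
AMNH M-51854,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,F,adult
AMNH M-51855,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,M,adult
AMNH M-51857,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,F,adult
AMNH M-51858,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,M,adult
AMNH M-81815,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,U,adult
BICPC NH.CON.37,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,F,adult
BICPC NH.CON.110,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,M,adult
BICPC NH.CON.112,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,M,adult
MNHN ZM-MO-2005-297,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,M,adult
NHMUK ZD 2018.143,Rhinocerotidae,Ceratotherium simum,Ceratotherium simum,2300,U,adult
AMNH M-113777,Rhinocerotidae,Diceros bicornis,Diceros bicornis,1050,U,adult
MNHN ZM-AC-1944-278,Rhinocerotidae,Diceros bicornis,Diceros bicornis,1050,M,adult
NHMUK ZD 1879.9.26.6,Rhinocerotidae,Diceros bicornis,Diceros bicornis,1050,U,unknown
AMNH M-81892,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,M,adult
NHMUK ZD 1879.6.14.2,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,M,adult
NHMUK ZD 1894.9.24.1,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,U,adult
NHMUK ZE 1948.12.20.1,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,U,adult
NHMUK ZE 1949.1.11.1,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,U,adult
NHMUK ZD 2004.23,Rhinocerotidae,Dicerorhinus sumatrensis,Dicerorhinus sumatrensis,775,U,adult
MNHN ZM-AC-A7970,Rhinocerotidae,Rhinoceros sondaicus,Rhinoceros sondaicus,1350,U,adult
NHMUK ZD 1871.12.29.7,Rhinocerotidae,Rhinoceros sondaicus,Rhinoceros sondaicus,1350,M,adult
AMNH M-35759,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,M,adult
AMNH M-54454,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,F,adult
MNHN ZM-AC-1967-101,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,F,adult
NHMUK ZE 1961.5.10.1,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,M,adult
NHMUK ZD 1972.822,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,U,adult
NHMUK ZD 1884.12.1.2,Rhinocerotidae,Rhinoceros unicornis,Rhinoceros unicornis,2000,F,adult
MVZ 141172,Tapiridae,Tapirus bairdii,Tapirus bairdii,260,U,adult
MNHN ZM-AC-1931-528,Tapiridae,Tapirus indicus,Tapirus indicus,340,M,adult
MNHN ZM-AC-1945-460,Tapiridae,Tapirus indicus,Tapirus indicus,340,M,adult
NMB 8125,Tapiridae,Tapirus indicus,Tapirus indicus,340,F,adult
RBINS 1184D,Tapiridae,Tapirus indicus,Tapirus indicus,340,M,adult
RBINS 1184E,Tapiridae,Tapirus indicus,Tapirus indicus,340,M,adult
MNHN ZM-AC-1982-34,Tapiridae,Tapirus pinchaque,Tapirus pinchaque,175,M,adult
MNHN ZM-AC-1877-765,Tapiridae,Tapirus pinchaque,Tapirus pinchaque,175,U,adult
MNHN ZM-AC-1937-1,Tapiridae,Tapirus terrestris,Tapirus terrestris,220,U,adult
MNHN ZM-MO-1990-20,Tapiridae,Tapirus terrestris,Tapirus terrestris,220,M,adult
RBINS 1185D,Tapiridae,Tapirus terrestris,Tapirus terrestris,220,M,adult
RBINS 1185E,Tapiridae,Tapirus terrestris,Tapirus terrestris,220,U,adult
MNHN ZM-AC-1893-634,Equidae,Equus africanus asinus,Equus africanus,275,M,adult
MNHN ZM-2005-717,Equidae,Equus africanus asinus,Equus africanus,275,U,adult
RBINS 12970,Equidae,Equus africanus asinus,Equus africanus,275,F,adult
RBINS 13076,Equidae,Equus africanus asinus,Equus africanus,275,F,adult
MNHN ZM-AC-1880-1103,Equidae,Equus hemionus,Equus hemionus,230,M,adult
MNHN ZM-AC-A541,Equidae,Equus ferus caballus,Equus ferus,490,F,adult
MVZ 162289,Equidae,Equus ferus caballus,Equus ferus,490,M,adult
MNHN ZM-AC-1975-124,Equidae,Equus ferus przewalskii,Equus ferus,250,F,adult
RBINS 14281,Equidae,Equus ferus przewalskii,Equus ferus,250,M,adult
RBINS 33386,Equidae,Equus burchellii granti,Equus burchellii,247,U,adult
RBINS 32166,Equidae,Equus grevyi,Equus grevyi,400,M,adult
RBINS 12129,Equidae,Equus quagga boehmi,Equus quagga,247,M,adult
RBINS 1218,Equidae,Equus quagga chapmani,Equus quagga,247,F,adult
IMNH R2425,Equidae,Equus quagga quagga,Equus quagga,247,U,adult
RBINS 3974,Equidae,Equus zebra hartmannae,Equus zebra,310,M,subadult
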