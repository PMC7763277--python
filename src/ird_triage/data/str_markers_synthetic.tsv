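# Synthetic stand-in map: 26 X-chromosome microsatellite markers with
# plausible ordered positions (bp). Marker names follow DXS nomenclature;
# positions are NOT curated genomic coordinates.
name	chrom	position
DXS1060	X	4200000
DXS8051	X	7800000
DXS987	X	11500000
DXS1226	X	15600000
DXS1214	X	20400000
DXS1068	X	24900000
DXS993	X	30200000
DXS991	X	35100000
DXS986	X	38900000
DXS990	X	42500000
DXS1106	X	55000000
DXS1210	X	63000000
DXS1001	X	70000000
DXS1047	X	76500000
DXS1227	X	83000000
DXS8043	X	89500000
DXS8073	X	95800000
DXS1073	X	101500000
DXS8088	X	107800000
DXS7132	X	113200000
DXS6800	X	119000000
DXS6789	X	124500000
DXS6809	X	130800000
DXS1193	X	137500000
DXS8377	X	146000000
DXS1108	X	153500000
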