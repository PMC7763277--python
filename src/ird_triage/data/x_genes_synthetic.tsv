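# Synthetic stand-in coordinates for X-chromosome retinal-disease genes and
# the CITED1 candidate, ordered consistently with their map order; intervals
# are plausible but NOT curated genomic coordinates.
gene	chrom	start	end
RPGR	X	38128424	38186817
NYX	X	41333308	41361551
NDP	X	43808031	43832920
CACNA1F	X	49061523	49089833
RP2	X	46696376	46741793
PGK1	X	77320685	77384793
CITED1	X	71521542	71529347
CHM	X	85116184	85302566
TIMM8A	X	100600643	100603957
PRPS1	X	106871654	106894256
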