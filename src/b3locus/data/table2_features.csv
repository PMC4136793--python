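name,kind,start,end,strand,note
rluF,other,245,2109,+,ribosomal large subunit pseudouridine synthase F
Pol_1,other,3536,4072,+,DNA/RNA polymerase
Pol_2,other,5603,6601,+,reverse transcriptase-RNase H-integrase
hyp_1,other,9893,10651,+,conserved hypothetical protein
CYP,other,13695,15784,+,cytochrome P450
omt,other,16301,23699,+,O-methyltransferase
rnt,other,24383,25349,+,ribonuclease T
PEphb3.1,pheromone,26325,26510,+,fungal mating-type pheromone
PEphb3.2,pheromone,27056,27232,+,B mating type pheromone precursor
PESTE3.3.1,receptor,28186,29384,+,putative pheromone receptor
PEphb3.3,pheromone,29629,29877,+,fungal mating-type pheromone
PESTE3.3.2,receptor,30416,31911,+,putative pheromone receptor
PESTE3.3.3,receptor,32405,34232,+,hypothetical fungal pheromone GPCR STE3-type
PEphb3.4,pheromone,35693,35869,+,lipopeptide mating pheromone precursor
PESTE3.3.4,receptor,36579,38224,+,pheromone receptor Rcb2
hyp_2,other,38948,41569,+,hypothetical protein
ubiA,other,43157,43972,+,UbiA prenyltransferase
hyp_3,other,44187,45557,+,predicted protein
sgnH,other,46375,48010,+,SGNH hydrolase
hyp_4,other,48339,51782,+,hypothetical protein
hyp_5,other,53063,55751,+,hypothetical protein
Pol_3,other,57385,59974,+,reverse transcriptase-RNase H-integrase
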