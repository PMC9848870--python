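# Default control-region motif configuration: name, IUPAC pattern, max_mismatch.
# The poly-C tract is the conserved wagtail domain-I tract; the box and CSB1
# consensi below are editable placeholder patterns approximating avian
# control-region motifs.  The software treats every row purely as a search
# pattern and makes no claim of universality — replace with curated consensi
# for real analyses.
poly_C	CCCCCCCCCCTTCCCCCCCC	2
F_box	ATGTACTATTGAACGTACAT	2
E_box	CCTGAAGAAAGAACCTTCAG	2
D_box	CCCTTGACCGAGGAACCAGA	2
C_box	TGCAGTTTCAACGGCATCTG	2
B_box	TCGGACATAGGGATTTATCG	2
bird_similarity_box	CAACGATTAATGCTCGATAG	2
CSB1	TTCGTGCATTTGGTTCCTAT	2
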