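marker_id	chr_position	allele_pair	f1	f2	r
Marker1	LUGG01000002.1_2880791	A/G	GAAGGTGACCAAGTTCATGCTACCACAACAGCGCAGCAGTA	GAAGGTCGGAGTCAACGGATTCCACAACAGCGCAGCAGTG	CAACCGCTCGTCTAATAATTCTCC
Marker2	LUGG01000003.1_1987918	A/G	GAAGGTGACCAAGTTCATGCTCGACTGCGTCTTGTATTTCTCTT	GAAGGTCGGAGTCAACGGATTCGACTGCGTCTTGTATTTCTCTC	GAGATGACGAGGCAGTGAATGAC
Marker3	LUGG01000004.1_346179	T/C	GAAGGTGACCAAGTTCATGCTGTATTTCGTGCAGTGCTCCTTA	GAAGGTCGGAGTCAACGGATTTTTCGTGCAGTGCTCCTTG	AGGAGGAGATGAAGGAAGTTTGTT
Marker4	LUGG01000006.1_718221	G/A	GAAGGTGACCAAGTTCATGCTCCTTCCTCCAGCACAAGCC	GAAGGTCGGAGTCAACGGATTTCCTTCCTCCAGCACAAGCT	TGACTATCTGCGGGATACTGAAGTT
Marker5	LUGG01000013.1_1509986	G/A	GAAGGTGACCAAGTTCATGCTGTCTCGTCATCCGAGTTGTCG	GAAGGTCGGAGTCAACGGATTAGTCTCGTCATCCGAGTTGTCA	AGAGTGATGTGATGTTGTCTGAGCA
Marker6	LUGG01000017.1_156103	T/C	GAAGGTGACCAAGTTCATGCTGTGCTTGCTTACCACAGCTTCTAT	GAAGGTCGGAGTCAACGGATTGTGCTTGCTTACCACAGCTTCTAC	GTTGCTCACTATCAGACAGTTTAAGGG
Marker7	LUGG01000022.1_499394	C/A	GAAGGTGACCAAGTTCATGCTTCCCTTCCTTCTAGCCTTGACC	GAAGGTCGGAGTCAACGGATTTCCCTTCCTTCTAGCCTTGACA	GCCTCGAGATCTGGAATTTTGTAG
Marker8	LUGG01000003.1_1053539	C/T	GAAGGTGACCAAGTTCATGCTTGACCAGCTACTCTTGCAGGG	GAAGGTCGGAGTCAACGGATTCTGACCAGCTACTCTTGCAGGA	TACAGCTGGATGGGAGTCGTCA
Marker9	LUGG01000003.1_2042709	C/T	GAAGGTGACCAAGTTCATGCTAGGTTTACAGGAGCTGTTGTAGATATG	GAAGGTCGGAGTCAACGGATTCAGGTTTACAGGAGCTGTTGTAGATATA	TCTAAGGTTTTCAACAAAGTCAGCG
Marker10	LUGG01000002.1_1446577	C/T	GAAGGTGACCAAGTTCATGCTAGGCGACGGTGTCATGAGG	GAAGGTCGGAGTCAACGGATTGAGGCGACGGTGTCATGAGA	CTGCTGAACCTCTGGAGACTCGTAT
Marker11	LUGG01000023.1_401039	A/G	GAAGGTGACCAAGTTCATGCTCCAACTCTTGATCTACCTGCCAAT	GAAGGTCGGAGTCAACGGATTCCAACTCTTGATCTACCTGCCAAC	TAGAGTCGCGCAAATTGGAGGT
Marker12	LUGG01000033.1_182680	C/A	GAAGGTGACCAAGTTCATGCTGCGCAAAATATGCTTGCCTC	GAAGGTCGGAGTCAACGGATTAGCGCAAAATATGCTTGCCTA	CGGCATTTGAAAGCTCGAGAA
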