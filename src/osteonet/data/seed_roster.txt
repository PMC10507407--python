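# 14 experimentally detected seed proteins of the desmin-osteogenesis
# interactome (rat symbols), including the osteogenic markers Runx2 and Alpp
Des
Vim
Cfl1
Pfn1
Msn
Myl4
Myl12a
Hspb1
Got1
Arhgdia
Runx2
Alpp
Rhoa
Slc9a3r1
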