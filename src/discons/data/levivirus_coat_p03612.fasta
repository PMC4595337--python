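>P03612 binding_class=rna taxon=virus Coat protein, bacteriophage MS2 (Levivirus); chain of the coat-protein/RNA-hairpin complex
MASNFTQFVLVDNGGTGDVTVAPSNFANGVAEWISSNSRSQAYKVTCSVRQSSAQNRKYT
IKVEVPKVATQTVGGVELPVAAWRSYLNMELTIPIFATNSDCELIVKAMQGLLKDGNPIP
SAIAANSGIY
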