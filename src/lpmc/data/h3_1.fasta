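>H3_1 human histone H3.1, 136 residues
MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALR
EIRRYQKSTELLIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAY
LVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA
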