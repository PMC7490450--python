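>hsa-miR-200b-3p MIMAT0000318 mature miRNA
UAAUACUGCCUGGUAAUGAUGA
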