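>NisA nisin A prepropeptide (leader 1-23, propeptide 24-57)
MSTKDFNLDLVSVSKKDSGASPRITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK
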