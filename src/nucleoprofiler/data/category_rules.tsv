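pattern	category	priority
ribosom	R	10
chaperon|cold.?shock|thioredoxin|superoxide|peroxidase|redox|alkyl hydroperoxide|groel|groes|dnak|dnaj	C	20
DNA.?binding|transcription|regulator|helix.?turn.?helix|histone|nucleoid|sigma factor|repressor|activator|response regulator	D	30
unknown function|uncharacteri[sz]ed|hypothetical	U	40
enzyme|ase\b|membrane|transporter|cytosolic|metabol	E	50
.	U	1000
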