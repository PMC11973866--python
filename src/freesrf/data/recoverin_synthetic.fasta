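>recoverin_synthetic SYNTHETIC stand-in: recoverin-like, 201 aa, 23200.7 g/mol (vertebrate-average composition; not a database sequence)
SRDSEGLGPYTNILLNAIEKACVRLYMEKEEQMFMGLQEIRLLILISSSKRQWFHKRETT
RYREEATVHSRANGLGLKARLRADDALVLNATRIMSKVLLQDDDTITSIFFAYFSTNESY
WFVQQYMPQYWKVPKVKDPRPVWVLTCFTTLIPYTRAPTDYRDQGCQPREIIMARPNFVP
VLSITALSNDGTSPDFADAAS
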