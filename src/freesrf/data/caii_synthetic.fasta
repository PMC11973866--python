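>caii_synthetic SYNTHETIC stand-in: carbonic-anhydrase-II-like, 260 aa, 29252.8 g/mol (vertebrate-average composition; not a database sequence)
EESNPSGKNSTPRPKYPTAGELEDLWLTERLFSGLTCNDISTDEDKTRKPNKSRKAPCDA
ATPAIEEKGIWTGSQTPGYKRKAPFMHGTSLAFVGIRDSKLTTTFETFFFAAKRFDAVAQ
GFRRDLVYARKAGEDYISQVTAKFKTNSLVEDLWDLFTEEKDARGSTGRSRVSCNNTQKS
DEQHTNSNLECDPVNDLRKSAGTQAGLPIAKKLHRGRTPQFEKEPKEYGVIAKRWQLDLN
RDPFDLGDNLAQTLYQMSII
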