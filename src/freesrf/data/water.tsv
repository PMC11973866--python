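# Solvation-shell water constants.
# alpha_shell_water: average polarizability of one water molecule inside a protein
#   solvation shell (A^3); v_water: volume of one water molecule (A^3).
# key	value	source
alpha_shell_water	1.5	shell-water average polarizability
v_water	25.0	molecular volume of water
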