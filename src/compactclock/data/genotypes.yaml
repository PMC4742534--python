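# Mutant presets, keyed by line name.
#
# tx_scale multiplies the maximal transcription rate (and acute-light
# amplitude, where present) of a merged gene pair: 0.5 = single
# loss-of-function mutant, 0.1 = double mutant, 0 = null.  Both members of
# a merged pair map to the same simulated line.  ox_v_cl_multiple replaces
# the regulated CL transcription term by a constant rate expressed as a
# multiple of the wild-type maximal rate (constitutive overexpression).
wildtype: {}
cca1:     {tx_scale: {CL: 0.5}}
lhy:      {tx_scale: {CL: 0.5}}
prr9:     {tx_scale: {P97: 0.5}}
prr7:     {tx_scale: {P97: 0.5}}
prr5:     {tx_scale: {P51: 0.5}}
toc1:     {tx_scale: {P51: 0.5}}
elf3-12:  {tx_scale: {EL: 0.5}}   # weak Evening Complex line
cca1lhy:  {tx_scale: {CL: 0.1}}
prr9prr7: {tx_scale: {P97: 0.1}}
prr5toc1: {tx_scale: {P51: 0.1}}
elf4lux:  {tx_scale: {EL: 0.0}}   # EC null (elf4, lux or elf3 knockout)
cca1-ox:  {ox_v_cl_multiple: 5.0}
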