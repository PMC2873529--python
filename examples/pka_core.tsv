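# Example 5-gene core for the Dictyostelium PKA pathway, in the package's
# edge-list format (parent<TAB>child). Direction follows the regulatory
# arrows of the established biochemical pathway: PufA sequesters pkaC mRNA,
# PkaR inhibits PkaC, AcaA produces the cAMP that releases PkaR, and RegA
# degrades it. Which five genes to use as the core is a modelling choice --
# edit this file to match the rows of your expression matrix.
pufA	pkaC
pkaR	pkaC
acaA	pkaR
regA	pkaR
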