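"""Align a miRNA against a candidate target site and inspect the duplex.

The aligner classifies every position as Watson-Crick match, G:U wobble,
mismatch or gap, and sums a penalty (wobble 0.5, mismatch/gap 1, doubled at
seed positions 2-13 from the miRNA 5' end).  Lower penalty = better site.
"""

from mirduplex import align_duplex

# an Arabidopsis-style 21-mer and a site with one mismatch in the 3' region
mirna = "UGACAGAAGAGAGUGAGCACA"
site = "UGUGCUCUCUCUCUUCUGUCA"  # 5'->3' on the transcript

aln = align_duplex(mirna, site)
print(aln.render())
print(f"states : {aln.states}")
print(f"penalty: {aln.penalty}")
# The midline marks matches with '|' and wobbles with ':'.  The penalty is
# the additive cost of the non-matching columns, seed positions doubled.
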