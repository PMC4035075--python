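"""Scan a transcript for target sites of one miRNA.

A site is implanted with a known edit profile (one seed wobble), then the
seed-anchored scanner is asked to find it at two cutoffs.
"""

from mirduplex import (
    SynthProfile,
    generate_mirnas,
    generate_transcript,
    implant_site,
    scan_transcript,
)

mirna = generate_mirnas(1, seed=8)[0]
transcript = generate_transcript(400, "TX1", seed=8)
transcript, truth = implant_site(
    transcript, mirna, SynthProfile(n_seed_wobbles=1), position=150, seed=8
)
print(f"implanted at {truth.site_start}-{truth.site_end}, penalty {truth.penalty}")

for cutoff in (0.0, 2.0):
    hits = scan_transcript(mirna, transcript, cutoff)
    print(f"cutoff {cutoff}: {[(h.site_start, h.score) for h in hits]}")
# The wobble costs 0.5 doubled inside the seed window, so the site appears
# only once the cutoff reaches 1.0.
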