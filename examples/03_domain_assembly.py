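"""Reassemble a domain from fragmented HMM hits.

HMM searches align locally, so one divergent domain often shows up as two
or more fragments.  Two consecutive fragments merge only when their
start and end coordinates are both >20 residues apart, the sequence gap
is at most 200 residues, and their profile coordinates overlap by at most
30 positions.
"""

from ssnclose import DomainHit, assemble_fragments, length_filter

mergeable = [
    DomainHit("prot1", "GHX", 200, 1, 100, 1, 100, 1e-30),
    DomainHit("prot1", "GHX", 200, 150, 250, 95, 200, 1e-12),
]
merged = assemble_fragments(mergeable)
d = merged[0]
print(f"two fragments (1-100, 150-250) -> {len(merged)} domain: "
      f"{d.seq_from}-{d.seq_to} from {len(d.fragments)} fragments")

too_far = [
    DomainHit("prot2", "GHX", 200, 1, 100, 1, 100, 1e-30),
    DomainHit("prot2", "GHX", 200, 360, 450, 95, 200, 1e-12),  # gap 260 > 200
]
print(f"gap of 260 residues -> {len(assemble_fragments(too_far))} separate domains")

# length sanity: shorter than half the HMM is dropped; extreme lengths
# relative to the family are flagged for manual inspection
population = [assemble_fragments([DomainHit("p%d" % i, "GHX", 200, 1, 195 + i, 1, 150, 1e-9)])[0]
              for i in range(11)]
runt = assemble_fragments([DomainHit("runt", "GHX", 200, 1, 99, 1, 80, 1e-9)])[0]
giant = assemble_fragments([DomainHit("giant", "GHX", 200, 1, 620, 1, 150, 1e-9)])[0]
flagged = length_filter(population + [runt, giant], {"GHX": 200})
for dom in flagged[-2:]:
    print(f"{dom.seq_id}: length {dom.length} -> {dom.length_flag}")
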