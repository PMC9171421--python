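"""Scan a transcript in three frames and compute its ORF dominance.

The transcript is constructed to carry the ORF layout of the human NCYM
transcript: a 109-aa primary ORF in the frame at 5' offset 1 and three
secondary ORFs of 69, 8 and 6 aa in the frame at offset 2.
"""

from orfdom import embed_orfs, profile_transcript, round_half_up, scan_frames

transcript = embed_orfs({1: [109], 2: [69, 8, 6]}, id="ncym_like")
orf_set = scan_frames(transcript)
profile = profile_transcript(orf_set)

print(f"transcript length : {len(transcript.bases)} nt")
for orf in orf_set.orfs:
    print(f"  frame {orf.frame}  start {orf.start:4d}  {orf.aa_length:4d} aa")
print(f"pORF length       : {profile.porf_length} aa")
print(f"secORF lengths    : {profile.secorf_lengths}")
print(f"ORF dominance     : {round_half_up(profile.dominance)}")
print(f"ORF coverage      : {round_half_up(profile.coverage)}")

# Dominance = 109 / (109 + 69 + 8 + 6) = 0.568: the primary ORF makes up
# 56.8% of the transcript's total ORF content, typical of a coding RNA.
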