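"""Tokenize a DNA sequence with both segmentation schemes.

Continuous segmentation slides a width-3 window one base at a time,
producing the L-2 overlapping trinucleotides.  Skip segmentation slides
the window three bases at a time from offsets 0, 1 and 2, producing
three non-overlapping derived sequences whose final word may be shorter.
"""

from orivec import build_vocabulary, continuous_tsss, skip_tsss

seq = "ACGTCGTA"
print(f"input sequence: {seq} (L = {len(seq)})")

cont = continuous_tsss(seq)
print(f"\ncontinuous ({len(cont)} tokens = L-2):")
print("  ", " ".join(cont.tokens))

print("\nskip (3 derived sequences, no base discarded):")
for ts in skip_tsss(seq):
    print(f"   offset {ts.offset}: {' '.join(ts.tokens)}")

for mode in ("continuous", "skip"):
    v = build_vocabulary(mode)
    print(f"\n{mode} vocabulary: {v.n_words} words (+ 1 PAD index)")
# 64 trinucleotides for continuous; skip adds the 4 mono- and 16
# dinucleotides that can appear as a final word, giving 84.
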