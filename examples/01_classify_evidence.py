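"""Combine ACMG-AMP evidence codes into five-tier verdicts.

Each line prints the evidence set, the verdict, and the combining rule
that fired (e.g. P.i.b = very strong + >=2 moderate).  A lone benign-side
code next to a firing pathogenic combination does not force VUS; only
combinations firing on both sides do.
"""

from exosf import classify, parse_evidence

EXAMPLES = [
    "PVS1 PM1 PM2",            # truncating, hotspot, absent from controls
    "PVS1 PM2",                # truncating but only one moderate criterion
    "PM1 PM2 PP3 PP5",         # moderate + supporting only
    "PS3 PM2 PM3 PP3 PP5",     # functional evidence + moderates + supporting
    "PVS1 PM1 PM2 PP5 BS2",    # stray benign code completes no combination
    "PVS1 PM1 PM2 BS1 BS2",    # combinations fire on both sides
    "BA1",                     # stand-alone benign (common allele)
    "PP1 PP2 PP3",             # supporting evidence alone is never enough
]

for text in EXAMPLES:
    result = classify(parse_evidence(text))
    print(f"{text:26s} -> {result.verdict:18s} ({result.fired_rule})")
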