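# Illustrative mutation list (compact notation), one mutation per line.
# These are synthetic examples for demonstrating the tooling, not a curated
# mutation set for any real protein.
V51R      # substitution: valine 51 -> arginine
F508del   # deletion of phenylalanine at 508
508insG   # insertion of glycine after 508
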