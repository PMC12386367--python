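"""Shared pytest configuration (test modules import helper oracles directly)."""
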