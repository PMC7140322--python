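from retrocomp.seq_io import CodingSequence, validate_orf


def make_cds(sequence: str, **kw) -> CodingSequence:
    """Validated CodingSequence from a raw string (test helper)."""
    return validate_orf(CodingSequence(id=kw.pop("id", "seq"), sequence=sequence, **kw))
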