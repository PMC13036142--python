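"""Exception hierarchy.

ValidationError covers bad values in otherwise well-formed input;
FormatError covers structurally malformed files. The CLI maps
ValidationError/FormatError to exit code 1 and anything else to 2.
"""


class ValidationError(ValueError):
    pass


class FormatError(ValidationError):
    pass
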